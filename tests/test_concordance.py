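import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxorder import (concordance, cost_percentile_subset,
                       find_flux_ordered_pairs, level_partition,
                       map_data_to_reactions, mean_difference,
                       reaction_profile_from_table, regulatory_level_analysis,
                       synthetic_omics)
from fluxorder.concordance import DataMappingError
from fluxorder.order_dag import build_order_dag
from fluxorder.order_finder import OrderedPairSet

from conftest import toy_model

values = st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=1,
                  max_size=12)


class TestMeanDifference:
    @pytest.mark.parametrize("a,b,expected", [
        ([2, 4], [1, 3], 1.0),
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([5], [2, 2, 2], 3.0),
    ])
    def test_examples(self, a, b, expected):
        assert mean_difference(a, b) == pytest.approx(expected)

    @given(values, values)
    @settings(max_examples=60, deadline=None)
    def test_double_sum_identity(self, a, b):
        # (1/nm) sum_p sum_q (a_p - b_q) == mean(a) - mean(b)
        double = sum(x - y for x in a for y in b) / (len(a) * len(b))
        assert mean_difference(a, b) == pytest.approx(double, abs=1e-6,
                                                      rel=1e-9)

    def test_empty_multiset_rejected(self):
        with pytest.raises(ValueError):
            mean_difference([], [1.0])


class TestGprMapping:
    def model_with_rules(self):
        return toy_model(
            ["A"],
            [("r_or", {"A": 1.0}, 0, 10, "g1 or g2"),
             ("r_dup", {"A": -0.5}, 0, 10, "g1 and g1"),
             ("r_none", {"A": -0.5}, 0, 10, "")])

    def test_or_rule_pools_all_gene_values(self):
        prof = map_data_to_reactions(self.model_with_rules(),
                                     {"g1": [1, 2], "g2": [3]})
        assert sorted(prof.values["r_or"]) == [1, 2, 3]

    def test_duplicate_gene_in_rule_counts_once(self):
        prof = map_data_to_reactions(self.model_with_rules(),
                                     {"g1": [1, 2], "g2": [3]})
        assert sorted(prof.values["r_dup"]) == [1, 2]

    def test_reaction_without_gpr_absent(self):
        prof = map_data_to_reactions(self.model_with_rules(),
                                     {"g1": [1], "g2": [2]})
        assert "r_none" not in prof.values

    def test_dataframe_input_pools_replicates(self):
        df = pd.DataFrame({"gene_id": ["g1", "g1", "g2"],
                           "condition": ["c", "c", "c"],
                           "replicate": [0, 1, 0],
                           "value": [1.0, 2.0, 3.0]})
        prof = map_data_to_reactions(self.model_with_rules(), df)
        assert sorted(prof.values["r_or"]) == [1, 2, 3]

    def test_disjoint_gene_ids_raise_with_diagnostics(self):
        with pytest.raises(DataMappingError, match="look like"):
            map_data_to_reactions(self.model_with_rules(),
                                  {"b0001": [1.0], "b0002": [2.0]})


class TestConcordance:
    def orders_and_profile(self, noise_sd, seed, model):
        pairs = find_flux_ordered_pairs(model, n_samples=100, seed=seed)
        om = synthetic_omics(model, pairs, noise_sd, seed=seed)
        prof = map_data_to_reactions(om.model, om.gene_table)
        return pairs, prof

    def test_noiseless_profile_fully_concordant(self, branch):
        pairs, prof = self.orders_and_profile(0.0, 11, branch)
        res = concordance(pairs, prof, n_perm=99, seed=1)
        assert res.f_pos == 1.0
        assert res.n_pairs == len(pairs.ordered)

    def test_identical_value_sets_give_zero_strict_fraction(self):
        orders = OrderedPairSet(ordered={("r1", "r2")})
        prof = reaction_profile_from_table({"r1": [2.0, 3.0],
                                            "r2": [2.0, 3.0]})
        res = concordance(orders, prof, n_perm=49, seed=0)
        assert res.f_pos == 0.0

    @pytest.mark.parametrize("n_perm", [9, 99])
    def test_p_value_within_permutation_bounds(self, branch, n_perm):
        pairs, prof = self.orders_and_profile(0.5, 3, branch)
        res = concordance(pairs, prof, n_perm=n_perm, seed=5)
        assert 1 / (n_perm + 1) <= res.p_value <= 1.0

    def test_null_data_is_not_significant_typically(self, paperlike):
        # values independent of the ordering: f_pos should hover near 1/2
        pairs = find_flux_ordered_pairs(paperlike, n_samples=100, seed=0)
        rng = np.random.default_rng(42)
        hits = 0
        for rep in range(10):
            prof = reaction_profile_from_table(
                {rid: [float(v) for v in rng.normal(0, 1, 3)]
                 for rid in paperlike.reaction_ids})
            res = concordance(pairs, prof, n_perm=99, seed=rep)
            hits += res.p_value <= 0.05
        assert hits <= 1

    def test_no_covered_pairs_raises(self, branch):
        pairs = find_flux_ordered_pairs(branch, n_samples=100, seed=0)
        prof = reaction_profile_from_table({"unrelated": [1.0]})
        with pytest.raises(ValueError, match="no ordered pair"):
            concordance(pairs, prof, n_perm=9, seed=0)

    def test_without_replacement_mode_runs(self, branch):
        pairs, prof = self.orders_and_profile(0.2, 7, branch)
        res = concordance(pairs, prof, n_perm=49, seed=2,
                          with_replacement=False)
        assert 0.0 <= res.f_pos <= 1.0


class TestCostPercentile:
    def orders(self):
        rids = [f"r{k}" for k in range(1, 11)]
        # descending chain r10 >= r9 >= ... >= r1, as directed pairs
        ordered = {(rids[b], rids[a]) for a in range(10) for b in range(a + 1, 10)}
        return OrderedPairSet(ordered=ordered), rids

    def test_percentile_zero_is_identity(self):
        orders, rids = self.orders()
        costs = reaction_profile_from_table({r: [float(k + 1)]
                                             for k, r in enumerate(rids)})
        assert cost_percentile_subset(orders, costs, 0).ordered == \
            orders.ordered

    def test_threshold_keeps_only_expensive_pairs(self):
        orders, rids = self.orders()
        costs = reaction_profile_from_table({r: [float(k + 1)]
                                             for k, r in enumerate(rids)})
        # 70th percentile of 1..10 (linear interpolation) = 7.3,
        # so only r8, r9, r10 (costs 8, 9, 10) survive: 3 pairs
        sub = cost_percentile_subset(orders, costs, 70)
        survivors = {r for p in sub.ordered for r in p}
        assert survivors == {"r8", "r9", "r10"}
        assert len(sub.ordered) == 3

    def test_pair_with_uncosted_member_dropped(self):
        orders, rids = self.orders()
        costs = reaction_profile_from_table(
            {r: [float(k + 1)] for k, r in enumerate(rids) if r != "r9"})
        sub = cost_percentile_subset(orders, costs, 70)
        assert all("r9" not in p for p in sub.ordered)

    def test_out_of_range_percentile_rejected(self):
        orders, _ = self.orders()
        with pytest.raises(ValueError):
            cost_percentile_subset(orders, None, 100)


class TestRegulatoryLevels:
    def chain_dag_model(self, n=9):
        rids = [f"r{k}" for k in range(n)]
        ordered = {(rids[a], rids[b]) for a in range(n)
                   for b in range(a + 1, n)}
        dag = build_order_dag(OrderedPairSet(ordered=ordered))
        model = toy_model(["A"],
                          [(rid, {"A": 1.0 if k == 0 else -1.0}, 0, 10,
                            f"g{k}") for k, rid in enumerate(rids)])
        return dag, model

    def test_identical_distributions_not_significant(self):
        dag, model = self.chain_dag_model()
        counts = {f"g{k}": 5.0 for k in range(9)}
        out = regulatory_level_analysis(dag, level_partition(dag), counts,
                                        model)
        for p in out["p_values"].values():
            assert p is None or p > 0.05

    def test_shifted_first_subset_detected(self):
        # 30+ genes per subset with stochastically larger counts up top
        n = 9
        rids = [f"r{k}" for k in range(n)]
        ordered = {(rids[a], rids[b]) for a in range(n)
                   for b in range(a + 1, n)}
        dag = build_order_dag(OrderedPairSet(ordered=ordered))
        genes_per_rxn = 35
        rxns = []
        for k, rid in enumerate(rids):
            rule = " or ".join(f"g{k}_{i}" for i in range(genes_per_rxn))
            rxns.append((rid, {"A": 1.0 if k == 0 else -1.0}, 0, 10, rule))
        model = toy_model(["A"], rxns)
        rng = np.random.default_rng(0)
        counts = {}
        for k in range(n):
            shift = 6.0 if k == 0 else 0.0
            for i in range(genes_per_rxn):
                counts[f"g{k}_{i}"] = float(rng.poisson(3 + shift))
        out = regulatory_level_analysis(dag, level_partition(dag), counts,
                                        model)
        assert out["p_values"]["first_vs_last"] < 0.05

    def test_single_gene_subsets_use_exact_test(self):
        dag, model = self.chain_dag_model(n=3)
        counts = {"g0": 7.0, "g1": 3.0, "g2": 1.0}
        out = regulatory_level_analysis(dag, level_partition(dag), counts,
                                        model)
        # exact one-sided U test with n=m=1: p = 0.5 when the first wins
        assert out["p_values"]["first_vs_last"] == pytest.approx(0.5)

    def test_empty_subset_skipped_with_warning(self):
        dag, model = self.chain_dag_model(n=2)  # no level >= 2 nodes
        counts = {"g0": 1.0, "g1": 2.0}
        with pytest.warns(UserWarning, match="empty subset"):
            out = regulatory_level_analysis(dag, level_partition(dag), counts,
                                            model)
        assert out["p_values"]["first_vs_last"] is None
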