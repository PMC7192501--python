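import networkx as nx
import numpy as np
import pytest
from scipy.optimize import linprog

from fluxorder import (assign_levels, biomass_ancestor_subgraph,
                       build_order_dag, condition_overlap,
                       essentiality_order_report, find_essential_reactions,
                       find_flux_ordered_pairs, level_partition)
from fluxorder.order_dag import CyclicOrderError, OrderDAG
from fluxorder.order_finder import OrderedPairSet


def dag_from(ordered, equal=(), groups=None):
    s = OrderedPairSet(ordered=set(ordered),
                       equal={frozenset(p) for p in equal})
    return build_order_dag(s, groups)


class TestBuildOrderDag:
    def test_chain_transitive_edge_removed(self):
        d = dag_from([("a", "b"), ("b", "c"), ("a", "c")])
        edges = {(min(x), min(y)) for x, y in d.edges}
        assert edges == {("a", "b"), ("b", "c")}

    def test_equal_pair_collapses_to_single_node_without_self_edge(self):
        d = dag_from([], equal=[("a", "b")])
        assert d.nodes == [frozenset(("a", "b"))]
        assert d.edges == []

    def test_branch_has_uptake_group_as_sole_root(self, branch):
        pairs = find_flux_ordered_pairs(branch, n_samples=80, seed=0)
        d = build_order_dag(pairs, pairs.equal_groups(branch.reaction_ids))
        roots = d.roots()
        assert len(roots) == 1 and "uptake" in roots[0]

    def test_cycle_raises_with_offending_nodes(self):
        s = OrderedPairSet(ordered={("a", "b"), ("b", "c"), ("c", "a")})
        with pytest.raises(CyclicOrderError):
            build_order_dag(s)

    def test_transitive_reduction_is_idempotent(self, paperlike):
        pairs = find_flux_ordered_pairs(paperlike, n_samples=80, seed=0)
        d = build_order_dag(pairs, pairs.equal_groups(paperlike.reaction_ids))
        again = nx.transitive_reduction(d.graph)
        assert set(again.edges) == set(d.graph.edges)


class TestAssignLevels:
    def test_path_levels_increase_by_one(self):
        d = dag_from([("a", "b"), ("b", "c"), ("a", "c")])
        levels = {min(n): l for n, l in d.levels.items()}
        assert levels == {"a": 0, "b": 1, "c": 2}

    def test_diamond_longest_shortest_path(self):
        # a->b->d, a->c->e->d plus a second root f->d: the level of d is the
        # longest of the shortest root paths: via a it is 2, via f it is 1
        ordered = {("a", "b"), ("b", "d"), ("a", "c"), ("c", "e"), ("e", "d"),
                   ("a", "d"), ("a", "e"), ("b", "?"),  # placeholder removed
                   ("c", "d"), ("f", "d")}
        ordered.discard(("b", "?"))
        d = dag_from(ordered)
        levels = {min(n): l for n, l in d.levels.items()}
        assert levels["a"] == 0 and levels["f"] == 0
        assert levels["d"] == 2

    def test_isolated_node_is_its_own_root_at_level_zero(self):
        s = OrderedPairSet(ordered={("a", "b")})
        d = build_order_dag(s, [frozenset(("a",)), frozenset(("b",)),
                                frozenset(("lonely",))])
        assert d.levels[frozenset(("lonely",))] == 0

    def test_level_histogram_covers_all_nodes(self, growth):
        pairs = find_flux_ordered_pairs(growth, n_samples=80, seed=0)
        d = build_order_dag(pairs, pairs.equal_groups(growth.reaction_ids))
        hist = d.level_histogram()
        assert hist["n_nodes"].sum() == len(d.nodes)
        roots = set(d.roots())
        level0 = {n for n, l in d.levels.items() if l == 0}
        assert roots == level0

    def test_partition_first_middle_last(self):
        d = dag_from([("a", "b"), ("b", "c"), ("a", "c"),
                      ("c", "d"), ("a", "d"), ("b", "d")])
        p = level_partition(d)
        names = {"first": {min(n) for n in p.first},
                 "middle": {min(n) for n in p.middle},
                 "last": {min(n) for n in p.last}}
        assert names == {"first": {"a"}, "middle": {"b"},
                         "last": {"c", "d"}}


class TestConditionOverlap:
    def test_identical_sets_have_zero_jaccard_distance(self):
        a = OrderedPairSet(ordered={("x", "y"), ("y", "z"), ("x", "z")},
                           condition="c1")
        b = OrderedPairSet(ordered=set(a.ordered), condition="c2")
        out = condition_overlap([a, b])
        assert out["jaccard_distance"][("c1", "c2")] == 0.0
        assert out["n_shared"] == 3

    def test_disjoint_sets_have_distance_one(self):
        a = OrderedPairSet(ordered={("x", "y")}, condition="c1")
        b = OrderedPairSet(ordered={("p", "q")}, condition="c2")
        assert condition_overlap([a, b])["jaccard_distance"][("c1", "c2")] == 1.0

    def test_partial_overlap_formula(self):
        a = OrderedPairSet(ordered={("1", "2"), ("3", "4"), ("5", "6")},
                           condition="A")
        b = OrderedPairSet(ordered={("1", "2"), ("7", "8")}, condition="B")
        out = condition_overlap([a, b])
        assert out["jaccard_distance"][("A", "B")] == pytest.approx(0.75)
        assert out["exclusive"]["A"]["count"] == 2
        assert out["exclusive"]["B"]["fraction"] == pytest.approx(0.5)


class TestBiomassAncestors:
    def test_biomass_as_root_has_no_ancestors(self):
        s = OrderedPairSet(ordered={("biomass", "down")})
        d = build_order_dag(s)
        sub = biomass_ancestor_subgraph(d, "biomass")
        assert sub.nodes == []

    def test_chain_above_biomass(self):
        s = OrderedPairSet(ordered={("uptake", "biomass")})
        d = build_order_dag(s)
        sub = biomass_ancestor_subgraph(d, "biomass")
        assert {min(n) for n in sub.nodes} == {"uptake"}

    def test_matches_difference_lp_oracle_on_growth(self, growth_medium):
        model, _ = growth_medium
        pairs = find_flux_ordered_pairs(model, n_samples=100, seed=1)
        d = build_order_dag(pairs, pairs.equal_groups(model.reaction_ids))
        sub = biomass_ancestor_subgraph(d, "biomass", exclude={"atpm"})
        got = sub.reactions()
        # oracle: reactions with min(v_r - v_biomass) >= 0 and some slack > 0
        jb = model.index("biomass")
        want = set()
        for j, rid in enumerate(model.reaction_ids):
            if rid in ("biomass", "atpm"):
                continue
            c = np.zeros(model.n_reactions)
            c[j], c[jb] = 1.0, -1.0
            lo = linprog(c, A_eq=model.S, b_eq=np.zeros(model.n_metabolites),
                         bounds=list(zip(model.lower_bounds,
                                         model.upper_bounds)),
                         method="highs")
            hi = linprog(-c, A_eq=model.S, b_eq=np.zeros(model.n_metabolites),
                         bounds=list(zip(model.lower_bounds,
                                         model.upper_bounds)),
                         method="highs")
            if lo.fun >= -1e-6 and -hi.fun > 1e-6:
                want.add(rid)
        assert got == want

    def test_missing_biomass_raises(self):
        d = dag_from([("a", "b")])
        with pytest.raises(KeyError):
            biomass_ancestor_subgraph(d, "nope")

    def test_excluded_reaction_removed(self, growth_medium):
        model, _ = growth_medium
        pairs = find_flux_ordered_pairs(model, n_samples=100, seed=1)
        d = build_order_dag(pairs, pairs.equal_groups(model.reaction_ids))
        sub = biomass_ancestor_subgraph(d, "biomass", exclude={"atpm"})
        assert "atpm" not in sub.reactions()


class TestEssentiality:
    def test_matches_single_knockout_oracle(self, growth_medium):
        model, _ = growth_medium
        got = find_essential_reactions(model)
        jb = model.index("biomass")
        want = set()
        for j, rid in enumerate(model.reaction_ids):
            lb = model.lower_bounds.copy()
            ub = model.upper_bounds.copy()
            lb[j] = ub[j] = 0.0
            lb[jb] = 0.0  # essentiality asks about growth at all
            c = np.zeros(model.n_reactions)
            c[jb] = -1.0
            res = linprog(c, A_eq=model.S,
                          b_eq=np.zeros(model.n_metabolites),
                          bounds=list(zip(lb, ub)), method="highs")
            if res.status != 0 or -res.fun < 1e-6:
                want.add(rid)
        assert got == want

    def test_sole_uptake_essential_redundant_route_not(self, growth):
        ess = find_essential_reactions(growth)
        assert "glc_uptake" in ess and "prec1" in ess
        assert "prec2a" not in ess and "prec2b" not in ess

    def test_ancestors_subset_of_essential(self, growth_medium):
        model, _ = growth_medium
        pairs = find_flux_ordered_pairs(model, n_samples=100, seed=2)
        d = build_order_dag(pairs, pairs.equal_groups(model.reaction_ids))
        sub = biomass_ancestor_subgraph(d, "biomass", exclude={"atpm"})
        report = essentiality_order_report(find_essential_reactions(model),
                                           sub)
        assert report["violations"] == []

    def test_empty_dag_report(self):
        empty = OrderDAG(graph=nx.DiGraph())
        report = essentiality_order_report({"a", "b"}, empty)
        assert report["n_ordered_and_essential"] == 0
        assert report["n_essential_not_ordered"] == 2
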