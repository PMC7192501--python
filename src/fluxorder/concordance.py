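"""Agreement between the flux order relation and omics/kinetic data.

A data table (transcript, protein, flux, k_cat or enzyme cost values) is
mapped onto reactions through the Gene-Protein-Reaction rules: every gene
appearing anywhere in a reaction's rule contributes all its values, across
replicates, to that reaction's multiset D_i.  For each flux-ordered pair
(r_i, r_j) with data on both sides, the statistic

    delta_ij = (1 / nm) sum_p sum_q (d_ip - d_jq) = mean(D_i) - mean(D_j)

measures whether the data follow the predicted order; f_>0 = Pr(delta_ij > 0)
over all covered ordered pairs is the agreement score (the strictly positive
fraction, so pairs sharing an identical value set do not inflate it).
Significance comes from a permutation null that reassigns values at the
profile's granularity (per gene for transcript/protein data, per reaction for
flux and k_cat), recomputing f_>0 each round; the empirical p-value is
(r + 1) / (n + 1) with r the number of permuted scores >= the observed one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model_io import MetabolicModel
from .order_dag import LevelPartition, OrderDAG
from .order_finder import OrderedPairSet

__all__ = ["ReactionDataProfile", "ConcordanceResult", "DataMappingError",
           "map_data_to_reactions", "reaction_profile_from_table",
           "mean_difference", "concordance", "cost_percentile_subset",
           "regulatory_level_analysis"]


class DataMappingError(ValueError):
    """Gene/reaction identifiers in the data table do not match the model."""


def _genes_of_rule(rule: str) -> frozenset:
    """Set of gene ids appearing in a boolean GPR rule (duplicates once)."""
    if not rule or not rule.strip():
        return frozenset()
    from cobra.core.gene import GPR

    return frozenset(GPR.from_string(rule).genes)


@dataclass
class ReactionDataProfile:
    """reaction id -> multiset of data values, with provenance for permutation.

    ``granularity`` decides how the permutation null reassigns values:
    ``"gene"`` profiles keep the gene -> reaction structure and permute gene
    values; ``"reaction"`` profiles permute reaction values directly.
    """

    values: dict = field(default_factory=dict)      # rid -> list[float]
    data_type: str = ""
    granularity: str = "reaction"                   # "gene" | "reaction"
    gene_values: dict = field(default_factory=dict)  # gene -> list[float]
    reaction_genes: dict = field(default_factory=dict)  # rid -> frozenset

    def __post_init__(self) -> None:
        if self.granularity not in ("gene", "reaction"):
            raise ValueError("granularity must be 'gene' or 'reaction'")
        for rid, vals in self.values.items():
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0:
                raise ValueError(f"empty data multiset for reaction {rid!r}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite data value for reaction {rid!r}")

    def mean(self, rid: str) -> float:
        return float(np.mean(self.values[rid]))

    def covered(self) -> set[str]:
        return set(self.values)


def map_data_to_reactions(model: MetabolicModel,
                          gene_table: dict | pd.DataFrame,
                          data_type: str = "") -> ReactionDataProfile:
    """Pool gene-level values onto reactions through the GPR rules.

    ``gene_table`` is either a mapping gene -> list of values or a DataFrame
    with ``gene_id`` and ``value`` columns (replicate/condition columns are
    ignored: all rows of a gene are pooled).  Every gene appearing anywhere in
    a reaction's GPR contributes all its values once (a gene duplicated inside
    a rule still counts once); reactions with no covered gene are absent.
    """
    if isinstance(gene_table, pd.DataFrame):
        if not {"gene_id", "value"} <= set(gene_table.columns):
            raise DataMappingError(
                "gene table needs 'gene_id' and 'value' columns; got "
                f"{list(gene_table.columns)}")
        gmap: dict = {}
        for gid, grp in gene_table.groupby("gene_id"):
            gmap[str(gid)] = [float(v) for v in grp["value"]]
    else:
        gmap = {str(g): [float(v) for v in vs] for g, vs in gene_table.items()}

    model_genes: set[str] = set()
    rxn_genes: dict[str, frozenset] = {}
    for rid, rule in zip(model.reaction_ids, model.gpr):
        genes = _genes_of_rule(rule)
        rxn_genes[rid] = genes
        model_genes |= genes
    covered_genes = model_genes & set(gmap)
    if model_genes and gmap and not covered_genes:
        example_model = sorted(model_genes)[:3]
        example_data = sorted(gmap)[:3]
        raise DataMappingError(
            "no gene id in the data table matches the model's GPR genes "
            f"(model ids look like {example_model}, data ids like "
            f"{example_data})")

    values: dict[str, list] = {}
    used_genes: dict[str, list] = {}
    for rid, genes in rxn_genes.items():
        pooled: list[float] = []
        for g in sorted(genes):
            if g in gmap:
                pooled.extend(gmap[g])
        if pooled:
            values[rid] = pooled
    for g in sorted(covered_genes):
        used_genes[g] = gmap[g]
    return ReactionDataProfile(values=values, data_type=data_type,
                               granularity="gene", gene_values=used_genes,
                               reaction_genes=rxn_genes)


def reaction_profile_from_table(table: dict | pd.DataFrame,
                                data_type: str = "") -> ReactionDataProfile:
    """Profile from reaction-level data (flux, k_cat, mean enzyme cost)."""
    if isinstance(table, pd.DataFrame):
        if not {"reaction_id", "value"} <= set(table.columns):
            raise DataMappingError(
                "reaction table needs 'reaction_id' and 'value' columns")
        values = {str(r): [float(v) for v in grp["value"]]
                  for r, grp in table.groupby("reaction_id")}
    else:
        values = {str(r): list(np.atleast_1d(np.asarray(v, dtype=float)))
                  for r, v in table.items()}
    return ReactionDataProfile(values=values, data_type=data_type,
                               granularity="reaction")


def mean_difference(D_i, D_j) -> float:
    """delta_ij: the double-sum average difference, i.e. mean(D_i) - mean(D_j)."""
    a = np.asarray(list(D_i), dtype=float)
    b = np.asarray(list(D_j), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mean_difference requires nonempty multisets")
    return float(a.mean() - b.mean())


@dataclass
class ConcordanceResult:
    """delta distribution, positive fraction and permutation p-value."""

    delta: list
    f_pos: float
    n_pairs: int
    p_value: float
    n_permutations: int
    seed: int | None = None
    data_type: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "data_type": self.data_type,
                "f_pos": self.f_pos,
                "n_pairs": self.n_pairs,
                "p_value": self.p_value,
                "n_permutations": self.n_permutations,
                "seed": self.seed,
                "delta": list(map(float, self.delta)),
            }, fh, indent=2)

    def delta_histogram(self, path, bins: int = 30) -> None:
        counts, edges = np.histogram(np.asarray(self.delta), bins=bins)
        pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                      "count": counts}).to_csv(path, sep="\t", index=False)


def _covered_pairs(orders: OrderedPairSet, values: dict) -> list[tuple]:
    return [(i, j) for (i, j) in sorted(orders.ordered)
            if i in values and j in values]


def _f_pos(pairs, values: dict) -> float:
    deltas = [np.mean(values[i]) - np.mean(values[j]) for i, j in pairs]
    return float(np.mean([d > 0 for d in deltas])) if deltas else float("nan")


def concordance(orders: OrderedPairSet, profile: ReactionDataProfile,
                n_perm: int = 10000, seed: int | None = None,
                with_replacement: bool = True) -> ConcordanceResult:
    """Concordance of a data profile with the flux order relation.

    The permutation null redraws values at the profile's granularity from the
    pool of all available values, preserving each gene's (or reaction's)
    multiset size, with replacement by default (``with_replacement=False``
    permutes the pooled values instead).
    """
    pairs = _covered_pairs(orders, profile.values)
    if not pairs:
        raise ValueError("no ordered pair has data on both sides")
    deltas = [mean_difference(profile.values[i], profile.values[j])
              for i, j in pairs]
    f_obs = float(np.mean([d > 0 for d in deltas]))

    rng = np.random.default_rng(seed)
    if profile.granularity == "gene":
        units = sorted(profile.gene_values)
        sizes = [len(profile.gene_values[u]) for u in units]
        pool = np.concatenate([profile.gene_values[u] for u in units])
        rxn_units = {rid: sorted(set(profile.reaction_genes[rid]) & set(units))
                     for rid in {r for p in pairs for r in p}}
    else:
        units = sorted(profile.values)
        sizes = [len(profile.values[u]) for u in units]
        pool = np.concatenate([profile.values[u] for u in units])
        rxn_units = {rid: [rid] for rid in units}

    r_count = 0
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    for _ in range(n_perm):
        if with_replacement:
            drawn = rng.choice(pool, size=offsets[-1], replace=True)
        else:
            drawn = rng.permutation(pool)
        unit_vals = {u: drawn[offsets[k]:offsets[k + 1]]
                     for k, u in enumerate(units)}
        perm_values = {}
        for rid, us in rxn_units.items():
            if us:
                perm_values[rid] = np.concatenate([unit_vals[u] for u in us])
        perm_pairs = [(i, j) for i, j in pairs
                      if i in perm_values and j in perm_values]
        if not perm_pairs:
            continue
        if _f_pos(perm_pairs, perm_values) >= f_obs:
            r_count += 1
    p = (r_count + 1) / (n_perm + 1)
    return ConcordanceResult(delta=deltas, f_pos=f_obs, n_pairs=len(pairs),
                             p_value=p, n_permutations=n_perm, seed=seed,
                             data_type=profile.data_type)


def cost_percentile_subset(orders: OrderedPairSet,
                           costs: ReactionDataProfile,
                           percentile: float) -> OrderedPairSet:
    """Ordered pairs whose enzymes are at least as costly as a percentile.

    The threshold is the given percentile (linear interpolation, inclusive)
    of the distribution of all employed enzyme costs (the per-reaction mean
    costs in ``costs``); a pair survives iff BOTH reactions have a known cost
    >= the threshold.  Percentile 0 is the identity.
    """
    if not (0 <= percentile < 100):
        raise ValueError("percentile must lie in [0, 100)")
    out = OrderedPairSet(condition=orders.condition)
    out.equal = set(orders.equal)
    if percentile == 0:
        out.ordered = set(orders.ordered)
        return out
    if costs.granularity != "reaction":
        raise ValueError("costs must be at reaction granularity")
    mean_cost = {rid: float(np.mean(v)) for rid, v in costs.values.items()}
    threshold = float(np.percentile(list(mean_cost.values()), percentile))
    out.ordered = {
        (i, j) for (i, j) in orders.ordered
        if i in mean_cost and j in mean_cost
        and mean_cost[i] >= threshold and mean_cost[j] >= threshold
    }
    return out


def regulatory_level_analysis(dag: OrderDAG, partition: LevelPartition,
                              reg_counts: dict | pd.DataFrame,
                              model: MetabolicModel,
                              exact_max_n: int = 20) -> dict:
    """Do genes of upper-level reactions carry more regulatory interactions?

    ``reg_counts`` maps gene -> total number of regulatory interactions
    (activating + inhibitory).  Genes are attached to the first/middle/last
    node subsets through the GPR rules of each subset's reactions (a gene
    counts once per subset).  Returns the three per-subset count
    distributions and one-sided Mann-Whitney U p-values for first > middle,
    first > last and middle > last (exact U distribution when both samples
    are small and tie-free, normal approximation with tie correction
    otherwise).
    """
    import warnings

    if isinstance(reg_counts, pd.DataFrame):
        reg_counts = {str(g): float(c) for g, c in
                      zip(reg_counts["gene_id"], reg_counts["n_interactions"])}
    gene_of_rxn = {rid: _genes_of_rule(rule)
                   for rid, rule in zip(model.reaction_ids, model.gpr)}

    def subset_counts(nodes) -> np.ndarray:
        genes: set[str] = set()
        for node in nodes:
            for rid in node:
                genes |= gene_of_rxn.get(rid, frozenset())
        return np.array(sorted(reg_counts[g] for g in genes
                               if g in reg_counts), dtype=float)

    dists = {"first": subset_counts(partition.first),
             "middle": subset_counts(partition.middle),
             "last": subset_counts(partition.last)}

    def one_sided(hi: np.ndarray, lo: np.ndarray, label: str):
        if hi.size == 0 or lo.size == 0:
            warnings.warn(f"empty subset in comparison {label}; skipped")
            return None
        small = max(hi.size, lo.size) <= exact_max_n
        tie_free = len(np.unique(np.concatenate([hi, lo]))) == hi.size + lo.size
        method = "exact" if (small and tie_free) else "asymptotic"
        res = stats.mannwhitneyu(hi, lo, alternative="greater", method=method)
        return float(res.pvalue)

    pvals = {
        "first_vs_middle": one_sided(dists["first"], dists["middle"],
                                     "first vs middle"),
        "first_vs_last": one_sided(dists["first"], dists["last"],
                                   "first vs last"),
        "middle_vs_last": one_sided(dists["middle"], dists["last"],
                                    "middle vs last"),
    }
    return {"distributions": dists, "p_values": pvals}
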