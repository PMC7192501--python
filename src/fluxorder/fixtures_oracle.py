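"""Toy networks, a random-network generator and brute-force oracles.

The oracles decide order and coupling questions by means independent of the
Charnes-Cooper route used by the main path:

* difference-LP mode extremises v_i - v_j directly over the flux polytope
  (two LPs per pair, any model size);
* vertex mode enumerates the vertices of {v : Sv = 0, lb <= v <= ub} by
  brute force over active bound sets (a linear objective attains its extrema
  at vertices, so decisions over vertices are exact) — small models only.

The named fixtures provide known order/coupling structure: ``chain`` is fully
coupled throughout, ``branch`` realises the canonical uptake-above-branches
situation, ``diamond`` adds reconvergent routes, ``growth`` has a biomass
pseudo-reaction with one unique and one redundant precursor route, and
``paperlike`` is a 9-reaction, 5-metabolite network structurally analogous to
the kind of toy network used to illustrate the flux order relation (synthetic;
not a transcription of any published figure, whose stoichiometry is depicted
only graphically).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model_io import MetabolicModel

__all__ = ["FixtureSpec", "VertexEnumerationError", "make_fixture",
           "chain_fixture", "branch_fixture", "diamond_fixture",
           "growth_fixture", "paperlike_fixture", "random_fixture",
           "enumerate_vertices", "oracle_order", "oracle_coupling",
           "oracle_ordered_pair_set", "synthetic_omics", "SyntheticOmics"]

ORACLE_TOL = 1e-6


class VertexEnumerationError(RuntimeError):
    """Too many candidate active sets; use the difference-LP mode instead."""


@dataclass(frozen=True)
class FixtureSpec:
    """Named construction recipe for a deterministic toy model."""

    name: str
    params: tuple = ()

    def build(self) -> MetabolicModel:
        return make_fixture(self)


def _model(met_ids, reactions, biomass_id=None, atpm_id=None):
    """reactions: list of (id, {met: coeff}, lb, ub[, gpr])."""
    met_pos = {m: k for k, m in enumerate(met_ids)}
    rows, cols, data = [], [], []
    rids, lbs, ubs, gprs = [], [], [], []
    for j, rxn in enumerate(reactions):
        rid, stoich, lb, ub = rxn[:4]
        gpr = rxn[4] if len(rxn) > 4 else ""
        rids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        gprs.append(gpr)
        for met, coeff in stoich.items():
            rows.append(met_pos[met])
            cols.append(j)
            data.append(float(coeff))
    S = sp.csc_matrix((data, (rows, cols)), shape=(len(met_ids), len(rids)))
    return MetabolicModel(metabolite_ids=list(met_ids), reaction_ids=rids,
                          S=S, lower_bounds=np.array(lbs),
                          upper_bounds=np.array(ubs), gpr=gprs,
                          biomass_id=biomass_id, atpm_id=atpm_id)


def chain_fixture(length: int = 3, uptake_ub: float = 10.0) -> MetabolicModel:
    """Linear pathway: uptake -> M1 -> ... -> export; all pairs fully coupled."""
    if length < 2:
        raise ValueError("chain needs at least 2 reactions")
    mets = [f"M{k}" for k in range(1, length)]
    rxns = [("R1", {"M1": 1.0}, 0.0, uptake_ub)]
    for k in range(2, length):
        rxns.append((f"R{k}", {f"M{k-1}": -1.0, f"M{k}": 1.0}, 0.0, uptake_ub))
    rxns.append((f"R{length}", {f"M{length-1}": -1.0}, 0.0, uptake_ub))
    return _model(mets, rxns)


def branch_fixture(uptake_ub: float = 10.0) -> MetabolicModel:
    """Uptake feeding two independent export branches.

    The uptake is flux-ordered above each branch (its flux is their sum);
    each branch's conversion and export are fully coupled with ratio 1.
    """
    mets = ["A", "B", "C"]
    rxns = [
        ("uptake", {"A": 1.0}, 0.0, uptake_ub),
        ("branch1", {"A": -1.0, "B": 1.0}, 0.0, uptake_ub),
        ("export1", {"B": -1.0}, 0.0, uptake_ub),
        ("branch2", {"A": -1.0, "C": 1.0}, 0.0, uptake_ub),
        ("export2", {"C": -1.0}, 0.0, uptake_ub),
    ]
    return _model(mets, rxns)


def diamond_fixture(uptake_ub: float = 10.0) -> MetabolicModel:
    """Two parallel routes that reconverge before export."""
    mets = ["A", "B", "C", "D"]
    rxns = [
        ("uptake", {"A": 1.0}, 0.0, uptake_ub),
        ("rab", {"A": -1.0, "B": 1.0}, 0.0, uptake_ub),
        ("rac", {"A": -1.0, "C": 1.0}, 0.0, uptake_ub),
        ("rbd", {"B": -1.0, "D": 1.0}, 0.0, uptake_ub),
        ("rcd", {"C": -1.0, "D": 1.0}, 0.0, uptake_ub),
        ("export", {"D": -1.0}, 0.0, uptake_ub),
    ]
    return _model(mets, rxns)


def growth_fixture(uptake_ub: float = 10.0,
                   with_atpm: bool = True) -> MetabolicModel:
    """Biomass-producing network with one unique and one redundant route.

    Biomass consumes two precursors: P1 comes only through ``prec1``
    (essential; fully coupled to biomass with ratio 2), P2 through either of
    two redundant reactions (individually dispensable).  An ATP-maintenance
    style drain on the carbon pool is included by default.
    """
    mets = ["A", "P1", "P2"]
    rxns = [
        ("glc_uptake", {"A": 1.0}, 0.0, uptake_ub, "g_upt"),
        ("prec1", {"A": -1.0, "P1": 1.0}, 0.0, 3 * uptake_ub, "g_p1"),
        ("prec2a", {"A": -1.0, "P2": 1.0}, 0.0, 3 * uptake_ub,
         "g_p2a or g_p2s"),
        ("prec2b", {"A": -1.0, "P2": 1.0}, 0.0, 3 * uptake_ub,
         "g_p2b or g_p2s"),
        ("biomass", {"P1": -2.0, "P2": -1.0}, 0.0, 3 * uptake_ub, ""),
    ]
    if with_atpm:
        rxns.append(("atpm", {"A": -1.0}, 0.0, uptake_ub, ""))
    return _model(mets, rxns, biomass_id="biomass",
                  atpm_id="atpm" if with_atpm else None)


def paperlike_fixture(uptake_ub: float = 10.0) -> MetabolicModel:
    """9-reaction, 5-metabolite network mixing ordered and unordered pairs.

    Two uptakes converge on a shared pool C that splits into two export
    routes, one of which can also be fed laterally; synthetic analogue of the
    toy networks used to illustrate flux ordering.
    """
    mets = ["A", "B", "C", "D", "F"]
    rxns = [
        ("E1", {"A": 1.0}, 0.0, uptake_ub),
        ("E2", {"B": 1.0}, 0.0, uptake_ub),
        ("R1", {"A": -1.0, "C": 1.0}, 0.0, uptake_ub),
        ("R2", {"B": -1.0, "C": 1.0}, 0.0, uptake_ub),
        ("R3", {"C": -1.0, "D": 1.0}, 0.0, 2 * uptake_ub),
        ("R4", {"C": -1.0, "F": 1.0}, 0.0, 2 * uptake_ub),
        ("R5", {"D": -1.0, "F": 1.0}, 0.0, 2 * uptake_ub),
        ("E3", {"D": -1.0}, 0.0, 2 * uptake_ub),
        ("E4", {"F": -1.0}, 0.0, 2 * uptake_ub),
    ]
    return _model(mets, rxns)


def random_fixture(n_metabolites: int = 8, n_reactions: int = 12,
                   seed: int = 0, ub: float = 10.0) -> MetabolicModel:
    """Random sparse irreversible network with imports and exports.

    Deterministic for a fixed seed.  Internal reactions consume one or two
    metabolites and produce one or two others with coefficients in {1, 2};
    two imports and two exports anchor the network to the environment.  Many
    random columns end up blocked; canonicalisation prunes them.
    """
    rng = np.random.default_rng(seed)
    mets = [f"m{k}" for k in range(n_metabolites)]
    n_internal = max(n_reactions - 4, 0)
    rxns = []
    # layered flow: internal conversions go from lower to higher metabolite
    # index, imports feed the bottom, exports drain the top, so a substantial
    # part of the network can carry steady-state flux
    for j in range(n_internal):
        if j == 0:  # backbone guaranteeing a live import-to-export route
            rxns.append(("r0", {mets[0]: -1.0, mets[-1]: 1.0}, 0.0, ub))
            continue
        i_sub = int(rng.integers(0, n_metabolites - 1))
        i_prod = int(rng.integers(i_sub + 1, n_metabolites))
        a = float(rng.integers(1, 3))
        b = float(rng.integers(1, 3))
        stoich = {mets[i_sub]: -a, mets[i_prod]: b}
        if rng.random() < 0.25 and i_prod - i_sub > 1:
            mid = int(rng.integers(i_sub + 1, i_prod))
            stoich[mets[mid]] = stoich.get(mets[mid], 0.0) + float(
                rng.choice([-1.0, 1.0]))
            stoich = {m: c for m, c in stoich.items() if c != 0.0}
        rxns.append((f"r{j}", stoich, 0.0, ub))
    for k in range(min(2, n_metabolites)):
        rxns.append((f"imp{k}", {mets[k]: 1.0}, 0.0, ub))
    for k in range(min(2, n_metabolites)):
        rxns.append((f"exp{k}", {mets[n_metabolites - 1 - k]: -1.0}, 0.0, ub))
    return _model(mets, rxns[:n_reactions])


_BUILDERS = {
    "chain": chain_fixture,
    "branch": branch_fixture,
    "diamond": diamond_fixture,
    "growth": growth_fixture,
    "paperlike": paperlike_fixture,
    "random": random_fixture,
}


def make_fixture(spec: FixtureSpec) -> MetabolicModel:
    if spec.name not in _BUILDERS:
        raise ValueError(f"unknown fixture {spec.name!r}; "
                         f"choose from {sorted(_BUILDERS)}")
    model = _BUILDERS[spec.name](*spec.params)
    if model.n_reactions == 0:
        raise ValueError("degenerate fixture with zero reactions")
    return model


# ----------------------------------------------------------------------------
# Vertex enumeration
# ----------------------------------------------------------------------------

def enumerate_vertices(model: MetabolicModel, tol: float = 1e-9,
                       max_systems: int = 500_000) -> np.ndarray:
    """All vertices of {v : Sv = 0, lb <= v <= ub} by active-set enumeration.

    At a vertex, at least n - rank(S) variables sit at a bound; every choice
    of that many variables and bound sides gives a candidate linear system.
    Requires finite bounds; intended for models with <= ~20 reactions.
    """
    S = model.S.toarray()
    n = model.n_reactions
    lb, ub = model.lower_bounds, model.upper_bounds
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise VertexEnumerationError("vertex enumeration needs finite bounds")
    rank = np.linalg.matrix_rank(S) if S.size else 0
    d = n - rank
    from math import comb

    n_systems = comb(n, d) * 2 ** d
    if n_systems > max_systems:
        raise VertexEnumerationError(
            f"{n_systems} candidate active sets (n={n}, corank={d}); "
            "use the difference-LP oracle instead")
    verts = []
    for fixed_t in combinations(range(n), d):
        fixed = list(fixed_t)
        free = [k for k in range(n) if k not in fixed_t]
        S_free = S[:, free]
        if free and np.linalg.matrix_rank(S_free) < len(free):
            continue  # active set does not determine a unique point
        for sides in product((0, 1), repeat=d):
            v = np.empty(n)
            for k, side in zip(fixed, sides):
                v[k] = ub[k] if side else lb[k]
            if free:
                rhs = -S[:, fixed] @ v[fixed] if fixed else np.zeros(S.shape[0])
                sol, res, _, _ = np.linalg.lstsq(S_free, rhs, rcond=None)
                v[free] = sol
                if np.max(np.abs(S @ v)) > 1e-7:
                    continue
            else:
                if np.max(np.abs(S @ v)) > 1e-7:
                    continue
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                verts.append(np.clip(v, lb, ub))
    if not verts:
        return np.empty((0, n))
    V = np.array(verts)
    V = np.unique(np.round(V, 7), axis=0)
    return V


# ----------------------------------------------------------------------------
# Oracles
# ----------------------------------------------------------------------------

def _diff_extrema(model: MetabolicModel, i: str, j: str) -> tuple[float, float]:
    """min and max of v_i - v_j over the flux polytope (two LPs)."""
    n = model.n_reactions
    c = np.zeros(n)
    c[model.index(i)] = 1.0
    c[model.index(j)] = -1.0
    bounds = list(zip(model.lower_bounds, model.upper_bounds))
    lo = linprog(c, A_eq=model.S, b_eq=np.zeros(model.n_metabolites),
                 bounds=bounds, method="highs")
    hi = linprog(-c, A_eq=model.S, b_eq=np.zeros(model.n_metabolites),
                 bounds=bounds, method="highs")
    if lo.status != 0 or hi.status != 0:
        raise RuntimeError("difference-LP oracle failed "
                           f"(statuses {lo.status}, {hi.status})")
    return float(lo.fun), float(-hi.fun)


def oracle_order(model: MetabolicModel, i: str, j: str,
                 mode: str = "diff_lp", tol: float = ORACLE_TOL,
                 vertices: np.ndarray | None = None) -> str:
    """Independent order decision: ``ordered``, ``equal`` or ``unordered``.

    ordered iff min(v_i - v_j) >= -tol over the polytope and
    max(v_i - v_j) > tol; equal iff both extrema lie within +/- tol.
    """
    if mode == "diff_lp":
        lo, hi = _diff_extrema(model, i, j)
    elif mode == "vertex":
        V = enumerate_vertices(model) if vertices is None else vertices
        diffs = V[:, model.index(i)] - V[:, model.index(j)]
        lo, hi = float(diffs.min()), float(diffs.max())
    else:
        raise ValueError(f"unknown oracle mode {mode!r}")
    if abs(lo) <= tol and abs(hi) <= tol:
        return "equal"
    if lo >= -tol and hi > tol:
        return "ordered"
    return "unordered"


def oracle_ordered_pair_set(model: MetabolicModel, mode: str = "diff_lp",
                            tol: float = ORACLE_TOL):
    """Brute-force flux order relation over all n(n-1) pairs."""
    from .order_finder import OrderedPairSet

    out = OrderedPairSet(condition=f"oracle-{mode}")
    V = enumerate_vertices(model) if mode == "vertex" else None
    ids = model.reaction_ids
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            verdict = oracle_order(model, ids[a], ids[b], mode=mode, tol=tol,
                                   vertices=V)
            if verdict == "ordered":
                out.ordered.add((ids[a], ids[b]))
            elif verdict == "equal":
                out.equal.add(frozenset((ids[a], ids[b])))
            else:
                reverse = oracle_order(model, ids[b], ids[a], mode=mode,
                                       tol=tol, vertices=V)
                if reverse == "ordered":
                    out.ordered.add((ids[b], ids[a]))
    return out


def oracle_coupling(model: MetabolicModel, i: str, j: str,
                    tol: float = ORACLE_TOL,
                    vertices: np.ndarray | None = None) -> str:
    """Coupling class from polytope vertices.

    Activity implications are read off vertices (a feasible point with
    v_i > 0, v_j = 0 exists iff such a vertex exists, since the face
    {v_j = 0} is itself a polytope whose vertices are polytope vertices);
    full vs partial is decided by ratio constancy over vertices with
    v_j > 0, which by convexity extends to the whole polytope.
    """
    V = enumerate_vertices(model) if vertices is None else vertices
    vi = V[:, model.index(i)]
    vj = V[:, model.index(j)]
    i_only = bool(np.any((vi > tol) & (vj <= tol)))
    j_only = bool(np.any((vj > tol) & (vi <= tol)))
    if i_only and j_only:
        return "uncoupled"
    if i_only:
        return "directional_ij"   # i leads: v_j > 0 forces v_i > 0
    if j_only:
        return "directional_ji"   # j leads
    mask = vj > tol
    if not np.any(mask):
        return "undetermined"     # both always inactive: blocked upstream
    ratios = vi[mask] / vj[mask]
    if ratios.max() - ratios.min() <= tol * max(1.0, ratios.max()):
        return "full"
    return "partial"


# ----------------------------------------------------------------------------
# Synthetic omics generator
# ----------------------------------------------------------------------------

@dataclass
class SyntheticOmics:
    """Synthetic gene-level data tables tied to a sampled flux truth."""

    gene_table: "object"            # pandas DataFrame
    model: MetabolicModel           # model with (possibly assigned) GPRs
    truth: dict = field(default_factory=dict)  # rid -> true flux value


def synthetic_omics(model: MetabolicModel, orders, noise_sd: float,
                    seed: int | None = None,
                    n_replicates: int = 3) -> SyntheticOmics:
    """Gene data tables whose underlying truth is one steady-state flux vector.

    Reactions without a GPR get a synthetic single-gene rule ``g_<rid>``.
    Each gene's replicate values are the true flux of its reaction plus
    Gaussian noise of standard deviation ``noise_sd``; with zero noise every
    ordered pair with strictly different true fluxes is concordant by
    construction.
    """
    import pandas as pd

    from .order_finder import sample_flux_space

    rng = np.random.default_rng(seed)
    m = model.copy()
    m.gpr = [g if g.strip() else f"g_{rid}"
             for rid, g in zip(m.reaction_ids, m.gpr)]
    sample = sample_flux_space(m, 1, seed=None if seed is None else seed + 1)
    truth = dict(zip(m.reaction_ids, sample.matrix[0]))

    rows = []
    seen_genes = set()
    for rid, rule in zip(m.reaction_ids, m.gpr):
        from cobra.core.gene import GPR

        for gene in sorted(GPR.from_string(rule).genes):
            if gene in seen_genes:
                continue
            seen_genes.add(gene)
            for rep in range(n_replicates):
                rows.append({
                    "gene_id": gene,
                    "condition": "synthetic",
                    "replicate": rep,
                    "value": truth[rid] + rng.normal(0.0, noise_sd)
                    if noise_sd > 0 else truth[rid],
                })
    table = pd.DataFrame(rows,
                         columns=["gene_id", "condition", "replicate",
                                  "value"])
    return SyntheticOmics(gene_table=table, model=m, truth=truth)
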