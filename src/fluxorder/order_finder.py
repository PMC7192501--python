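"""Two-stage identification of flux-ordered reaction pairs.

Deciding v_i >= v_j for every steady state needs two LPs per pair, n(n-1) in
total.  A sampling prefilter cuts that down: steady-state flux vectors are
drawn from the polytope, and any directed pair violated in the sample carries
an explicit counterexample and is provably unordered.  Fully coupled pairs are
resolved directly from their constant ratio alpha without LPs (ordered iff
alpha > 1 for the orientation with the larger flux; always-equal iff
alpha = 1).  The surviving candidates are verified exactly with the
Charnes-Cooper ratio programs, so the final result is independent of the
sample and of the sampler seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from . import lp_core
from .coupling import CouplingTable
from .model_io import MediumConfig, MetabolicModel

__all__ = ["FluxSample", "OrderedPairSet", "sample_flux_space",
           "candidate_pairs", "remove_fully_coupled",
           "find_flux_ordered_pairs"]

logger = logging.getLogger("fluxorder")

#: Absolute tolerance on sampled flux differences for the prefilter.
SAMPLE_TOL = 1e-6


@dataclass
class FluxSample:
    """Steady-state flux vectors: rows = samples, columns = model reactions."""

    matrix: np.ndarray
    reaction_ids: list[str]
    sampler: str = "hit-and-run"
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]


@dataclass
class OrderedPairSet:
    """The flux order relation over a model's reactions.

    ``ordered`` holds directed pairs (i, j) with v_i >= v_j in every steady
    state and v_i > v_j in at least one; ``equal`` holds unordered pairs whose
    fluxes are identical in every steady state (fully coupled, ratio 1),
    which the DAG stage collapses into single nodes.  ``undetermined`` holds
    pairs on which the LP solver failed in both attempts.
    """

    ordered: set = field(default_factory=set)
    equal: set = field(default_factory=set)       # frozensets {i, j}
    undetermined: set = field(default_factory=set)
    condition: str = ""

    def __len__(self) -> int:
        return len(self.ordered)

    def equal_groups(self, reaction_ids=None) -> list[frozenset]:
        """Partition of reactions into always-equal-flux groups (union-find).

        When ``reaction_ids`` is given, every listed reaction appears in the
        partition, singletons included.
        """
        parent: dict = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

        for pair in self.equal:
            a, b = tuple(pair)
            union(a, b)
        if reaction_ids is not None:
            for r in reaction_ids:
                find(r)
        groups: dict = {}
        for x in parent:
            groups.setdefault(find(x), set()).add(x)
        return [frozenset(g) for g in groups.values()]

    def check_partial_order(self, strict: bool = True) -> list[str]:
        """Verify antisymmetry, irreflexivity and transitivity.

        Returns a list of human-readable violations; raises when ``strict``
        and any are found (they would indicate numerical-tolerance defects).
        """
        problems = []
        for (i, j) in self.ordered:
            if i == j:
                problems.append(f"reflexive pair ({i}, {j})")
            if (j, i) in self.ordered:
                problems.append(f"antisymmetry violated for ({i}, {j})")
        succ: dict = {}
        for (i, j) in self.ordered:
            succ.setdefault(i, set()).add(j)
        for i, js in succ.items():
            for j in js:
                for k in succ.get(j, ()):  # i >= j >= k
                    if k != i and k not in js:
                        problems.append(
                            f"transitivity violated: ({i},{j}),({j},{k}) "
                            f"without ({i},{k})")
        if strict and problems:
            raise AssertionError("; ".join(problems))
        return problems

    def to_frame(self) -> pd.DataFrame:
        rows = [{"source_id": i, "target_id": j, "relation": "ordered"}
                for (i, j) in sorted(self.ordered)]
        rows += [{"source_id": a, "target_id": b, "relation": "equal"}
                 for a, b in sorted(tuple(sorted(p)) for p in self.equal)]
        return pd.DataFrame(rows, columns=["source_id", "target_id", "relation"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, condition: str = "") -> "OrderedPairSet":
        out = cls(condition=condition)
        for _, row in df.iterrows():
            if row["relation"] == "ordered":
                out.ordered.add((row["source_id"], row["target_id"]))
            elif row["relation"] == "equal":
                out.equal.add(frozenset((row["source_id"], row["target_id"])))
        return out

    @classmethod
    def from_tsv(cls, path, condition: str = "") -> "OrderedPairSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"), condition=condition)


# ----------------------------------------------------------------------------
# Sampling prefilter
# ----------------------------------------------------------------------------

def sample_flux_space(model: MetabolicModel, n_samples: int,
                      seed: int | None = None, burn_in: int = 100,
                      thin: int = 5) -> FluxSample:
    """Hit-and-run sample of the steady-state flux polytope.

    Directions are drawn in the null space of S, so every iterate satisfies
    Sv = 0 exactly; chord limits come from the flux bounds.  Deterministic
    for a fixed seed.  A zero-volume polytope (e.g. alpha_b = 1 pinning the
    space to a point) triggers a warning and the single feasible point is
    returned for every row.
    """
    rng = np.random.default_rng(seed)
    n = model.n_reactions
    lb, ub = model.lower_bounds, model.upper_bounds
    if n_samples == 0:
        return FluxSample(np.empty((0, n)), list(model.reaction_ids),
                          seed=seed)

    # interior starting point: maximise the smallest slack to either bound
    from scipy.optimize import linprog
    import scipy.sparse as sp
    width = ub - lb
    c = np.zeros(n + 1)
    c[-1] = -1.0
    # v - s >= lb, v + s <= ub for non-pinned coordinates
    free = width > 1e-12
    rows = []
    idx = np.flatnonzero(free)
    I = sp.eye(n, format="csc")[idx, :]
    ones = sp.csc_matrix(np.ones((len(idx), 1)))
    rows.append(sp.hstack([-I, ones], format="csc"))   # -v + s <= -lb
    rows.append(sp.hstack([I, ones], format="csc"))    # v + s <= ub
    A_ub = sp.vstack(rows, format="csc")
    b_ub = np.concatenate([-lb[idx], ub[idx]])
    A_eq = sp.hstack([model.S, sp.csc_matrix((model.n_metabolites, 1))],
                     format="csc")
    finite_w = width[np.isfinite(width)]
    s_cap = 0.5 * float(finite_w.max()) if finite_w.size else 1.0
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq,
                  b_eq=np.zeros(model.n_metabolites),
                  bounds=[(l, u) for l, u in zip(lb, ub)] + [(0.0, s_cap)],
                  method="highs")
    if res.status == 2:
        raise lp_core.InfeasibleLPError("flux space is empty; cannot sample")
    if res.status != 0:
        raise lp_core.LPError("could not find an interior point for sampling")
    v = res.x[:n]
    slack = res.x[-1]

    N = scipy.linalg.null_space(model.S.toarray())
    if N.shape[1] == 0 or slack <= 1e-10:
        warnings.warn("flux space has zero volume; returning the single "
                      "feasible point for every sample row")
        return FluxSample(np.tile(v, (n_samples, 1)), list(model.reaction_ids),
                          sampler="degenerate-point", seed=seed)

    out = np.empty((n_samples, n))
    kept = 0
    it = 0
    total_iters = burn_in + n_samples * thin
    while kept < n_samples:
        d = N @ rng.standard_normal(N.shape[1])
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            continue
        d /= norm
        t_lo, t_hi = -np.inf, np.inf
        mask = np.abs(d) > 1e-12
        dm, vm = d[mask], v[mask]
        hi = (ub[mask] - vm) / dm
        lo = (lb[mask] - vm) / dm
        t_hi = min(np.min(np.where(dm > 0, hi, np.inf)),
                   np.min(np.where(dm < 0, lo, np.inf)), t_hi)
        t_lo = max(np.max(np.where(dm > 0, lo, -np.inf)),
                   np.max(np.where(dm < 0, hi, -np.inf)), t_lo)
        if not np.isfinite(t_lo) or not np.isfinite(t_hi) or t_hi <= t_lo:
            it += 1
            if it > 50 * total_iters:
                warnings.warn("sampler made no progress; flux space appears "
                              "degenerate")
                out[kept:] = v
                break
            continue
        v = v + rng.uniform(t_lo, t_hi) * d
        np.clip(v, lb, ub, out=v)
        it += 1
        if it > burn_in and (it - burn_in) % thin == 0:
            out[kept] = v
            kept += 1
    return FluxSample(out, list(model.reaction_ids), seed=seed)


def candidate_pairs(sample: FluxSample, tol: float = SAMPLE_TOL) -> set:
    """Directed pairs (i, j) with v_i >= v_j - tol in every sampled row.

    A single sampled violation is an explicit counterexample, so eliminated
    pairs are provably unordered; an empty sample vacuously returns all
    directed pairs.
    """
    ids = sample.reaction_ids
    n = len(ids)
    if sample.n_samples == 0:
        return {(ids[a], ids[b]) for a in range(n) for b in range(n) if a != b}
    M = sample.matrix
    keep = set()
    for a in range(n):
        diff = M[:, a][:, None] - M  # diff[s, b] = v_a - v_b in row s
        ok = np.all(diff >= -tol, axis=0)
        for b in np.flatnonzero(ok):
            if b != a:
                keep.add((ids[a], ids[b]))
    return keep


def remove_fully_coupled(cands: set, coupling: CouplingTable,
                         eps: float = lp_core.EPS_RATIO
                         ) -> tuple[set, OrderedPairSet]:
    """Resolve candidates that are fully coupled without solving LPs.

    A fully coupled pair has v_i = alpha v_j in every steady state, so its
    order status follows from alpha alone: ordered (i, j) iff alpha > 1,
    ordered (j, i) iff alpha < 1, always-equal iff alpha = 1.  Returns the
    remaining candidates and the directly resolved relations.
    """
    resolved = OrderedPairSet()
    remaining = set()
    handled = set()
    for (i, j) in cands:
        entry = coupling.get(i, j)
        if entry is None or entry.klass != "full":
            remaining.add((i, j))
            continue
        key = frozenset((i, j))
        if key in handled:
            continue
        handled.add(key)
        # entry.alpha is the ratio v_{entry.i} / v_{entry.j}
        alpha = entry.alpha
        if abs(alpha - 1.0) <= eps:
            resolved.equal.add(key)
        elif alpha > 1.0:
            resolved.ordered.add((entry.i, entry.j))
        else:
            resolved.ordered.add((entry.j, entry.i))
    return remaining, resolved


def _verify_pair(model: MetabolicModel, i: str, j: str, eps: float) -> str:
    """LP verification with one retry on an alternative backend."""
    try:
        bounds = lp_core.flux_ratio_bounds(model, i, j)
        return lp_core.is_ordered(bounds, eps=eps)
    except lp_core.RatioUndefinedError:
        logger.warning("ratio undefined for (%s, %s); classified unordered",
                       i, j)
        return "unordered"
    except lp_core.LPError:
        try:
            from ._glpk_backend import flux_ratio_bounds_glpk
            bounds = flux_ratio_bounds_glpk(model, i, j)
            return lp_core.is_ordered(bounds, eps=eps)
        except Exception:
            logger.warning("LP failed twice for pair (%s, %s); undetermined",
                           i, j)
            return "undetermined"


def find_flux_ordered_pairs(model: MetabolicModel,
                            cfg: MediumConfig | None = None,
                            n_samples: int = 1000,
                            seed: int | None = None,
                            coupling: CouplingTable | None = None,
                            eps: float = lp_core.EPS_RATIO,
                            condition: str = "") -> OrderedPairSet:
    """Identify all flux-ordered reaction pairs of the canonical model.

    When ``cfg`` is given the model is medium-constrained (and re-checked for
    blocked reactions) first.  A precomputed ``coupling`` table lets fully
    coupled candidates be resolved without LPs.  The result is exact: the
    sampling prefilter only eliminates pairs with explicit counterexamples,
    so the output is independent of ``n_samples`` and ``seed``.
    """
    from .model_io import apply_medium, remove_blocked_reactions

    if cfg is not None:
        model = remove_blocked_reactions(apply_medium(model, cfg))
    sample = sample_flux_space(model, n_samples, seed=seed)
    cands = candidate_pairs(sample)
    result = OrderedPairSet(condition=condition)
    if coupling is not None:
        cands, resolved = remove_fully_coupled(cands, coupling, eps=eps)
        result.ordered |= resolved.ordered
        result.equal |= resolved.equal
    done = set()
    for (i, j) in sorted(cands):
        if (i, j) in done:
            continue
        verdict = _verify_pair(model, i, j, eps)
        done.add((i, j))
        if verdict == "ordered":
            result.ordered.add((i, j))
            done.add((j, i))  # reverse cannot be ordered
        elif verdict == "equal":
            result.equal.add(frozenset((i, j)))
            done.add((j, i))
        elif verdict == "undetermined":
            result.undetermined.add(frozenset((i, j)))
    logger.info("order search: %d ordered, %d equal, %d undetermined pairs",
                len(result.ordered), len(result.equal),
                len(result.undetermined))
    return result


def run_manifest(model: MetabolicModel, cfg: MediumConfig | None,
                 n_samples: int, seed: int | None,
                 eps: float = lp_core.EPS_RATIO) -> dict:
    """Reproducibility manifest for an order-finding run."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(model.S.toarray()).tobytes())
    h.update(model.lower_bounds.tobytes())
    h.update(model.upper_bounds.tobytes())
    h.update(json.dumps(model.reaction_ids).encode())
    return {
        "model_hash": h.hexdigest()[:16],
        "n_reactions": model.n_reactions,
        "medium": None if cfg is None else {
            "carbon_source": cfg.carbon_source,
            "carbon_uptake_max": cfg.carbon_uptake_max,
            "open_exchanges": sorted(cfg.open_exchanges),
            "biomass_fraction": cfg.biomass_fraction,
            "atpm_min": cfg.atpm_min,
        },
        "n_samples": n_samples,
        "seed": seed,
        "eps": eps,
        "sample_tol": SAMPLE_TOL,
    }
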