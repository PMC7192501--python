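"""Linear-programming primitives: FBA and flux-ratio extremisation.

The flux order decision for a reaction pair (r_i, r_j) rests on the extrema of
the flux ratio v_i / v_j over the steady-state polytope
{v : Sv = 0, v_min <= v <= v_max}.  Those extrema solve a linear-fractional
program which the Charnes-Cooper substitution (w = v / v_j, t = 1 / v_j) turns
into the LP

    min / max  w_i
    s.t.       S w = 0,  w_j = 1,  t v_min <= w <= t v_max,  t >= 0.

The pair is flux-ordered (v_i >= v_j in every steady state, with strict
inequality somewhere) iff z_min >= 1 and z_max > 1; z_min = z_max = 1 marks an
always-equal pair (fully coupled with ratio 1).  Note that the bound
constraints are scaled by the homogenisation variable t, so z_max can be
genuinely unbounded even with finite flux bounds; an unbounded maximisation is
reported as z_max = inf and satisfies z_max > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model_io import MetabolicModel

__all__ = [
    "RatioBounds",
    "LPError",
    "InfeasibleLPError",
    "UnboundedLPError",
    "RatioUndefinedError",
    "EPS_RATIO",
    "solve_fba",
    "flux_ratio_bounds",
    "is_ordered",
]

#: Tolerance on ratio space for the ordered/equal decision; double-precision
#: LP duality gaps on genome-scale models exceed 1e-9, hence the looser value.
EPS_RATIO = 1e-6

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded",
           4: "numerical"}


class LPError(RuntimeError):
    """Solver failure with a status that is neither optimal nor unbounded."""


class InfeasibleLPError(LPError):
    """The linear program has no feasible point."""


class UnboundedLPError(LPError):
    """The linear program is unbounded in the optimisation direction."""


class RatioUndefinedError(LPError):
    """v_j is forced to zero: the flux ratio v_i / v_j is undefined."""


@dataclass(frozen=True)
class RatioBounds:
    """Extrema of the flux ratio v_i / v_j over the steady-state polytope.

    ``z_max`` is inf when the maximisation is unbounded.  Both values are
    dimensionless; for irreversible models z_min >= 0.
    """

    z_min: float
    z_max: float
    status_min: str = "optimal"
    status_max: str = "optimal"


def _linprog(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None):
    return linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                   bounds=bounds, method="highs")


def solve_fba(model: MetabolicModel, objective: str,
              sense: str = "max") -> tuple[float, np.ndarray]:
    """Flux balance analysis: extremise one reaction's flux over the polytope.

    Returns the optimum and a flux vector attaining it (satisfying Sv = 0 and
    the bounds to solver tolerance).
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    j = model.index(objective)
    n = model.n_reactions
    c = np.zeros(n)
    c[j] = -1.0 if sense == "max" else 1.0
    if np.any(model.lower_bounds > model.upper_bounds):
        raise InfeasibleLPError("contradictory bounds: lb > ub")
    res = _linprog(
        c, A_eq=model.S, b_eq=np.zeros(model.n_metabolites),
        bounds=list(zip(model.lower_bounds, model.upper_bounds)),
    )
    if res.status == 2:
        raise InfeasibleLPError("FBA problem infeasible")
    if res.status == 3:
        raise UnboundedLPError(f"FBA objective {objective!r} unbounded")
    if res.status != 0:
        raise LPError(f"FBA solver failure: {_STATUS.get(res.status)}")
    return float(res.x[j]), res.x


def flux_ratio_bounds(model: MetabolicModel, i: str, j: str,
                      homogeneous_lb: bool = True) -> RatioBounds:
    """Extrema of v_i / v_j over steady states with v_j > 0 (Charnes-Cooper).

    ``homogeneous_lb=False`` drops strictly positive lower bounds (sets them
    to zero), yielding the classification on the pure flux cone as used by
    coupling analysis on unconstrained models.

    Raises :class:`RatioUndefinedError` when both programs are infeasible,
    i.e. v_j is forced to zero everywhere.
    """
    if i == j:
        raise ValueError("flux ratio requires two distinct reactions")
    ji, jj = model.index(i), model.index(j)
    n = model.n_reactions
    m = model.n_metabolites
    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    if not homogeneous_lb:
        lb = np.zeros_like(lb)

    # variables x = [w_1..w_n, t]
    A_eq = sp.hstack([model.S, sp.csc_matrix((m, 1))], format="csc")
    A_eq = sp.vstack([A_eq,
                      sp.csc_matrix(([1.0], ([0], [jj])), shape=(1, n + 1))],
                     format="csc")
    b_eq = np.zeros(m + 1)
    b_eq[-1] = 1.0

    rows_ub = []
    # w_k - t * ub_k <= 0  (skip infinite ub)
    finite = np.isfinite(ub)
    I_fin = sp.eye(n, format="csc")[np.flatnonzero(finite), :]
    if I_fin.shape[0]:
        rows_ub.append(sp.hstack(
            [I_fin, sp.csc_matrix(-ub[finite].reshape(-1, 1))], format="csc"))
    # t * lb_k - w_k <= 0   (only needed where lb > 0; w >= 0 covers lb <= 0)
    pos = lb > 0
    I_pos = sp.eye(n, format="csc")[np.flatnonzero(pos), :]
    if I_pos.shape[0]:
        rows_ub.append(sp.hstack(
            [-I_pos, sp.csc_matrix(lb[pos].reshape(-1, 1))], format="csc"))
    A_ub = sp.vstack(rows_ub, format="csc") if rows_ub else None
    b_ub = np.zeros(A_ub.shape[0]) if A_ub is not None else None

    var_bounds = [(0.0, None)] * (n + 1)
    c = np.zeros(n + 1)

    def _solve(sense: str) -> tuple[float, str]:
        c[ji] = 1.0 if sense == "min" else -1.0
        res = _linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                       bounds=var_bounds)
        c[ji] = 0.0
        status = _STATUS.get(res.status, "unknown")
        if res.status == 0:
            val = float(res.x[ji])
            return max(val, 0.0), status
        if res.status == 3:
            return (0.0, status) if sense == "min" else (np.inf, status)
        return np.nan, status

    z_min, st_min = _solve("min")
    z_max, st_max = _solve("max")
    if st_min == "infeasible" and st_max == "infeasible":
        raise RatioUndefinedError(
            f"v_{j} is forced to zero: ratio v_{i}/v_{j} undefined"
        )
    return RatioBounds(z_min=z_min, z_max=z_max,
                       status_min=st_min, status_max=st_max)


def is_ordered(bounds: RatioBounds, eps: float = EPS_RATIO) -> str:
    """Classify a ratio-bounds result as ``ordered``, ``equal`` or ``unordered``.

    ordered: z_min >= 1 - eps and z_max > 1 + eps (v_i >= v_j everywhere and
    strictly greater somewhere); equal: both extrema within eps of 1 (fully
    coupled with ratio 1); unordered otherwise.
    """
    z_min, z_max = bounds.z_min, bounds.z_max
    if np.isnan(z_min) or np.isnan(z_max):
        return "unordered"
    if abs(z_min - 1.0) <= eps and np.isfinite(z_max) and abs(z_max - 1.0) <= eps:
        return "equal"
    if z_min >= 1.0 - eps and z_max > 1.0 + eps:
        return "ordered"
    return "unordered"
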