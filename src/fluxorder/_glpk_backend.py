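"""Secondary LP backend (GLPK via optlang) for retrying failed ratio programs.

Used only when the primary HiGHS solve of a Charnes-Cooper program fails; a
second opinion from an independent solver before a pair is reported
undetermined.
"""

from __future__ import annotations

import numpy as np

from .lp_core import RatioBounds
from .model_io import MetabolicModel


def flux_ratio_bounds_glpk(model: MetabolicModel, i: str, j: str) -> RatioBounds:
    from optlang.glpk_interface import Constraint, Model, Objective, Variable

    n = model.n_reactions
    ji, jj = model.index(i), model.index(j)
    w = [Variable(f"w_{k}", lb=0) for k in range(n)]
    t = Variable("t", lb=0)
    cons = []
    S = model.S.tocsr()
    for r in range(model.n_metabolites):
        row = S.getrow(r)
        if row.nnz == 0:
            continue
        expr = sum(float(c) * w[k] for k, c in zip(row.indices, row.data))
        cons.append(Constraint(expr, lb=0, ub=0))
    cons.append(Constraint(w[jj], lb=1, ub=1))
    for k in range(n):
        ub = model.upper_bounds[k]
        if np.isfinite(ub):
            cons.append(Constraint(w[k] - float(ub) * t, ub=0))
        lb = model.lower_bounds[k]
        if lb > 0:
            cons.append(Constraint(float(lb) * t - w[k], ub=0))

    m = Model()
    m.add(cons)

    def solve(direction):
        m.objective = Objective(1.0 * w[ji], direction=direction)
        status = m.optimize()
        if status == "optimal":
            return max(float(w[ji].primal), 0.0), "optimal"
        if status == "unbounded":
            return (np.inf if direction == "max" else 0.0), "unbounded"
        return np.nan, status

    z_min, st_min = solve("min")
    z_max, st_max = solve("max")
    return RatioBounds(z_min=z_min, z_max=z_max,
                       status_min=st_min, status_max=st_max)
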