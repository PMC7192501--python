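import numpy as np
import pytest
import scipy.sparse as sp

from fluxorder import FixtureSpec, MediumConfig, MetabolicModel, canonicalize
from fluxorder.fixtures_oracle import make_fixture

NAMED_FIXTURES = ["chain", "branch", "diamond", "growth", "paperlike"]


def build_canonical(name: str) -> MetabolicModel:
    params = (3,) if name == "chain" else ()
    return canonicalize(make_fixture(FixtureSpec(name, params)))


@pytest.fixture
def chain3():
    return build_canonical("chain")


@pytest.fixture
def branch():
    return build_canonical("branch")


@pytest.fixture
def diamond():
    return build_canonical("diamond")


@pytest.fixture
def growth():
    return build_canonical("growth")


@pytest.fixture
def paperlike():
    return build_canonical("paperlike")


@pytest.fixture
def growth_medium():
    """Growth fixture constrained to a carbon-limited medium."""
    cfg = MediumConfig(carbon_source="glc_uptake", carbon_uptake_max=9.0,
                       biomass_fraction=0.95, atpm_min=1.0)
    model = canonicalize(make_fixture(FixtureSpec("growth")), cfg)
    return model, cfg


def toy_model(met_ids, reactions, **kw):
    """Hand-build a model from (id, {met: coeff}, lb, ub[, gpr]) tuples."""
    met_pos = {m: k for k, m in enumerate(met_ids)}
    rows, cols, data = [], [], []
    rids, lbs, ubs, gprs = [], [], [], []
    for j, rxn in enumerate(reactions):
        rid, stoich, lb, ub = rxn[:4]
        rids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        gprs.append(rxn[4] if len(rxn) > 4 else "")
        for met, coeff in stoich.items():
            rows.append(met_pos[met])
            cols.append(j)
            data.append(float(coeff))
    S = sp.csc_matrix((data, (rows, cols)), shape=(len(met_ids), len(rids)))
    return MetabolicModel(metabolite_ids=list(met_ids), reaction_ids=rids,
                          S=S, lower_bounds=np.array(lbs),
                          upper_bounds=np.array(ubs), gpr=gprs, **kw)
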