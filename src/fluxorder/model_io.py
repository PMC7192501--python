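"""Reading, canonicalising and configuring constraint-based metabolic models.

The downstream order/coupling machinery works on a single canonical form: an
irreversible stoichiometric model (all lower bounds >= 0) with no blocked
reactions.  Reversible reactions are split into a forward and a ``_reverse``
copy with the negated stoichiometric column, infinite bounds are capped, and
reactions that cannot carry flux at steady state are removed.

Growth media are described by :class:`MediumConfig`: a sole carbon source with
a bounded import rate, a set of freely imported compounds (oxygen and
inorganics in the minimal-medium setups), a minimum flux through the
non-growth-associated ATP maintenance pseudo-reaction, and a required minimum
biomass production rate expressed as a fraction alpha_b of the FBA optimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

__all__ = [
    "MetabolicModel",
    "MediumConfig",
    "ModelFormatError",
    "ModelValidationError",
    "InfeasibleModelError",
    "MediumConfigError",
    "REVERSE_SUFFIX",
    "BOUND_CAP",
    "BLOCKED_TOL",
    "DEFAULT_MACROSYSTEMS",
    "read_model",
    "write_model",
    "split_reversible",
    "find_blocked_reactions",
    "remove_blocked_reactions",
    "apply_medium",
    "canonicalize",
    "macrosystem_of",
]

REVERSE_SUFFIX = "_reverse"

#: Cap for infinite flux bounds, mmol gDW^-1 h^-1.
BOUND_CAP = 1000.0

#: LP-optimum tolerance below which a reaction counts as blocked.
BLOCKED_TOL = 1e-9


class ModelFormatError(ValueError):
    """The model file could not be parsed."""


class ModelValidationError(ValueError):
    """The parsed model violates a structural requirement."""


class InfeasibleModelError(RuntimeError):
    """The steady-state system has no feasible flux distribution."""


class MediumConfigError(ValueError):
    """The medium configuration cannot be applied to the model."""


# Eight macrosystem categories; keys are substrings matched (case-insensitively)
# against subsystem labels.  Editable: pass a custom mapping to macrosystem_of.
DEFAULT_MACROSYSTEMS: dict[str, str] = {
    "amino acid": "Amino acid metabolism",
    "arginine": "Amino acid metabolism",
    "histidine": "Amino acid metabolism",
    "methionine": "Amino acid metabolism",
    "threonine": "Amino acid metabolism",
    "tyrosine": "Amino acid metabolism",
    "valine": "Amino acid metabolism",
    "alanine": "Amino acid metabolism",
    "glutamate": "Amino acid metabolism",
    "glycine": "Amino acid metabolism",
    "cysteine": "Amino acid metabolism",
    "glycolysis": "Carbohydrate metabolism",
    "citric acid": "Carbohydrate metabolism",
    "pentose phosphate": "Carbohydrate metabolism",
    "pyruvate": "Carbohydrate metabolism",
    "anaplerotic": "Carbohydrate metabolism",
    "alternate carbon": "Carbohydrate metabolism",
    "glyoxylate": "Carbohydrate metabolism",
    "oxidative phosphorylation": "Energy and maintenance",
    "energy": "Energy and maintenance",
    "atp maintenance": "Energy and maintenance",
    "biomass": "Energy and maintenance",
    "cell envelope": "Cell wall biosynthesis",
    "murein": "Cell wall biosynthesis",
    "lipopolysaccharide": "Cell wall biosynthesis",
    "cofactor": "Cofactor and vitamin metabolism",
    "prosthetic group": "Cofactor and vitamin metabolism",
    "folate": "Cofactor and vitamin metabolism",
    "lipid": "Lipid metabolism",
    "membrane lipid": "Lipid metabolism",
    "glycerophospholipid": "Lipid metabolism",
    "fatty acid": "Lipid metabolism",
    "nucleotide": "Nucleotide metabolism",
    "purine": "Nucleotide metabolism",
    "pyrimidine": "Nucleotide metabolism",
    "transport": "Transport",
    "exchange": "Transport",
}


def macrosystem_of(subsystem: str, mapping: dict[str, str] | None = None) -> str:
    """Map a subsystem label to one of the eight macrosystem categories.

    Unmapped subsystems (and empty labels) map to ``"other"``.
    """
    if not subsystem:
        return "other"
    table = DEFAULT_MACROSYSTEMS if mapping is None else mapping
    low = subsystem.lower()
    for key, macro in table.items():
        if key in low:
            return macro
    return "other"


@dataclass
class MetabolicModel:
    """Stoichiometric model: metabolites x reactions, bounds, GPR annotations.

    ``S`` holds the stoichiometric coefficients s_ij (rows = metabolites,
    columns = reactions); fluxes are in mmol gDW^-1 h^-1.  In canonical form
    all lower bounds are >= 0 (irreversible reactions only).
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sp.csc_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    gpr: list[str] = field(default_factory=list)
    subsystem: list[str] = field(default_factory=list)
    biomass_id: str | None = None
    atpm_id: str | None = None
    boundary_metabolites: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        n = len(self.reaction_ids)
        self.S = sp.csc_matrix(self.S)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        if not self.gpr:
            self.gpr = [""] * n
        if not self.subsystem:
            self.subsystem = [""] * n
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def index(self, reaction_id: str) -> int:
        try:
            return self._rxn_index[reaction_id]
        except AttributeError:
            self._rxn_index = {r: k for k, r in enumerate(self.reaction_ids)}
            return self._rxn_index[reaction_id]

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in set(self.reaction_ids)

    def validate(self) -> None:
        n = self.n_reactions
        if len(set(self.reaction_ids)) != n:
            raise ModelValidationError("duplicate reaction identifiers")
        if self.S.shape != (self.n_metabolites, n):
            raise ModelValidationError(
                f"S has shape {self.S.shape}, expected "
                f"({self.n_metabolites}, {n})"
            )
        if self.lower_bounds.shape != (n,) or self.upper_bounds.shape != (n,):
            raise ModelValidationError("bound vectors do not match reactions")
        if len(self.gpr) != n or len(self.subsystem) != n:
            raise ModelValidationError("annotation lists do not match reactions")

    @property
    def is_irreversible(self) -> bool:
        return bool(np.all(self.lower_bounds >= 0))

    def macrosystems(self, mapping: dict[str, str] | None = None) -> list[str]:
        return [macrosystem_of(s, mapping) for s in self.subsystem]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            gpr=list(self.gpr),
            subsystem=list(self.subsystem),
            biomass_id=self.biomass_id,
            atpm_id=self.atpm_id,
            boundary_metabolites=set(self.boundary_metabolites),
        )

    def subset_reactions(self, keep: list[int]) -> "MetabolicModel":
        """Model restricted to the reaction columns in ``keep`` (in order)."""
        keep = list(keep)
        kept_ids = [self.reaction_ids[k] for k in keep]
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=kept_ids,
            S=self.S[:, keep],
            lower_bounds=self.lower_bounds[keep],
            upper_bounds=self.upper_bounds[keep],
            gpr=[self.gpr[k] for k in keep],
            subsystem=[self.subsystem[k] for k in keep],
            biomass_id=self.biomass_id if self.biomass_id in kept_ids else None,
            atpm_id=self.atpm_id if self.atpm_id in kept_ids else None,
            boundary_metabolites=set(self.boundary_metabolites),
        )

    # -- exchange detection ------------------------------------------------
    def exchange_indices(self) -> list[int]:
        """Columns that exchange matter with the environment.

        A reaction is an exchange iff its column entries are all of one sign
        (it only produces, or only consumes).  When boundary-metabolite
        annotation is available (from SBML), columns touching only boundary
        metabolites take precedence.
        """
        out = []
        Scsc = self.S.tocsc()
        bnd = {
            i for i, m in enumerate(self.metabolite_ids)
            if m in self.boundary_metabolites
        }
        for j in range(self.n_reactions):
            col = Scsc.getcol(j)
            rows = col.indices
            vals = col.data
            if len(vals) == 0:
                continue
            if bnd and all(r in bnd for r in rows):
                out.append(j)
            elif np.all(vals > 0) or np.all(vals < 0):
                out.append(j)
        return out

    def import_indices(self) -> list[int]:
        """Exchanges that can bring matter in.

        In irreversible form an import column has only positive entries
        (produces internal metabolites from nothing).
        """
        imports = []
        Scsc = self.S.tocsc()
        for j in self.exchange_indices():
            vals = Scsc.getcol(j).data
            if np.all(vals > 0):
                imports.append(j)
        return imports


@dataclass(frozen=True)
class MediumConfig:
    """Minimal-medium configuration.

    alpha_b (``biomass_fraction``) is the required minimum biomass production
    as a fraction of the FBA optimum; distinct from the coupling ratio alpha.
    """

    carbon_source: str | None = None
    carbon_uptake_max: float = 20.0
    open_exchanges: frozenset[str] = frozenset()
    biomass_fraction: float = 0.95
    atpm_min: float = 3.15

    def __post_init__(self) -> None:
        if not (0.0 <= self.biomass_fraction <= 1.0):
            raise MediumConfigError("biomass_fraction must lie in [0, 1]")
        if self.carbon_uptake_max <= 0:
            raise MediumConfigError("carbon_uptake_max must be positive")


# ----------------------------------------------------------------------------
# Reading / writing
# ----------------------------------------------------------------------------

def _from_cobra(cm, biomass_id=None, atpm_id=None) -> MetabolicModel:
    met_ids = [m.id for m in cm.metabolites]
    met_pos = {m: k for k, m in enumerate(met_ids)}
    rxn_ids, lbs, ubs, gprs, subs = [], [], [], [], []
    rows, cols, data = [], [], []
    for j, rxn in enumerate(cm.reactions):
        if len(rxn.metabolites) == 0:
            raise ModelValidationError(
                f"reaction {rxn.id!r} has no reactants or products"
            )
        rxn_ids.append(rxn.id)
        lbs.append(rxn.lower_bound)
        ubs.append(rxn.upper_bound)
        gprs.append(rxn.gene_reaction_rule or "")
        subs.append(rxn.subsystem or "")
        for met, coeff in rxn.metabolites.items():
            rows.append(met_pos[met.id])
            cols.append(j)
            data.append(float(coeff))
    S = sp.csc_matrix(
        (data, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
    )
    boundary = {m.id for m in cm.metabolites if getattr(m, "_bound", 0) or
                m.compartment in ("b", "boundary")}
    if biomass_id is None:
        for rid in rxn_ids:
            if "biomass" in rid.lower():
                biomass_id = rid
                break
    if atpm_id is None and "ATPM" in rxn_ids:
        atpm_id = "ATPM"
    return MetabolicModel(
        metabolite_ids=met_ids, reaction_ids=rxn_ids, S=S,
        lower_bounds=np.array(lbs), upper_bounds=np.array(ubs),
        gpr=gprs, subsystem=subs, biomass_id=biomass_id, atpm_id=atpm_id,
        boundary_metabolites=boundary,
    )


def read_model(path: str, format: str | None = None,
               biomass_id: str | None = None,
               atpm_id: str | None = None) -> MetabolicModel:
    """Read an SBML (Level 3 + FBC) or COBRA-JSON model file.

    Original (possibly negative) bounds, GPR rules and subsystem labels are
    preserved verbatim; canonicalisation is a separate, explicit step.
    """
    import cobra.io

    if format is None:
        format = "json" if str(path).endswith(".json") else "sbml"
    try:
        if format == "json":
            cm = cobra.io.load_json_model(str(path))
        elif format == "sbml":
            cm = cobra.io.read_sbml_model(str(path))
        else:
            raise ModelFormatError(f"unknown model format {format!r}")
    except ModelFormatError:
        raise
    except Exception as exc:  # parser-level failure
        raise ModelFormatError(f"could not parse {path}: {exc}") from exc
    return _from_cobra(cm, biomass_id=biomass_id, atpm_id=atpm_id)


def to_cobra(model: MetabolicModel):
    """Convert to a cobra.Model (for serialisation and interoperability)."""
    import cobra

    cm = cobra.Model("fluxorder_model")
    mets = {
        mid: cobra.Metabolite(mid, compartment="c")
        for mid in model.metabolite_ids
    }
    cm.add_metabolites(list(mets.values()))
    Scsc = model.S.tocsc()
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        r = cobra.Reaction(rid)
        r.lower_bound = float(model.lower_bounds[j])
        r.upper_bound = float(model.upper_bounds[j])
        col = Scsc.getcol(j)
        r.add_metabolites({
            mets[model.metabolite_ids[i]]: float(v)
            for i, v in zip(col.indices, col.data)
        })
        if model.gpr[j]:
            r.gene_reaction_rule = model.gpr[j]
        r.subsystem = model.subsystem[j]
        rxns.append(r)
    cm.add_reactions(rxns)
    if model.biomass_id is not None and model.biomass_id in model.reaction_ids:
        cm.objective = model.biomass_id
    return cm


def write_model(model: MetabolicModel, path: str) -> None:
    """Serialise the model to COBRA-JSON."""
    import cobra.io

    cobra.io.save_json_model(to_cobra(model), str(path))


# ----------------------------------------------------------------------------
# Canonicalisation
# ----------------------------------------------------------------------------

def split_reversible(model: MetabolicModel) -> MetabolicModel:
    """Split reversible reactions into forward and backward direction.

    A reaction with lb < 0 is replaced by a forward copy with bounds
    [max(lb, 0), ub] and a reverse copy (negated stoichiometric column, id
    suffixed ``_reverse``) with bounds [0, -lb].  A forward copy left with
    ub <= 0 has zero width and is removed as blocked downstream.
    """
    met_ids = list(model.metabolite_ids)
    rxn_ids, lbs, ubs, gprs, subs = [], [], [], [], []
    cols = []
    Scsc = model.S.tocsc()
    for j, rid in enumerate(model.reaction_ids):
        lb, ub = model.lower_bounds[j], model.upper_bounds[j]
        col = Scsc.getcol(j)
        if lb < 0:
            # forward copy
            rxn_ids.append(rid)
            lbs.append(0.0)
            ubs.append(max(ub, 0.0))
            gprs.append(model.gpr[j])
            subs.append(model.subsystem[j])
            cols.append(col)
            # reverse copy
            rxn_ids.append(rid + REVERSE_SUFFIX)
            lbs.append(0.0)
            ubs.append(-lb)
            gprs.append(model.gpr[j])
            subs.append(model.subsystem[j])
            cols.append(-col)
        else:
            rxn_ids.append(rid)
            lbs.append(lb)
            ubs.append(ub)
            gprs.append(model.gpr[j])
            subs.append(model.subsystem[j])
            cols.append(col)
    S = sp.hstack(cols, format="csc") if cols else sp.csc_matrix((len(met_ids), 0))
    return MetabolicModel(
        metabolite_ids=met_ids, reaction_ids=rxn_ids, S=S,
        lower_bounds=np.array(lbs), upper_bounds=np.array(ubs),
        gpr=gprs, subsystem=subs,
        biomass_id=model.biomass_id, atpm_id=model.atpm_id,
        boundary_metabolites=set(model.boundary_metabolites),
    )


def cap_bounds(model: MetabolicModel, cap: float = BOUND_CAP) -> MetabolicModel:
    """Replace infinite upper bounds by ``cap`` (and -inf lower bounds by -cap)."""
    m = model.copy()
    m.upper_bounds = np.minimum(m.upper_bounds, cap)
    m.lower_bounds = np.maximum(m.lower_bounds, -cap)
    return m


def find_blocked_reactions(model: MetabolicModel,
                           tol: float = BLOCKED_TOL) -> set[str]:
    """Reactions that cannot carry flux at steady state.

    A reaction is blocked iff its maximum achievable flux over
    {v : Sv = 0, lb <= v <= ub} is <= tol.  Requires the irreversible form;
    independent of any objective.  Reactions pinned to lb = ub = 0 count as
    blocked without solving an LP.
    """
    from . import lp_core

    if not model.is_irreversible:
        raise ModelValidationError(
            "find_blocked_reactions requires an irreversible model"
        )
    blocked: set[str] = set()
    for j, rid in enumerate(model.reaction_ids):
        if model.upper_bounds[j] <= tol and model.lower_bounds[j] <= tol:
            blocked.add(rid)
            continue
        opt, _ = lp_core.solve_fba(model, rid, sense="max")
        if opt <= tol:
            blocked.add(rid)
    return blocked


def remove_blocked_reactions(model: MetabolicModel,
                             tol: float = BLOCKED_TOL) -> MetabolicModel:
    blocked = find_blocked_reactions(model, tol=tol)
    keep = [j for j, rid in enumerate(model.reaction_ids) if rid not in blocked]
    return model.subset_reactions(keep)


def apply_medium(model: MetabolicModel, cfg: MediumConfig) -> MetabolicModel:
    """Constrain the model to a minimal medium.

    Closes every import except the designated carbon source and the open
    exchanges, caps carbon uptake, imposes the ATP-maintenance minimum, then
    fixes the biomass lower bound to alpha_b times the FBA optimum under this
    medium.  Idempotent for a fixed configuration.
    """
    from . import lp_core

    m = model.copy()
    imports = m.import_indices()
    for j in imports:
        rid = m.reaction_ids[j]
        if rid == cfg.carbon_source:
            m.upper_bounds[j] = cfg.carbon_uptake_max
        elif rid in cfg.open_exchanges:
            pass
        else:
            m.upper_bounds[j] = 0.0
            m.lower_bounds[j] = min(m.lower_bounds[j], 0.0)
    if m.atpm_id is not None and m.atpm_id in set(m.reaction_ids):
        m.lower_bounds[m.index(m.atpm_id)] = cfg.atpm_min
    if cfg.biomass_fraction > 0:
        if m.biomass_id is None or m.biomass_id not in set(m.reaction_ids):
            raise MediumConfigError(
                "biomass_fraction > 0 requires a biomass reaction"
            )
        jb = m.index(m.biomass_id)
        m.lower_bounds[jb] = 0.0  # idempotence: optimum must not be self-bound
        try:
            opt, _ = lp_core.solve_fba(m, m.biomass_id, sense="max")
        except lp_core.InfeasibleLPError:
            raise MediumConfigError("no growth on this medium") from None
        if opt <= BLOCKED_TOL:
            raise MediumConfigError("no growth on this medium")
        m.lower_bounds[jb] = cfg.biomass_fraction * opt
    return m


def canonicalize(model: MetabolicModel, cfg: MediumConfig | None = None,
                 cap: float = BOUND_CAP,
                 blocked_tol: float = BLOCKED_TOL) -> MetabolicModel:
    """Full preprocessing pipeline to the canonical irreversible form.

    Split reversible reactions, cap infinite bounds, remove blocked reactions;
    when a medium is given, apply it and remove blocked reactions again
    (medium constraints create new blocked reactions).
    """
    m = split_reversible(model)
    m = cap_bounds(m, cap=cap)
    m = remove_blocked_reactions(m, tol=blocked_tol)
    if cfg is not None:
        m = apply_medium(m, cfg)
        m = remove_blocked_reactions(m, tol=blocked_tol)
    return m
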