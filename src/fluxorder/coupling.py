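"""Flux coupling analysis from the ratio characterisation.

For an (ordered storage of an) unordered pair {r_i, r_j}, let R_min, R_max be
the extrema of v_i / v_j over steady states with v_j > 0:

* full      — R_min = R_max = alpha (> 0): the ratio is constant in every
              steady state,
* partial   — 0 < R_min < R_max < inf: activities match in both directions and
              the ratio is bounded (beta = R_max),
* directional — exactly one side is bounded; R_min > 0 means v_j > 0 forces
              v_i > 0 (i is the *leader*, j the follower), R_max < inf means
              the converse,
* uncoupled — R_min = 0 and R_max = inf.

Directional pairs are stored leader -> follower, the orientation in which the
flux order relation, when present, also holds; this is the orientation used by
the coupling hierarchy (reactions at the top control the activation state of
reactions below).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lp_core
from .model_io import MetabolicModel

__all__ = ["CouplingEntry", "CouplingTable", "classify_coupling",
           "coupling_table", "order_coupling_overlap"]


@dataclass(frozen=True)
class CouplingEntry:
    """Coupling classification of one reaction pair.

    ``klass`` is one of full / partial / directional / uncoupled /
    undetermined.  For directional entries ``leader`` and ``follower`` are
    set; for full entries ``alpha`` is the constant ratio v_i / v_j.
    ``ratio_low`` / ``ratio_high`` are the extrema of v_i / v_j.
    """

    i: str
    j: str
    klass: str
    ratio_low: float = np.nan
    ratio_high: float = np.nan
    alpha: float | None = None
    leader: str | None = None
    follower: str | None = None


@dataclass
class CouplingTable:
    """Per-pair coupling classes over a model's unordered reaction pairs."""

    entries: dict[frozenset, CouplingEntry] = field(default_factory=dict)
    condition: str = ""

    def get(self, i: str, j: str) -> CouplingEntry | None:
        return self.entries.get(frozenset((i, j)))

    def add(self, entry: CouplingEntry) -> None:
        self.entries[frozenset((entry.i, entry.j))] = entry

    def pairs_of_class(self, klass: str) -> list[CouplingEntry]:
        return [e for e in self.entries.values() if e.klass == klass]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"reaction_i": e.i, "reaction_j": e.j, "class": e.klass,
             "ratio_low": e.ratio_low, "ratio_high": e.ratio_high,
             "alpha": e.alpha if e.alpha is not None else np.nan,
             "leader": e.leader or "", "follower": e.follower or ""}
            for e in self.entries.values()
        ]
        return pd.DataFrame(
            rows, columns=["reaction_i", "reaction_j", "class", "ratio_low",
                           "ratio_high", "alpha", "leader", "follower"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def classify_coupling(model: MetabolicModel, i: str, j: str,
                      eps: float = lp_core.EPS_RATIO,
                      homogeneous_lb: bool = True) -> CouplingEntry:
    """Classify the coupling between two unblocked reactions.

    With ``homogeneous_lb=True`` the analysis uses the same (homogenised)
    constraints as the ordering analysis; set it False to drop strictly
    positive lower bounds (pure flux-cone classification, the behaviour of
    coupling analyses on unconstrained models).
    """
    b = lp_core.flux_ratio_bounds(model, i, j, homogeneous_lb=homogeneous_lb)
    rl, rh = b.z_min, b.z_max
    if np.isnan(rl) or np.isnan(rh):
        return CouplingEntry(i, j, "undetermined", rl, rh)
    low_pos = rl > eps
    high_fin = np.isfinite(rh)
    if low_pos and high_fin:
        if abs(rh - rl) <= eps * max(1.0, abs(rl)):
            alpha = 0.5 * (rl + rh)
            return CouplingEntry(i, j, "full", rl, rh, alpha=alpha)
        return CouplingEntry(i, j, "partial", rl, rh)
    if low_pos:  # v_j > 0 forces v_i > 0: i leads
        return CouplingEntry(i, j, "directional", rl, rh,
                             leader=i, follower=j)
    if high_fin:  # v_i > 0 forces v_j > 0: j leads
        return CouplingEntry(i, j, "directional", rl, rh,
                             leader=j, follower=i)
    return CouplingEntry(i, j, "uncoupled", rl, rh)


def coupling_table(model: MetabolicModel, eps: float = lp_core.EPS_RATIO,
                   homogeneous_lb: bool = True,
                   condition: str = "") -> CouplingTable:
    """Classify every unordered reaction pair of the canonical model."""
    table = CouplingTable(condition=condition)
    ids = model.reaction_ids
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            try:
                entry = classify_coupling(model, ids[a], ids[b], eps=eps,
                                          homogeneous_lb=homogeneous_lb)
            except lp_core.LPError:
                entry = CouplingEntry(ids[a], ids[b], "undetermined")
            table.add(entry)
    return table


def order_coupling_overlap(orders, coupling: CouplingTable) -> dict:
    """Conditional probabilities between ordered and coupled pair sets.

    O is the set of flux-ordered pairs; C the union of coupled pairs
    (full/partial/directional); D, P, F the individual classes.  Directional
    pairs count as ordered when their ordered orientation exists.  Returns
    Pr(C|O), Pr(D|O), Pr(P|O), Pr(F|O), Pr(O|C), Pr(O|D), Pr(O|P) as exact
    fractions (NaN with a warning when a conditioning set is empty).
    """
    import warnings

    ordered = set(orders.ordered)          # directed (i, j)
    ordered_unordered = {frozenset(p) for p in ordered}
    # equal pairs are fully coupled with ratio 1 and ordered "by definition"
    # only in the weak sense; they are excluded from O (the paper removes
    # always-equal pairs from the ordered set) but counted in F.
    coupled_classes = {"full", "partial", "directional"}
    C = {k for k, e in coupling.entries.items() if e.klass in coupled_classes}
    D = {k for k, e in coupling.entries.items() if e.klass == "directional"}
    P = {k for k, e in coupling.entries.items() if e.klass == "partial"}
    F = {k for k, e in coupling.entries.items() if e.klass == "full"}

    O = ordered_unordered

    def frac(num: int, den: int, label: str) -> float:
        if den == 0:
            warnings.warn(f"conditioning set empty for {label}; returning NaN")
            return float("nan")
        return num / den

    out = {
        "Pr(C|O)": frac(len(O & C), len(O), "Pr(C|O)"),
        "Pr(D|O)": frac(len(O & D), len(O), "Pr(D|O)"),
        "Pr(P|O)": frac(len(O & P), len(O), "Pr(P|O)"),
        "Pr(F|O)": frac(len(O & F), len(O), "Pr(F|O)"),
        "Pr(O|C)": frac(len(O & C), len(C), "Pr(O|C)"),
        "Pr(O|D)": frac(len(O & D), len(D), "Pr(O|D)"),
        "Pr(O|P)": frac(len(O & P), len(P), "Pr(O|P)"),
        "n_ordered": len(O),
        "n_coupled": len(C),
    }
    return out
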