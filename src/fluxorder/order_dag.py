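"""Flux order DAG: collapse, transitive reduction, levels, and derived analyses.

The flux order relation is a partial order on reactions, so its digraph is
acyclic once always-equal groups (fully coupled with ratio 1, and chains
thereof) are collapsed into single nodes.  The transitive reduction (Hasse
diagram) keeps only edges not implied by transitivity.  The *level* of a node
is the longest shortest path from any root (in-degree-0 node) that reaches it;
roots sit at level 0, and a node unreachable from every other root is its own
root.  Levels partition into *first* (level 0), *middle* (level 1) and *last*
(levels >= 2) subsets for the regulatory analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import lp_core
from .model_io import MetabolicModel
from .order_finder import OrderedPairSet

__all__ = ["OrderDAG", "LevelPartition", "CyclicOrderError", "build_order_dag",
           "assign_levels", "level_partition", "condition_overlap",
           "biomass_ancestor_subgraph", "find_essential_reactions",
           "essentiality_order_report"]


class CyclicOrderError(RuntimeError):
    """A cycle in the order digraph (a numerical-tolerance artifact)."""


@dataclass
class OrderDAG:
    """Collapsed, transitively reduced flux order digraph with levels.

    Nodes are frozensets of reaction ids (singletons, or groups whose fluxes
    are equal in every steady state); ``graph`` is a networkx DiGraph over
    those nodes, ``levels`` maps node -> 0-based level index.
    """

    graph: nx.DiGraph
    levels: dict = field(default_factory=dict)
    condition: str = ""

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def edges(self):
        return list(self.graph.edges)

    def node_of(self, reaction_id: str) -> frozenset:
        for node in self.graph.nodes:
            if reaction_id in node:
                return node
        raise KeyError(f"reaction {reaction_id!r} not in DAG")

    def node_label(self, node: frozenset) -> str:
        return min(node)

    def reactions(self) -> set[str]:
        out: set[str] = set()
        for node in self.graph.nodes:
            out |= node
        return out

    def roots(self) -> list[frozenset]:
        return [n for n in self.graph.nodes if self.graph.in_degree(n) == 0]

    def level_histogram(self) -> pd.DataFrame:
        """Nodes and reactions per level (0-based and 1-based labels)."""
        rows = []
        by_level: dict[int, list] = {}
        for node, lev in self.levels.items():
            by_level.setdefault(lev, []).append(node)
        for lev in sorted(by_level):
            nodes = by_level[lev]
            rows.append({
                "level": lev, "level_1based": lev + 1,
                "n_nodes": len(nodes),
                "n_reactions": sum(len(n) for n in nodes),
            })
        return pd.DataFrame(rows,
                            columns=["level", "level_1based", "n_nodes",
                                     "n_reactions"])

    # -- export ------------------------------------------------------------
    def _labelled(self, model: MetabolicModel | None = None) -> nx.DiGraph:
        g = nx.DiGraph()
        macro = {}
        if model is not None:
            macro = dict(zip(model.reaction_ids, model.macrosystems()))
        for node in self.graph.nodes:
            label = self.node_label(node)
            g.add_node(label,
                       members=";".join(sorted(node)),
                       level=int(self.levels.get(node, 0)),
                       level_1based=int(self.levels.get(node, 0)) + 1,
                       macrosystem=";".join(sorted(
                           {macro.get(r, "other") for r in node}))
                       if macro else "")
        for a, b in self.graph.edges:
            g.add_edge(self.node_label(a), self.node_label(b))
        return g

    def to_graphml(self, path, model: MetabolicModel | None = None) -> None:
        nx.write_graphml(self._labelled(model), path)

    def to_dot(self, path, model: MetabolicModel | None = None) -> None:
        g = self._labelled(model)
        lines = ["digraph fluxorder {"]
        for n, data in g.nodes(data=True):
            lines.append(
                f'  "{n}" [level={data["level"]}, members="{data["members"]}"];'
            )
        for a, b in g.edges:
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


@dataclass(frozen=True)
class LevelPartition:
    """Disjoint covering split of DAG nodes into first/middle/last subsets."""

    first: frozenset
    middle: frozenset
    last: frozenset

    def __post_init__(self) -> None:
        if (self.first & self.middle) or (self.first & self.last) \
                or (self.middle & self.last):
            raise ValueError("level partition subsets must be disjoint")


def build_order_dag(orders: OrderedPairSet,
                    equal_groups: list[frozenset] | None = None,
                    condition: str = "") -> OrderDAG:
    """Build the flux order DAG from verified pairs.

    Reactions in always-equal groups are merged into single nodes, group-level
    edges deduplicated, and the transitive reduction applied (unique for
    DAGs).  A cycle would mean the input was not antisymmetric/transitive and
    raises :class:`CyclicOrderError` listing the offending nodes.
    """
    if equal_groups is None:
        reactions = {r for p in orders.ordered for r in p}
        equal_groups = orders.equal_groups(reactions)
    node_of: dict[str, frozenset] = {}
    for grp in equal_groups:
        for r in grp:
            node_of[r] = grp
    g = nx.DiGraph()
    for grp in equal_groups:
        g.add_node(grp)
    for (i, j) in orders.ordered:
        a = node_of.setdefault(i, frozenset([i]))
        b = node_of.setdefault(j, frozenset([j]))
        if a not in g:
            g.add_node(a)
        if b not in g:
            g.add_node(b)
        if a != b:
            g.add_edge(a, b)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise CyclicOrderError(
            "order digraph contains a cycle (numerical artifact): "
            + " -> ".join(min(e[0]) for e in cycle))
    reduced = nx.transitive_reduction(g)
    dag = OrderDAG(graph=reduced, condition=condition)
    dag.levels = assign_levels(dag)
    return dag


def assign_levels(dag: OrderDAG) -> dict:
    """Level of each node: the longest shortest path from any root.

    level(n) = max over roots r reaching n of the shortest-path edge count
    r -> n; roots (and isolated nodes) get level 0.
    """
    g = dag.graph
    levels = {n: 0 for n in g.nodes}
    for root in dag.roots():
        for node, dist in nx.single_source_shortest_path_length(g, root).items():
            if dist > levels[node]:
                levels[node] = dist
    return levels


def level_partition(dag: OrderDAG,
                    boundaries: tuple[int, int] = (1, 2)) -> LevelPartition:
    """Split nodes into first/middle/last level subsets.

    Defaults: first = level 0, middle = level 1, last = levels >= 2.
    ``boundaries = (a, b)`` puts levels < a in first, [a, b) in middle and
    >= b in last.
    """
    a, b = boundaries
    first, middle, last = set(), set(), set()
    for node, lev in dag.levels.items():
        (first if lev < a else middle if lev < b else last).add(node)
    return LevelPartition(frozenset(first), frozenset(middle), frozenset(last))


def condition_overlap(sets: list[OrderedPairSet]) -> dict:
    """Shared/exclusive ordered-pair counts and pairwise Jaccard distances."""
    if len(sets) < 2:
        raise ValueError("condition_overlap needs at least two conditions")
    names = [s.condition or f"condition_{k}" for k, s in enumerate(sets)]
    pair_sets = [set(s.ordered) for s in sets]
    shared = set.intersection(*pair_sets)
    out: dict = {"n_shared": len(shared), "conditions": names,
                 "exclusive": {}, "jaccard_distance": {}}
    for name, ps in zip(names, pair_sets):
        others = set().union(*(q for q in pair_sets if q is not ps))
        excl = ps - others
        out["exclusive"][name] = {
            "count": len(excl),
            "fraction": len(excl) / len(ps) if ps else float("nan"),
            "shared_fraction": len(shared) / len(ps) if ps else float("nan"),
        }
    for a in range(len(sets)):
        for b in range(a + 1, len(sets)):
            union = pair_sets[a] | pair_sets[b]
            inter = pair_sets[a] & pair_sets[b]
            dist = 1.0 - len(inter) / len(union) if union else 0.0
            out["jaccard_distance"][(names[a], names[b])] = dist
    return out


def biomass_ancestor_subgraph(dag: OrderDAG, biomass_id: str,
                              exclude: set[str] | None = None) -> OrderDAG:
    """Induced subgraph on all ancestors of the biomass reaction.

    These are the reactions whose flux upper-bounds biomass production in
    every steady state.  ``exclude`` removes reactions whose ordering with
    biomass is an artifact of configuration (default: the ATP-maintenance
    pseudo-reaction, whose fixed minimum flux orders it above biomass by
    construction).
    """
    try:
        bio_node = dag.node_of(biomass_id)
    except KeyError as exc:
        raise KeyError(
            f"biomass reaction {biomass_id!r} absent from the DAG") from exc
    exclude = set(exclude) if exclude else set()
    ancestors = nx.ancestors(dag.graph, bio_node)
    kept_nodes = []
    mapping = {}
    for node in ancestors:
        trimmed = frozenset(node - exclude)
        if trimmed:
            kept_nodes.append(node)
            mapping[node] = trimmed
    sub = nx.DiGraph()
    for node in kept_nodes:
        sub.add_node(mapping[node])
    for a, b in dag.graph.subgraph(kept_nodes).edges:
        sub.add_edge(mapping[a], mapping[b])
    out = OrderDAG(graph=sub, condition=dag.condition)
    out.levels = assign_levels(out)
    return out


def find_essential_reactions(model: MetabolicModel,
                             growth_tol: float | None = None,
                             relax_biomass_lb: bool = True) -> set[str]:
    """Reactions whose forced inactivity abolishes biomass production.

    Each reaction in turn is pinned to zero flux and biomass re-maximised;
    essential iff the knockout optimum falls below ``growth_tol`` (default
    1e-6 x the wild-type optimum) or the knockout is infeasible.  By default
    a configured biomass minimum (alpha_b > 0) is relaxed during the scan so
    that essentiality reflects the ability to grow at all, not the ability to
    sustain the configured growth rate.
    """
    if model.biomass_id is None:
        raise ValueError("model has no biomass reaction designated")
    jb = model.index(model.biomass_id)
    saved_lb = model.lower_bounds[jb]
    if relax_biomass_lb:
        model.lower_bounds[jb] = 0.0
    try:
        return _essential_scan(model, growth_tol)
    finally:
        model.lower_bounds[jb] = saved_lb


def _essential_scan(model: MetabolicModel,
                    growth_tol: float | None) -> set[str]:
    wild, _ = lp_core.solve_fba(model, model.biomass_id, sense="max")
    if growth_tol is None:
        growth_tol = 1e-6 * wild
    essential = set()
    for j, rid in enumerate(model.reaction_ids):
        lb0, ub0 = model.lower_bounds[j], model.upper_bounds[j]
        model.lower_bounds[j] = 0.0
        model.upper_bounds[j] = 0.0
        try:
            opt, _ = lp_core.solve_fba(model, model.biomass_id, sense="max")
            if opt < growth_tol:
                essential.add(rid)
        except lp_core.InfeasibleLPError:
            essential.add(rid)
        finally:
            model.lower_bounds[j] = lb0
            model.upper_bounds[j] = ub0
    return essential


def essentiality_order_report(essential: set[str],
                              ancestors: OrderDAG) -> dict:
    """Cross-tabulate biomass-ordered reactions against essential ones.

    Every ancestor of biomass in the order DAG must be essential (zero flux
    through it would force biomass to zero); violations are reported as
    defects rather than silently accepted.
    """
    ordered_rxns = ancestors.reactions()
    violations = sorted(ordered_rxns - set(essential))
    return {
        "n_ordered_and_essential": len(ordered_rxns & set(essential)),
        "n_essential_not_ordered": len(set(essential) - ordered_rxns),
        "violations": violations,
    }
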