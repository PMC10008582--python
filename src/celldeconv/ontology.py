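"""Cell-type ontology graphs and belief propagation of fraction estimates.

A cell-type ontology is a directed acyclic graph of is-a relationships,
stored here as child -> parent edges. Belief propagation sums predicted
fraction mass upwards: each node receives the raw mass of itself plus all
of its distinct descendants, so that mass assigned to a specific subclass
("cd4 t cell") is also captured by the more generic class ("t cell").
Propagated values are "at-or-below" masses and deliberately not a simplex:
every ancestor of a predicted type counts that type's mass once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .types import CellTypeCatalog, DeconvolutionResult, OntologyError

log = logging.getLogger(__name__)


@dataclass
class OntologyGraph:
    """Directed acyclic child -> parent cell-type graph."""

    graph: nx.DiGraph  # edge (child, parent)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise OntologyError(f"ontology contains a cycle through {cycle[0][0]!r}")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def descendants_or_self(self, node: str) -> set[str]:
        """All nodes at or below ``node`` (reachable to it via child->parent)."""
        return {node} | nx.ancestors(self.graph, node)

    def topological_order(self) -> list[str]:
        """Children before parents (roots last)."""
        return list(nx.topological_sort(self.graph))

    def roots(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]


def read_ontology(path) -> OntologyGraph:
    """Read a child<TAB>parent edge list into an :class:`OntologyGraph`.

    Self-loops are rejected; duplicate identical edges are deduplicated with
    a warning; any cycle raises :class:`OntologyError` naming one member.
    """
    g = nx.DiGraph()
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise OntologyError(f"line {ln}: expected child<TAB>parent, got {line!r}")
            child, parent = parts[0].strip(), parts[1].strip()
            if child == parent:
                raise OntologyError(f"line {ln}: self-loop on {child!r}")
            if (child, parent) in seen:
                log.warning("duplicate edge (%s -> %s) deduplicated", child, parent)
                continue
            seen.add((child, parent))
            g.add_edge(child, parent)
    return OntologyGraph(g)


@dataclass
class PropagatedFractions:
    """Accumulated at-or-below mass per ontology node, per sample."""

    values: np.ndarray  # (n_nodes, n_samples)
    node_order: list[str]  # topological (children first)
    sample_ids: list[str]
    raw: DeconvolutionResult = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.node_order, columns=self.sample_ids)


def propagate(fractions: DeconvolutionResult, g: OntologyGraph) -> PropagatedFractions:
    """Sum predicted fraction mass upwards along the ontology.

    value(v) = sum of raw mass over the distinct nodes in {v} + descendants(v).
    DAG-safe: a node reachable through several paths is counted once. On trees
    this reduces to subtree sums; a root covering the whole catalog
    accumulates total mass 1.
    """
    missing = [t for t in fractions.catalog if t not in g.graph]
    if missing:
        raise OntologyError(f"catalog names missing from ontology: {missing}")
    order = g.topological_order()
    node_idx = {n: i for i, n in enumerate(order)}
    n_samples = fractions.fractions.shape[0]
    raw = np.zeros((len(order), n_samples))
    for j, t in enumerate(fractions.catalog):
        raw[node_idx[t]] += fractions.fractions[:, j]
    values = np.zeros_like(raw)
    for n in order:
        below = g.descendants_or_self(n)
        values[node_idx[n]] = raw[[node_idx[u] for u in below]].sum(axis=0)
    return PropagatedFractions(
        values=values,
        node_order=order,
        sample_ids=list(fractions.sample_ids),
        raw=fractions,
    )


def validate_graph(g: OntologyGraph, catalog: CellTypeCatalog) -> dict:
    """Diagnostic report: unmapped catalog names, multi-parent nodes, roots,
    isolated nodes. Never raises."""
    unmapped = [t for t in catalog if t not in g.graph]
    multi_parent = [n for n in g.graph.nodes if g.graph.out_degree(n) > 1]
    isolated = [n for n in g.graph.nodes if g.graph.degree(n) == 0]
    issues = []
    if unmapped:
        issues.append(f"unmapped catalog names: {unmapped}")
    for n in multi_parent:
        issues.append(f"{n!r}: multi-parent (DAG mode)")
    return {
        "unmapped": unmapped,
        "multi_parent": multi_parent,
        "roots": g.roots(),
        "isolated": isolated,
        "issues": issues,
    }
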