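"""Graph data model.

A :class:`Graph` is a node set plus a labelled edge list with a graph-wide
directedness flag and an optional per-edge weight map.  Node identifiers are
opaque, case-sensitive strings (gene symbols are case-significant, so no
normalisation is ever applied).

Conventions:

* In undirected mode the edge ``(a, b)`` and ``(b, a)`` are the same edge,
  stored once under a canonical (lexicographically sorted) endpoint order.
* Duplicate ``(source, target, label)`` triples collapse to a single edge.
* Self-loops are parsed and stored but ignored by every shortest-path
  computation: with positive weights a self-loop can never lie on a shortest
  path, and otherwise it only creates degenerate cycles.
* Weights are keyed by the endpoint pair, not the labelled triple; parallel
  edges that differ only in label therefore share a weight.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .errors import MissingWeightError

logger = logging.getLogger(__name__)

EdgeTriple = tuple[str, str, str]
PairKey = tuple[str, str]


@dataclass(frozen=True)
class WeightMap:
    """A named edge attribute holding real-valued (possibly negative) weights.

    ``entries`` are keyed by ``(source, target)`` as they appeared in the
    input; symmetric lookup for undirected graphs happens at attachment time.
    """

    attribute_name: str
    entries: Mapping[PairKey, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "entries", dict(self.entries))

    def lookup(self, u: str, v: str, directed: bool) -> Optional[float]:
        """Return the weight for edge (u, v), symmetric in undirected mode.

        If an undirected file lists both orientations with different values,
        the minimum wins (shortest paths only ever use the cheapest parallel
        edge) and a warning is logged.
        """
        fwd = self.entries.get((u, v))
        if directed:
            return fwd
        rev = self.entries.get((v, u)) if u != v else None
        if fwd is not None and rev is not None and fwd != rev:
            logger.warning(
                "conflicting weights for undirected edge (%s,%s): %r vs %r; keeping minimum",
                u, v, fwd, rev,
            )
            return min(fwd, rev)
        return fwd if fwd is not None else rev


class Graph:
    """An immutable directed or undirected graph with optional edge weights."""

    __slots__ = ("nodes", "edges", "directed", "weights")

    def __init__(
        self,
        nodes: Iterable[str] = (),
        edges: Iterable[EdgeTriple] = (),
        directed: bool = False,
        weights: Optional[Mapping[PairKey, float]] = None,
    ):
        directed = bool(directed)
        canon_edges: dict[EdgeTriple, None] = {}
        node_set = set(nodes)
        for u, v, label in edges:
            if not directed and v < u:
                u, v = v, u
            canon_edges.setdefault((u, v, label), None)
            node_set.add(u)
            node_set.add(v)
        object.__setattr__(self, "nodes", frozenset(node_set))
        object.__setattr__(self, "edges", tuple(canon_edges))
        object.__setattr__(self, "directed", directed)
        if weights is None:
            object.__setattr__(self, "weights", None)
        else:
            canon_w: dict[PairKey, float] = {}
            for (u, v), w in weights.items():
                key = self.pair_key(u, v)
                if key in canon_w and canon_w[key] != float(w):
                    logger.warning(
                        "conflicting weights for edge (%s,%s): %r vs %r; keeping minimum",
                        key[0], key[1], canon_w[key], float(w),
                    )
                    canon_w[key] = min(canon_w[key], float(w))
                else:
                    canon_w[key] = float(w)
            pairs = self.edge_pairs()
            missing = sorted(pairs - canon_w.keys())
            if missing:
                raise MissingWeightError(missing)
            # drop entries for pairs that are not edges
            object.__setattr__(
                self, "weights", {k: canon_w[k] for k in sorted(pairs)}
            )

    def __setattr__(self, name, value):  # pragma: no cover - immutability guard
        raise AttributeError("Graph is immutable")

    # -- basic queries ----------------------------------------------------

    def pair_key(self, u: str, v: str) -> PairKey:
        """Canonical endpoint pair for an edge (sorted in undirected mode)."""
        if not self.directed and v < u:
            return (v, u)
        return (u, v)

    def edge_pairs(self) -> set[PairKey]:
        """The set of canonical endpoint pairs (labels ignored)."""
        return {(u, v) for u, v, _ in self.edges}

    def has_edge(self, u: str, v: str) -> bool:
        return self.pair_key(u, v) in self.edge_pairs()

    @property
    def is_weighted(self) -> bool:
        return self.weights is not None

    @property
    def has_negative_weights(self) -> bool:
        return self.weights is not None and any(w < 0 for w in self.weights.values())

    def isolated_nodes(self) -> set[str]:
        """Nodes that are no edge endpoint (self-loop endpoints do not count)."""
        touched = {n for u, v, _ in self.edges for n in (u, v)}
        return set(self.nodes) - touched

    def n_edges(self) -> int:
        return len(self.edges)

    # -- derived structures ----------------------------------------------

    def adjacency(self) -> dict[str, list[tuple[str, float]]]:
        """Traversal adjacency: node -> sorted list of (neighbor, weight).

        Unit weights (integer 1) in unweighted mode, so unweighted
        arithmetic stays exact.  Self-loops are skipped; parallel labelled
        edges collapse (they share one weight per pair anyway).
        """
        nbr: dict[str, dict[str, float]] = {n: {} for n in self.nodes}
        for u, v, _label in self.edges:
            if u == v:
                continue
            w = self.weights[(u, v)] if self.weights is not None else 1
            if v not in nbr[u] or w < nbr[u][v]:
                nbr[u][v] = w
            if not self.directed and (u not in nbr[v] or w < nbr[v][u]):
                nbr[v][u] = w
        return {u: sorted(d.items()) for u, d in nbr.items()}

    def without_edge(self, u: str, v: str) -> "Graph":
        """A copy of the graph with every edge between u and v removed."""
        key = self.pair_key(u, v)
        edges = [e for e in self.edges if (e[0], e[1]) != key]
        weights = None
        if self.weights is not None:
            weights = {k: w for k, w in self.weights.items() if k != key}
        return Graph(self.nodes, edges, self.directed, weights)

    # -- equality ---------------------------------------------------------

    def __eq__(self, other):
        if not isinstance(other, Graph):
            return NotImplemented
        return (
            self.directed == other.directed
            and self.nodes == other.nodes
            and set(self.edges) == set(other.edges)
            and self.weights == other.weights
        )

    def __hash__(self):
        return hash((self.directed, self.nodes, frozenset(self.edges)))

    def __repr__(self):
        kind = "directed" if self.directed else "undirected"
        w = ", weighted" if self.is_weighted else ""
        return f"<Graph {kind}{w}: {len(self.nodes)} nodes, {len(self.edges)} edges>"


def attach_weights(graph: Graph, weight_map: WeightMap) -> Graph:
    """Return a weighted copy of *graph*; the original is unmodified.

    Every edge must be covered by the weight map (symmetric lookup in
    undirected mode); missing edges raise :class:`MissingWeightError`
    listing the uncovered pairs rather than silently defaulting.
    """
    resolved: dict[PairKey, float] = {}
    missing: list[PairKey] = []
    for u, v in sorted(graph.edge_pairs()):
        w = weight_map.lookup(u, v, graph.directed)
        if w is None or (isinstance(w, float) and math.isnan(w)):
            missing.append((u, v))
        else:
            resolved[(u, v)] = float(w)
    if missing:
        raise MissingWeightError(missing)
    return Graph(graph.nodes, graph.edges, graph.directed, resolved)
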