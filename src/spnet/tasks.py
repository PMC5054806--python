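"""The three reconstruction tasks.

* :func:`sp_tree` — all shortest paths from one source to every reachable
  node (a "multi" shortest-path tree: a DAG when ties exist).
* :func:`sp_cluster` — all shortest paths among a selected node set; the
  union is a minimal-cost module connecting the selection.
* :func:`connect_isolated` — attach a node of interest to the *nearest*
  members of a node set: only paths to members at the minimum distance are
  returned, and a path may not travel through another member of the set.

Each task returns a :class:`PathSet` (direction-annotated path listings
plus bookkeeping) and the :class:`Subnetwork` extracted as the union of
those paths.

Listing conventions follow the result tables of the original panel-style
workflow: in undirected cluster mode each unordered pair with k unique
paths is listed 2k times (forward and reversed), while tree and connect
results are listed once, oriented away from the source.  Zero-hop self
paths are never listed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .core import DEFAULT_MAX_PATHS, Path, enumerate_paths, shortest_dag, TIE_TOL
from .errors import (
    DisconnectedError,
    IntegrityError,
    SelectionError,
    UnknownNodeError,
)
from .graph import Graph


@dataclass(frozen=True)
class PathRecord:
    """One direction-annotated listing: a path credited to (source, target)."""

    source: str
    target: str
    path: Path


@dataclass(frozen=True)
class PathSet:
    """A task result: listings plus the bookkeeping the statistics need.

    ``selection`` records the nodes the task was asked about (the source
    for a tree, the selected set for a cluster, source plus members for
    connect); ``truncated`` is set when any pair hit the enumeration cap.
    """

    records: tuple[PathRecord, ...]
    mode: str  # "tree" | "cluster" | "connect"
    directed: bool
    weighted: bool
    truncated: bool
    selection: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.records)

    def unique_paths(self) -> list[Path]:
        """Collapse direction duplicates: in undirected mode a forward and
        its reversed listing count as one path."""
        seen: set[tuple[str, ...]] = set()
        out: list[Path] = []
        for rec in self.records:
            key = rec.path.nodes
            if not self.directed:
                key = min(key, tuple(reversed(key)))
            if key not in seen:
                seen.add(key)
                out.append(rec.path)
        return out


@dataclass(frozen=True)
class Subnetwork:
    """An extracted subnetwork together with its originating graph."""

    graph: Graph
    parent: Graph


def _sorted_records(records: Iterable[PathRecord]) -> tuple[PathRecord, ...]:
    return tuple(sorted(records, key=lambda r: (r.source, r.target, r.path.nodes)))


def sp_tree(
    graph: Graph, source: str, max_paths: int = DEFAULT_MAX_PATHS
) -> tuple[PathSet, Subnetwork]:
    """All shortest paths from *source* to every reachable node."""
    dag = shortest_dag(graph, source)
    records: list[PathRecord] = []
    truncated = False
    for target in sorted(dag.dist):
        if target == source:
            continue
        paths, trunc = enumerate_paths(dag, target, max_paths)
        truncated = truncated or trunc
        records.extend(PathRecord(source, target, p) for p in paths)
    pathset = PathSet(
        _sorted_records(records),
        mode="tree",
        directed=graph.directed,
        weighted=graph.is_weighted,
        truncated=truncated,
        selection=(source,),
    )
    return pathset, build_subnetwork(graph, pathset)


def sp_cluster(
    graph: Graph, selected: Iterable[str], max_paths: int = DEFAULT_MAX_PATHS
) -> tuple[PathSet, Subnetwork]:
    """All shortest paths between every pair of the selected nodes.

    Ordered pairs in directed mode; in undirected mode each unordered pair
    contributes the forward listings plus their reversals (the four-row
    display for one two-path pair).
    """
    selection = tuple(sorted(set(selected)))
    if len(selection) < 2:
        raise SelectionError("select two or more nodes")
    for node in selection:
        if node not in graph.nodes:
            raise UnknownNodeError(node)
    records: list[PathRecord] = []
    truncated = False
    if graph.directed:
        for a in selection:
            dag = shortest_dag(graph, a)
            for b in selection:
                if b == a:
                    continue
                paths, trunc = enumerate_paths(dag, b, max_paths)
                truncated = truncated or trunc
                records.extend(PathRecord(a, b, p) for p in paths)
    else:
        for i, a in enumerate(selection):
            if i == len(selection) - 1:
                break
            dag = shortest_dag(graph, a)
            for b in selection[i + 1 :]:
                paths, trunc = enumerate_paths(dag, b, max_paths)
                truncated = truncated or trunc
                for p in paths:
                    records.append(PathRecord(a, b, p))
                    records.append(PathRecord(b, a, p.reversed()))
    pathset = PathSet(
        _sorted_records(records),
        mode="cluster",
        directed=graph.directed,
        weighted=graph.is_weighted,
        truncated=truncated,
        selection=selection,
    )
    return pathset, build_subnetwork(graph, pathset)


def connect_isolated(
    graph: Graph,
    source: str,
    target_set: Iterable[str],
    max_paths: int = DEFAULT_MAX_PATHS,
) -> tuple[PathSet, Subnetwork]:
    """Connect *source* to the nearest members of *target_set*.

    Let ``d*`` be the minimum shortest-path distance from *source* over the
    members.  The result contains, for every member at distance ``d*``,
    every shortest path whose interior contains no member of the set:
    members further away — including members reachable only through other
    members — yield no paths.  The member set itself need not be internally
    connected.
    """
    members = tuple(sorted(set(target_set)))
    if not members:
        raise SelectionError("the target set is empty")
    if source in members:
        raise SelectionError(f"source node {source!r} is part of the target set")
    if source not in graph.nodes:
        raise UnknownNodeError(source)
    for node in members:
        if node not in graph.nodes:
            raise UnknownNodeError(node)
    dag = shortest_dag(graph, source)
    reachable = [m for m in members if m in dag.dist]
    if not reachable:
        raise DisconnectedError(
            f"no member of the target set is reachable from {source!r}"
        )
    tol = TIE_TOL if graph.is_weighted else 0
    d_star = min(dag.dist[m] for m in reachable)
    nearest = [m for m in reachable if dag.dist[m] <= d_star + tol]
    member_set = set(members)
    records: list[PathRecord] = []
    truncated = False
    for m in nearest:
        paths, trunc = enumerate_paths(dag, m, max_paths)
        truncated = truncated or trunc
        for p in paths:
            if member_set.isdisjoint(p.nodes[1:-1]):
                records.append(PathRecord(source, m, p))
    pathset = PathSet(
        _sorted_records(records),
        mode="connect",
        directed=graph.directed,
        weighted=graph.is_weighted,
        truncated=truncated,
        selection=(source,) + members,
    )
    return pathset, build_subnetwork(graph, pathset)


def build_subnetwork(graph: Graph, pathset: PathSet) -> Subnetwork:
    """Extract the union of a PathSet's nodes and edges as a subnetwork.

    Every node and consecutive pair must exist in *graph*, otherwise
    :class:`IntegrityError`; an empty PathSet yields an empty subnetwork.
    """
    node_union: set[str] = set()
    pair_union: set[tuple[str, str]] = set()
    edge_pairs = graph.edge_pairs()
    for rec in pathset.records:
        for node in rec.path.nodes:
            if node not in graph.nodes:
                raise IntegrityError(f"path references unknown node {node!r}")
        node_union.update(rec.path.nodes)
        for a, b in zip(rec.path.nodes, rec.path.nodes[1:]):
            key = graph.pair_key(a, b)
            if key not in edge_pairs:
                raise IntegrityError(f"path references missing edge ({a},{b})")
            pair_union.add(key)
    edges = [e for e in graph.edges if (e[0], e[1]) in pair_union]
    weights = None
    if graph.weights is not None:
        weights = {k: graph.weights[k] for k in pair_union}
    sub = Graph(node_union, edges, graph.directed, weights)
    return Subnetwork(graph=sub, parent=graph)
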