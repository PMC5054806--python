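"""All-shortest-paths core.

The central object is the per-source :class:`PredecessorDag`: shortest-path
distances plus, for every node, the set of *all* predecessors that lie on at
least one shortest path from the source.  Unlike the textbook single-parent
Dijkstra tree, this compactly encodes every shortest path, which is the
quantity of interest when reconstructing subnetworks — two equally cheap
routes through an interactome are two distinct hypotheses.

Distances are computed with Dijkstra (binary heap) for non-negative weights
and with Bellman-Ford as soon as any weight is negative; the predecessor
relation is then recovered in a single clean pass over the edges
(``dist[u] + w(u,v) = dist[v]`` characterises exactly the edges lying on
shortest paths).  Negative-total-weight cycles raise
:class:`~spnet.errors.NegativeCycleError` naming one offending cycle;
zero-total-weight cycles inside the shortest-path subgraph raise
:class:`~spnet.errors.DegenerateCycleError`, because "all shortest paths"
is not a finite set of simple paths in that case.

Everything is single-threaded and deterministic: ties are broken
lexicographically on node identifiers, and two runs on the same input
produce identical orderings.
"""

from __future__ import annotations

import heapq
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping

from .errors import DegenerateCycleError, NegativeCycleError, UnknownNodeError
from .graph import Graph

#: Absolute tolerance for distance-tie detection in weighted mode.  In
#: unweighted mode arithmetic is integral and comparisons are exact.
TIE_TOL = 1e-9

#: Default per-pair enumeration cap.  Shortest-path counts can grow
#: exponentially with graph size; truncation at this cap is deterministic
#: (lexicographic order) and surfaced to callers via a flag.
DEFAULT_MAX_PATHS = 10_000

_INF = math.inf


@dataclass(frozen=True)
class Path:
    """A simple path: ordered node sequence, hop count, total weight.

    ``total_weight`` equals ``hops`` in unweighted mode.
    """

    nodes: tuple[str, ...]
    hops: int
    total_weight: float

    @classmethod
    def from_nodes(cls, nodes, total_weight) -> "Path":
        nodes = tuple(nodes)
        return cls(nodes, len(nodes) - 1, total_weight)

    def reversed(self) -> "Path":
        return Path(tuple(reversed(self.nodes)), self.hops, self.total_weight)

    @property
    def source(self) -> str:
        return self.nodes[0]

    @property
    def target(self) -> str:
        return self.nodes[-1]


@dataclass(frozen=True)
class PredecessorDag:
    """Single-source all-shortest-paths encoding.

    ``dist`` maps each *reachable* node to its total cost from ``source``
    (unreachable nodes are absent).  ``preds[v]`` is the set of neighbours
    ``p`` with ``dist[p] + w(p,v) = dist[v]`` — i.e. every predecessor of
    ``v`` on at least one shortest path.  ``preds[source]`` is empty and
    the relation is acyclic (guaranteed by the zero-cycle guard).
    """

    source: str
    dist: Mapping[str, float]
    preds: Mapping[str, frozenset[str]]


def shortest_dag(graph: Graph, source: str, algorithm: str = "auto") -> PredecessorDag:
    """Compute the full predecessor DAG for one source node.

    ``algorithm`` is ``"auto"`` (Dijkstra unless a negative weight is
    present, then Bellman-Ford), or an explicit ``"dijkstra"`` /
    ``"bellman-ford"``.  Forcing Dijkstra on a negative-weight graph is
    rejected, since the result would be wrong.
    """
    if source not in graph.nodes:
        raise UnknownNodeError(source)
    if algorithm not in ("auto", "dijkstra", "bellman-ford"):
        raise ValueError(f"unknown algorithm: {algorithm!r}")
    adj = graph.adjacency()
    tol = TIE_TOL if graph.is_weighted else 0
    negative = graph.has_negative_weights
    if algorithm == "dijkstra" and negative:
        raise ValueError("Dijkstra is not valid on graphs with negative weights")
    if algorithm == "bellman-ford" or (algorithm == "auto" and negative):
        dist = _bellman_ford(adj, source, tol)
    else:
        dist = _dijkstra(adj, source, tol)
    preds = _shortest_path_preds(adj, dist, source, tol)
    return PredecessorDag(source=source, dist=dist, preds=preds)


def _dijkstra(adj, source, tol):
    dist: dict[str, float] = {}
    pending = {source: 0}
    heap = [(0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in dist:
            continue
        dist[u] = d
        for v, w in adj.get(u, ()):
            if v in dist:
                continue
            nd = d + w
            if nd < pending.get(v, _INF) - tol:
                pending[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


def _bellman_ford(adj, source, tol):
    # deterministic edge order: sorted (u, v)
    edge_list = sorted((u, v, w) for u, nbrs in adj.items() for v, w in nbrs)
    dist: dict[str, float] = {source: 0}
    parent: dict[str, str] = {}
    n = len(adj)
    for _ in range(max(n - 1, 0)):
        changed = False
        for u, v, w in edge_list:
            du = dist.get(u)
            if du is None:
                continue
            nd = du + w
            if nd < dist.get(v, _INF) - tol:
                dist[v] = nd
                parent[v] = u
                changed = True
        if not changed:
            break
    for u, v, w in edge_list:
        du = dist.get(u)
        if du is not None and du + w < dist.get(v, _INF) - tol:
            parent[v] = u
            raise NegativeCycleError(_recover_cycle(parent, v, n))
    return dist


def _recover_cycle(parent, start, n):
    # after n-1 rounds an improvable node's parent chain must enter a cycle
    x = start
    for _ in range(n):
        x = parent[x]
    cycle = [x]
    y = parent[x]
    while y != x:
        cycle.append(y)
        y = parent[y]
    cycle.reverse()
    return cycle


def _shortest_path_preds(adj, dist, source, tol):
    """Recover the all-predecessors relation and guard against zero cycles."""
    cand: dict[str, set[str]] = {v: set() for v in dist}
    for u in dist:
        du = dist[u]
        for v, w in adj.get(u, ()):
            if v in dist and abs(du + w - dist[v]) <= tol:
                cand[v].add(u)
    # Kahn's algorithm over the candidate relation: a cycle can only arise
    # from a zero-total-weight cycle inside the shortest-path subgraph.
    indeg = {v: len(ps) for v, ps in cand.items()}
    succ = defaultdict(list)
    for v, ps in cand.items():
        for p in ps:
            succ[p].append(v)
    queue = [v for v, d in indeg.items() if d == 0]
    seen = 0
    while queue:
        u = queue.pop()
        seen += 1
        for v in succ.get(u, ()):
            indeg[v] -= 1
            if indeg[v] == 0:
                queue.append(v)
    if seen < len(cand):
        stuck = sorted(v for v, d in indeg.items() if d > 0)
        raise DegenerateCycleError(
            "zero-total-weight cycle inside the shortest-path subgraph "
            f"involving nodes: {', '.join(stuck)}; all-shortest-paths is "
            "not a finite set of simple paths here"
        )
    cand[source] = set()
    return {v: frozenset(ps) for v, ps in cand.items()}


def enumerate_paths(
    dag: PredecessorDag, target: str, max_paths: int = DEFAULT_MAX_PATHS
) -> tuple[list[Path], bool]:
    """Enumerate every shortest path from ``dag.source`` to *target*.

    Returns ``(paths, truncated)``.  Paths are emitted in lexicographic
    order of their node sequences; the list is empty when *target* is
    unreachable (a valid result, not an error) and contains the single
    zero-hop path when ``target == dag.source``.  Enumeration stops at
    ``max_paths`` with the truncation flag set.
    """
    if max_paths < 1:
        raise ValueError("max_paths must be >= 1")
    if target not in dag.dist:
        return [], False
    total = dag.dist[target]
    # nodes lying on at least one source->target shortest path
    on_path = {target}
    stack = [target]
    while stack:
        v = stack.pop()
        for p in dag.preds.get(v, ()):
            if p not in on_path:
                on_path.add(p)
                stack.append(p)
    succ: dict[str, list[str]] = defaultdict(list)
    for v in on_path:
        for p in dag.preds.get(v, ()):
            if p in on_path:
                succ[p].append(v)
    for lst in succ.values():
        lst.sort()

    paths: list[Path] = []
    truncated = False
    prefix = [dag.source]

    # forward DFS over the (acyclic) shortest-path subgraph; visiting
    # successors in sorted order yields lexicographic path order
    def dfs(u) -> bool:
        nonlocal truncated
        if u == target:
            if len(paths) >= max_paths:
                truncated = True
                return False
            paths.append(Path.from_nodes(prefix, total))
            return True
        for v in succ.get(u, ()):
            prefix.append(v)
            ok = dfs(v)
            prefix.pop()
            if not ok:
                return False
        return True

    dfs(dag.source)
    return paths, truncated


def all_pairs(
    graph: Graph, max_paths_per_pair: int = DEFAULT_MAX_PATHS
) -> dict[tuple[str, str], list[Path]]:
    """All shortest paths for every ordered node pair (self pairs included).

    Runs :func:`shortest_dag` from every node.  Unreachable pairs map to an
    empty list; the ``(s, s)`` entry is the zero-hop self path.  In
    undirected mode ``paths(t, s)`` are the node-by-node reversals of
    ``paths(s, t)``.
    """
    result: dict[tuple[str, str], list[Path]] = {}
    for s in sorted(graph.nodes):
        dag = shortest_dag(graph, s)
        for t in sorted(graph.nodes):
            paths, _ = enumerate_paths(dag, t, max_paths_per_pair)
            result[(s, t)] = paths
    return result
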