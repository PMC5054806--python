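"""Results-panel statistics.

Four quantities accompany every tree/cluster result: the average path
length, the number of unique shortest paths, the number of *expected*
paths (how many path relations a fully connected network with the same
relevant nodes would develop), and the Connected flag.  A grouped table
counts unique paths per size.

"Unique" always collapses direction duplicates: on an undirected network
the listing s->t and its reversal t->s are one path.  In weighted mode
"size" is the total weight being minimised (hop counts are still carried
on each path); otherwise it is the hop count.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Optional

from .errors import UnknownNodeError
from .graph import Graph
from .tasks import PathSet


@dataclass(frozen=True)
class StatsRecord:
    """The bottom table of a results panel.

    ``average_path_length`` is ``None`` (rendered as NA) when there are no
    paths to average.
    """

    average_path_length: Optional[float]
    unique_paths: int
    expected_paths: int
    connected: bool


def _path_size(path, weighted: bool):
    return path.total_weight if weighted else path.hops


def group_by_length(pathset: PathSet) -> dict:
    """Group unique paths by size: a map size -> count.

    Counts sum to the number of unique paths; in weighted mode sizes are
    rounded to 9 decimals so float ties share a bin, matching the tie
    tolerance of the path search.
    """
    table: dict = {}
    for path in pathset.unique_paths():
        size = _path_size(path, pathset.weighted)
        if pathset.weighted:
            size = round(size, 9)
        table[size] = table.get(size, 0) + 1
    return dict(sorted(table.items()))


def expected_paths(graph: Graph, paths_mode: str, n_relevant: int) -> int:
    """Path relations a fully connected network would develop.

    Tree mode: ``n - 1`` source-to-other relations.  Cluster mode: one per
    unordered pair (undirected) or ordered pair (directed) of the
    selection.
    """
    if n_relevant < 1:
        raise ValueError("n_relevant must be >= 1")
    if paths_mode == "tree":
        return n_relevant - 1
    if paths_mode == "cluster":
        if graph.directed:
            return n_relevant * (n_relevant - 1)
        return n_relevant * (n_relevant - 1) // 2
    raise ValueError(f"unknown paths_mode: {paths_mode!r}")


def _reachable(adj, start) -> set[str]:
    seen = {start}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v, _w in adj.get(u, ()):
            if v not in seen:
                seen.add(v)
                queue.append(v)
    return seen


def is_connected(graph: Graph, mode: str = "global", source: Optional[str] = None) -> bool:
    """Can all nodes communicate by means of a path?

    ``global``: standard connectivity for undirected graphs, strong
    connectivity (every ordered pair communicates) for directed ones.
    ``from_source``: every other node reachable from *source*, respecting
    edge direction.  An empty or single-node graph counts as connected.
    """
    if mode not in ("global", "from_source"):
        raise ValueError(f"unknown connectivity mode: {mode!r}")
    nodes = graph.nodes
    if mode == "from_source":
        if source is None:
            raise ValueError("from_source connectivity requires a source node")
        if source not in nodes:
            raise UnknownNodeError(source)
        return len(_reachable(graph.adjacency(), source)) == len(nodes)
    if len(nodes) <= 1:
        return True
    adj = graph.adjacency()
    root = min(nodes)
    if len(_reachable(adj, root)) != len(nodes):
        return False
    if not graph.directed:
        return True
    radj: dict[str, list[tuple[str, float]]] = {n: [] for n in nodes}
    for u, nbrs in adj.items():
        for v, w in nbrs:
            radj[v].append((u, w))
    return len(_reachable(radj, root)) == len(nodes)


def compute_stats(pathset: PathSet, graph: Graph) -> StatsRecord:
    """Compute the four panel statistics for a tree or cluster result.

    The Connected flag is single-source reachability for a tree and global
    connectivity for a cluster.  Connect-mode results carry no statistics
    panel and are rejected.
    """
    if pathset.mode not in ("tree", "cluster"):
        raise ValueError("statistics are defined for tree and cluster results")
    uniq = pathset.unique_paths()
    n = len(uniq)
    if n == 0:
        average = None
    else:
        average = sum(_path_size(p, pathset.weighted) for p in uniq) / n
    if pathset.mode == "tree":
        expected = expected_paths(graph, "tree", len(graph.nodes))
        connected = is_connected(graph, "from_source", source=pathset.selection[0])
    else:
        expected = expected_paths(graph, "cluster", len(pathset.selection))
        connected = is_connected(graph, "global")
    return StatsRecord(
        average_path_length=average,
        unique_paths=n,
        expected_paths=expected,
        connected=connected,
    )
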