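"""Independent test oracles.

These deliberately share no code with spnet's search: distances come from
a matrix Floyd-Warshall, and path sets from exhaustive DFS over all simple
paths filtered to the minimum total weight.  Both are only feasible on
tiny graphs, which is exactly where the test suite uses them.
"""

from __future__ import annotations

import math

TOL = 1e-9


def edge_weight_lookup(graph):
    """Map (u, v) in traversal direction -> weight (unit weights if none)."""
    table = {}
    for u, v, _label in graph.edges:
        if u == v:
            continue
        w = graph.weights[graph.pair_key(u, v)] if graph.is_weighted else 1
        key = (u, v)
        table[key] = min(table.get(key, math.inf), w)
        if not graph.directed:
            key = (v, u)
            table[key] = min(table.get(key, math.inf), w)
    return table


def floyd_warshall(graph):
    """All-pairs distances by the classic O(n^3) recurrence."""
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    dist = [[math.inf] * n for _ in range(n)]
    for i in range(n):
        dist[i][i] = 0
    for (u, v), w in edge_weight_lookup(graph).items():
        i, j = idx[u], idx[v]
        dist[i][j] = min(dist[i][j], w)
    for k in range(n):
        dk = dist[k]
        for i in range(n):
            dik = dist[i][k]
            if dik == math.inf:
                continue
            row = dist[i]
            for j in range(n):
                alt = dik + dk[j]
                if alt < row[j]:
                    row[j] = alt
    return {
        (a, b): dist[idx[a]][idx[b]]
        for a in nodes
        for b in nodes
        if dist[idx[a]][idx[b]] < math.inf
    }


def brute_force_shortest_paths(graph, source, target):
    """All simple paths source->target, filtered to minimum total weight.

    Returns (min_cost, sorted list of node tuples); (None, []) when the
    target is unreachable.  Exponential: tiny graphs only.
    """
    if source == target:
        return 0, [(source,)]
    weights = edge_weight_lookup(graph)
    adj = {}
    for (u, v), _w in weights.items():
        adj.setdefault(u, []).append(v)
    for lst in adj.values():
        lst.sort()
    found = []

    def dfs(node, visited, path, cost):
        for nxt in adj.get(node, ()):
            if nxt in visited:
                continue
            ncost = cost + weights[(node, nxt)]
            if nxt == target:
                found.append((ncost, tuple(path + [nxt])))
            else:
                visited.add(nxt)
                dfs(nxt, visited, path + [nxt], ncost)
                visited.remove(nxt)

    dfs(source, {source}, [source], 0)
    if not found:
        return None, []
    best = min(c for c, _ in found)
    paths = sorted(p for c, p in found if c <= best + TOL)
    return best, paths


def random_tree_edges(n, rng):
    """A uniform-ish random tree: node i attaches to a random earlier node."""
    edges = []
    for i in range(2, n + 1):
        j = int(rng.integers(1, i))
        edges.append((str(j), str(i), "pp"))
    return edges
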