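"""Bundled example networks and a seeded random-graph generator.

The three demo networks are small hand-curated graphs exercising every
task the library offers; they double as the reference inputs of the test
suite and the worked examples in the README.

``cluster_demo`` and ``connect_demo`` intentionally share one topology
(ten nodes, fourteen undirected edges): it simultaneously exhibits two
equal-cost four-hop routes between nodes 1 and 9, global connectivity,
and a node 6 whose nearest members of the set {8, 9, 10} are 8 and 10
(node 9 lies further away, behind them).  ``directed_demo`` is a five-node
directed network in which every node is reachable from node 1 while
node 1 is unreachable from nodes 2 and 3.

The random generator draws Erdős–Rényi graphs from numpy's PCG64 stream,
a PRNG whose algorithm is fixed and documented, so a (parameters, seed)
pair yields an identical graph on every platform and run order.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import numpy as np

from .graph import Graph
from .io import read_sif


def _load(name: str, directed: bool) -> Graph:
    ref = resources.files(__package__).joinpath("data", name)
    with ref.open("r", encoding="utf-8") as fh:
        return read_sif(fh, directed=directed)


def cluster_demo() -> Graph:
    """Ten-node, fourteen-edge undirected demo for pairwise path retrieval.

    Nodes 1 and 9 are linked by exactly two shortest paths, both of four
    hops: 1-8-7-4-9 and 1-8-10-4-9.
    """
    return _load("cluster_demo.sif", directed=False)


def connect_demo() -> Graph:
    """Demo for attaching node 6 to the node set {8, 9, 10}.

    Same topology as :func:`cluster_demo`; the nearest members of the set
    are 8 and 10 (one single-hop path each), while node 9 sits behind them.
    """
    return _load("connect_demo.sif", directed=False)


def directed_demo() -> Graph:
    """Five-node directed demo with one-way reachability.

    All nodes are reachable from node 1, but node 1 has in-degree zero, so
    it can never be reached from nodes 2 or 3.
    """
    return _load("directed_demo.sif", directed=True)


def random_graph(
    n: int,
    edge_prob: float,
    directed: bool = False,
    weighted: bool = False,
    weight_range: tuple[float, float] = (0.5, 2.0),
    seed: int = 0,
) -> Graph:
    """Seeded Erdős–Rényi graph G(n, p) with optional uniform weights.

    Nodes are the strings ``"1"`` .. ``"n"``.  Each unordered (or ordered,
    when directed) pair becomes an edge independently with probability
    *edge_prob*; weights are drawn uniformly from *weight_range*.  The
    draw order over pairs is fixed, so identical inputs and seed give an
    identical graph.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 < edge_prob <= 1):
        raise ValueError("edge_prob must be in (0, 1]")
    lo, hi = float(weight_range[0]), float(weight_range[1])
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
        raise ValueError("weight_range must be a finite (low, high) interval")
    rng = np.random.Generator(np.random.PCG64(seed))
    node_ids = [str(i) for i in range(1, n + 1)]
    label = "pd" if directed else "pp"
    edges: list[tuple[str, str, str]] = []
    weights: Optional[dict] = {} if weighted else None
    for i in range(1, n + 1):
        start = 1 if directed else i + 1
        for j in range(start, n + 1):
            if j == i:
                continue
            if rng.random() < edge_prob:
                u, v = str(i), str(j)
                edges.append((u, v, label))
                if weighted:
                    key = (u, v) if directed or v >= u else (v, u)
                    weights[key] = float(rng.uniform(lo, hi))
    return Graph(node_ids, edges, directed=directed, weights=weights)
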