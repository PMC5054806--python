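# Methods

## Problem setting

Interaction networks — protein–protein interactomes, signalling maps,
gene-regulatory graphs — are commonly analysed under a maximum-parsimony
assumption: information flow between two components follows the cheapest
route(s) available. A single shortest path is an arbitrary pick whenever
ties exist, and ties are ubiquitous in unweighted biological networks, so
`spnet` treats the *set of all shortest paths* between a pair as the unit
of analysis, and builds its three reconstruction tasks (tree, cluster,
connect-isolated) on that primitive.

## Graph model

A graph is a set of opaque, case-sensitive string node identifiers plus a
list of `(source, target, interaction-label)` edges, with one graph-wide
directedness flag and an optional weight map keyed by endpoint pair.
Choices where the format itself is silent:

* SIF carries no direction semantics, so directedness is a load-time flag,
  not inferred from the file.
* Tokenisation is whitespace-based (Cytoscape accepts both tab- and
  space-delimited SIF); a file mixing both per line still parses. This
  implies node identifiers cannot contain whitespace.
* Duplicate `(source, target, label)` triples collapse to one edge.
  Duplicate weight entries for one edge keep the minimum and log a
  warning: shortest paths only ever use the cheapest parallel edge, so
  any other resolution could not influence a result anyway.
* Self-loops are stored (they round-trip through SIF) but ignored by all
  path computations: with positive weights a self-loop is never on a
  shortest path, and with zero/negative weights it only creates the
  degenerate cycles rejected below.
* In undirected mode an edge is stored once under lexicographically
  sorted endpoints, and weight lookup is symmetric. Missing weights are a
  hard error at attachment time listing the uncovered edges — silently
  defaulting a weight would silently change every downstream distance.

## All-shortest-paths search

Distances from a source are computed with a binary-heap Dijkstra when all
weights are non-negative, and with Bellman–Ford (deterministic sorted edge
order, early exit) otherwise. The all-predecessors relation is recovered
in a separate pass: `u` is a predecessor of `v` iff `(u,v)` is an edge and
`d(u) + w(u,v) = d(v)`. This equation exactly characterises the edges
lying on at least one shortest path, so the relation — the shortest-path
DAG — encodes every shortest path from the source. Enumeration is a
forward depth-first traversal of the DAG restricted to nodes from which
the target is reachable, visiting successors in lexicographic order, so
paths emerge in lexicographic order of their node sequences without a
post-hoc sort.

Numerical and degenerate-input choices:

* **Tie tolerance.** Distance equality is exact in unweighted mode
  (integer arithmetic) and within an absolute 1e-9 in weighted mode, both
  for relaxation and for the predecessor equation, giving reproducible tie
  detection across platforms.
* **Negative weights.** Dijkstra is incorrect under negative weights, so
  any negative weight selects Bellman–Ford. A negative-total-weight cycle
  reachable from the source raises `NegativeCycleError` naming one cycle
  (recovered from the parent chain after the detection round). Note that
  in undirected mode any reachable negative edge is itself a negative
  closed walk (u→v→u), so undirected negative weights always error:
  negative weights are effectively a directed-network feature.
* **Zero-weight cycles.** If a zero-total-weight cycle lies inside the
  shortest-path DAG (e.g. a zero-weight edge in both directions between
  two equidistant nodes), "all shortest paths" is an infinite set of
  walks. The predecessor relation is checked for acyclicity with Kahn's
  algorithm and such inputs raise `DegenerateCycleError` rather than
  enumerate unboundedly. Zero-weight edges as such are fine.
* **Enumeration cap.** Shortest-path counts grow exponentially in the
  worst case, so enumeration truncates at `max_paths` (default 10 000 per
  pair). Because emission order is lexicographic and deterministic, the
  truncated prefix is reproducible; a `truncated` flag propagates to the
  task result and the CLI warns that statistics are lower bounds.
* Everything is single-threaded; results are independent of any
  scheduling by construction.

## Task semantics

* **tree(source)** lists every shortest path from the source to each
  reachable node, excluding the zero-hop self path. The subnetwork is the
  union of the listed paths; its node set is exactly the set of nodes
  reachable from the source (when at least one other node is reachable).
* **cluster(selection)** requires at least two distinct nodes (duplicates
  are removed first). Undirected: each unordered pair with k unique paths
  contributes 2k listings — forward plus node-by-node reversals — so one
  two-path pair displays as four rows; directed: all ordered pairs are
  computed independently. The doubling is applied in cluster mode only:
  a tree is inherently oriented away from its source, and the connect
  task's documented output counts single listings.
* **connect(source, members)** computes d\* = min over members of
  d(source, member), errors if no member is reachable, and returns, for
  every member at distance d\* (within the tie tolerance), every shortest
  path whose interior contains no member of the set. With positive
  weights an interior member would itself be closer than d\*, so the
  interior filter is provably redundant there; it is kept because it is
  the semantic definition ("connect to the *nearest* members, not through
  the set") and it matters under zero weights. Members further than d\*,
  including members whose routes pass through other members, yield no
  paths. The member set need not be internally connected. Connect
  results carry no statistics panel (the four statistics are defined for
  tree and cluster results); `compute_stats` rejects them and the CLI
  writes only the path table and subnetwork.

**Closure.** For every task, the extracted subnetwork preserves distances
between listed endpoints (all shortest-path edges are included, and a
subgraph cannot shorten a distance), so re-running the task on its own
subnetwork reproduces the identical listings. For connect, the selection
must first be restricted to the members present in the subnetwork —
non-nearest members contributed no paths and are therefore absent by the
subnetwork's own invariant (every node lies on a listed path).

## Statistics

* **Unique paths** collapse direction duplicates: on an undirected
  network a listing and its reversal are one path (canonical form:
  lexicographic minimum of the sequence and its reverse).
* **Average path length** is the mean *size* over unique paths — hop
  count in unweighted mode, total weight in weighted mode, since size
  must reflect the optimised quantity. It is undefined (NA) with zero
  paths. The grouped length table counts unique paths per size (weighted
  sizes rounded to 9 decimals so float ties share a bin, matching the
  search's tie tolerance).
* **Expected paths** — the relations a fully connected network would
  develop: n−1 for a tree over the n-node graph, k(k−1)/2 or k(k−1) for
  an (un)directed selection of k. This counting is the only one
  consistent with "if it were fully connected".
* **Connected** — for a tree, reachability of every node from the source
  (respecting direction); for a cluster, global connectivity, which for
  directed graphs is taken as strong connectivity (every ordered pair
  communicates), consistent with "all nodes able to communicate".

## Demo networks and the synthetic generator

The bundled demo networks are hand-curated, not measured data. The
cluster/connect demos share one 10-node, 14-edge undirected topology that
simultaneously exhibits: exactly two equal-cost 4-hop routes between
nodes 1 and 9 (through 7 and through 10, sharing first and last edges),
global connectivity, and a node 6 whose nearest members of {8, 9, 10}
are 8 and 10 at one hop while 9 sits three hops away behind member 10.
The directed demo is a five-node network (1→2, 1→3, 2→4, 3→4, 4→5, 5→2)
where everything is reachable from node 1 but node 1, having in-degree
zero, is unreachable from nodes 2 and 3.

The random generator draws Erdős–Rényi G(n, p) graphs with optional
uniform weights from numpy's PCG64 stream — a documented, fixed PRNG
algorithm, so a (parameters, seed) pair reproduces the identical graph on
any platform, and the pair-iteration order is fixed. The oracle-based
tests sweep n = 4..10 with p in {0.2, 0.3, 0.4}, crossing
directed/undirected with unweighted/positive-weighted (weights uniform in
[0.5, 2.0]); these sizes keep exhaustive simple-path enumeration — the
brute-force oracle — tractable while covering ties, unreachable pairs and
disconnected instances. What passing these tests shows is correctness of
the search and task semantics, not performance or statistical behaviour
on real interactomes: Erdős–Rényi graphs are not scale-free, have no
degree hubs, and at these sizes cannot probe memory or runtime scaling.

## Limitations

* Exhaustive all-paths enumeration is exponential in the worst case; the
  cap bounds work but then statistics are lower bounds (flagged).
* No k-shortest-paths (beyond ties), no heuristic/A* search, no Steiner
  trees; no GraphML/XGMML readers — SIF plus two weight-table dialects
  only.
* Weighted sizes are reported to 9 significant digits; weights of wildly
  different magnitudes may render coarsely in tables, though internal
  comparisons always use full precision.
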