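# spnet — shortest-path network reconstruction

`spnet` reconstructs and analyses subnetworks of molecular interaction
networks based on the shortest-path principle. Given an interactome (or any
graph in Cytoscape SIF format) it enumerates **all** shortest paths — not an
arbitrary single one — between node pairs, and offers three reconstruction
tasks built on that primitive:

* **tree** — all shortest paths from one source node to every reachable
  node (a "multi" shortest-path tree; a DAG when equal-cost ties exist);
* **cluster** — all shortest paths among a selected node set, whose union
  is a minimal-cost module connecting the selection (e.g. a gene list);
* **connect** — attach an isolated node of interest to the *nearest*
  members of a node set, returning only the shortest paths to members at
  the minimum distance and discarding paths that travel through other
  members of the set.

Each task returns the direction-annotated path listings, the extracted
subnetwork (the union of the paths), and — for tree and cluster — the
results-panel statistics: the average path length, the number of unique
shortest paths, the number of *expected* paths, and the Connected flag.

It is aimed at systems-biology workflows where information flow is assumed
to follow maximum parsimony: competing equal-cost routes through an
interactome are competing mechanistic hypotheses, so all of them matter.

## Method

For a source $s$ in a graph $G=(V,E)$ with edge weights $w$ (unit weights
when none are given), `spnet` computes the distances $d(s,v)$ with
Dijkstra's algorithm, switching to Bellman–Ford as soon as any weight is
negative. The *all-predecessors* relation

$$\mathrm{pred}(v) = \{\, u : (u,v) \in E,\; d(s,u) + w(u,v) = d(s,v) \,\}$$

(evaluated within an absolute tolerance of $10^{-9}$ in weighted mode)
defines the shortest-path DAG, which compactly encodes *every* shortest
path from $s$; paths are enumerated from it by depth-first traversal in
lexicographic order, with a deterministic cap (default 10 000 per pair).
Negative-total-weight cycles raise an error naming one cycle;
zero-total-weight cycles inside the shortest-path DAG are also rejected,
because "all shortest paths" is not a finite set of simple paths there.

The expected-paths statistic counts the path relations a fully connected
network would develop: $n-1$ for a tree over $n$ nodes, $\binom{k}{2}$
(undirected) or $k(k-1)$ (directed) for a selection of $k$ nodes. The
Connected flag reports reachability of all nodes from the source (tree)
or global connectivity (cluster; strong connectivity when directed).

## Worked example

The package ships three small demo networks. `cluster_demo` has ten nodes
and fourteen undirected edges, with two equal-cost routes between nodes 1
and 9:

```
$ python -c "from spnet import datasets, write_sif; import sys; write_sif(datasets.cluster_demo(), sys.stdout)" > net.sif
$ spnet cluster --network net.sif --out run1 1 9
4 path listings (2 unique) -> run1.paths.tsv, run1.subnet.sif, run1.stats.tsv

$ cat run1.paths.tsv
source	target	size	path
1	9	4	1|8|10|4|9
1	9	4	1|8|7|4|9
9	1	4	9|4|10|8|1
9	1	4	9|4|7|8|1

$ cat run1.stats.tsv
average_path_length	4
unique_paths	2
expected_paths	1
connected	True
paths_of_size_4	2
```

Because the network is undirected, the path 1→9 and its reversal 9→1 are
the same path: four listings, two unique paths, both of size (hop length)
4, hence the average path length of 4. `run1.subnet.sif` holds the
extracted subnetwork — the six nodes and six edges lying on those paths.

Connecting node 6 to the set {8, 9, 10} illustrates the nearest-member
rule — node 9 is further from 6 than members 8 and 10, so it is not a
target:

```
$ spnet connect --network net.sif --source 6 -m 8 -m 9 -m 10 --out c1
2 path listings (2 unique) -> c1.paths.tsv, c1.subnet.sif

$ cat c1.paths.tsv
source	target	size	path
6	10	1	6|10
6	8	1	6|8
```

The same operations are available as library functions
(`spnet.sp_tree`, `spnet.sp_cluster`, `spnet.connect_isolated`,
`spnet.compute_stats`, ...) returning `PathSet`, `Subnetwork` and
`StatsRecord` objects. `spnet synth` emits seeded Erdős–Rényi networks
for benchmarking and testing.

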