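"""All-shortest-paths core: distances, predecessor DAG, enumeration."""

import math

import networkx as nx
import pytest

from spnet import (
    DegenerateCycleError,
    Graph,
    NegativeCycleError,
    UnknownNodeError,
    all_pairs,
    enumerate_paths,
    read_sif,
    shortest_dag,
)
from conftest import seeded_instances
from helpers_oracles import (
    TOL,
    brute_force_shortest_paths,
    edge_weight_lookup,
    floyd_warshall,
)


def path_nodes(paths):
    return sorted(p.nodes for p in paths)


class TestShortestDag:
    def test_line_graph(self):
        g = read_sif("A pp B\nB pp C\n")
        dag = shortest_dag(g, "A")
        assert dag.dist == {"A": 0, "B": 1, "C": 2}
        assert dag.preds["B"] == {"A"} and dag.preds["C"] == {"B"}
        assert dag.preds["A"] == frozenset()

    def test_unreachable_nodes_absent(self, directed_net):
        dag = shortest_dag(directed_net, "2")
        assert "1" not in dag.dist and "1" not in dag.preds
        assert "3" not in dag.dist

    def test_unknown_source(self, cluster_net):
        with pytest.raises(UnknownNodeError):
            shortest_dag(cluster_net, "nope")

    def test_equal_cost_predecessors_all_kept(self, cluster_net):
        dag = shortest_dag(cluster_net, "1")
        assert dag.preds["4"] == {"7", "10"}
        assert dag.preds["5"] == {"3", "6", "7"}

    def test_pred_weight_identity(self):
        # every predecessor must close the distance equation
        for g in seeded_instances(30, base_seed=50):
            weights = edge_weight_lookup(g)
            for src in sorted(g.nodes)[:3]:
                dag = shortest_dag(g, src)
                for v, ps in dag.preds.items():
                    for p in ps:
                        assert abs(dag.dist[p] + weights[(p, v)] - dag.dist[v]) <= TOL

    def test_distances_match_floyd_warshall(self):
        for g in seeded_instances(40, base_seed=1000):
            fw = floyd_warshall(g)
            for src in sorted(g.nodes):
                dag = shortest_dag(g, src)
                expect = {t: d for (s, t), d in fw.items() if s == src}
                assert dag.dist.keys() == expect.keys()
                for t, d in expect.items():
                    assert dag.dist[t] == pytest.approx(d, abs=1e-9)

    def test_distances_match_networkx(self):
        for g in seeded_instances(10, base_seed=77):
            nxg = nx.DiGraph() if g.directed else nx.Graph()
            nxg.add_nodes_from(g.nodes)
            for (u, v), w in edge_weight_lookup(g).items():
                nxg.add_edge(u, v, weight=w)
            for src in sorted(g.nodes)[:2]:
                dag = shortest_dag(g, src)
                nx_dist = nx.single_source_dijkstra_path_length(nxg, src)
                assert dag.dist.keys() == nx_dist.keys()
                for t in nx_dist:
                    assert dag.dist[t] == pytest.approx(nx_dist[t], abs=1e-9)


class TestEnumeration:
    def test_worked_example_two_paths(self, cluster_net):
        dag = shortest_dag(cluster_net, "1")
        paths, truncated = enumerate_paths(dag, "9")
        assert not truncated
        assert path_nodes(paths) == [
            ("1", "8", "10", "4", "9"),
            ("1", "8", "7", "4", "9"),
        ]
        assert all(p.hops == 4 and p.total_weight == 4 for p in paths)

    def test_target_equals_source(self, cluster_net):
        dag = shortest_dag(cluster_net, "1")
        paths, _ = enumerate_paths(dag, "1")
        assert len(paths) == 1 and paths[0].nodes == ("1",) and paths[0].hops == 0

    def test_unreachable_target_is_empty_not_error(self, directed_net):
        dag = shortest_dag(directed_net, "2")
        paths, truncated = enumerate_paths(dag, "1")
        assert paths == [] and not truncated

    def test_lexicographic_order_and_determinism(self):
        for g in seeded_instances(10, base_seed=4):
            for src in sorted(g.nodes)[:2]:
                dag1 = shortest_dag(g, src)
                dag2 = shortest_dag(g, src)
                for t in sorted(g.nodes):
                    p1, _ = enumerate_paths(dag1, t)
                    p2, _ = enumerate_paths(dag2, t)
                    assert [p.nodes for p in p1] == [p.nodes for p in p2]
                    assert [p.nodes for p in p1] == sorted(p.nodes for p in p1)

    def test_truncation_cap_and_flag(self):
        # ladder of diamonds: 2^4 = 16 equal shortest paths
        lines = []
        for i in range(4):
            lines += [f"n{i} pp a{i}", f"n{i} pp b{i}", f"a{i} pp n{i+1}", f"b{i} pp n{i+1}"]
        g = read_sif("\n".join(lines))
        dag = shortest_dag(g, "n0")
        full, trunc = enumerate_paths(dag, "n4")
        assert len(full) == 16 and not trunc
        capped, trunc = enumerate_paths(dag, "n4", max_paths=5)
        assert len(capped) == 5 and trunc
        assert [p.nodes for p in capped] == [p.nodes for p in full[:5]]

    def test_brute_force_oracle(self):
        for g in seeded_instances(40, base_seed=2000):
            for src in sorted(g.nodes)[:3]:
                dag = shortest_dag(g, src)
                for t in sorted(g.nodes):
                    if t == src:
                        continue
                    cost, expected = brute_force_shortest_paths(g, src, t)
                    paths, _ = enumerate_paths(dag, t)
                    assert path_nodes(paths) == expected
                    if cost is not None:
                        assert dag.dist[t] == pytest.approx(cost, abs=1e-9)

    def test_path_weight_equals_distance(self):
        for g in seeded_instances(20, base_seed=3000):
            weights = edge_weight_lookup(g)
            src = min(g.nodes)
            dag = shortest_dag(g, src)
            for t in sorted(dag.dist):
                paths, _ = enumerate_paths(dag, t)
                for p in paths:
                    total = sum(weights[(a, b)] for a, b in zip(p.nodes, p.nodes[1:]))
                    assert abs(total - dag.dist[t]) <= TOL
                    assert abs(p.total_weight - dag.dist[t]) <= TOL
                    assert len(set(p.nodes)) == len(p.nodes)  # simple


class TestAlgorithmBranches:
    def test_dijkstra_bellman_ford_agree(self):
        for g in seeded_instances(30, base_seed=4000):
            for src in sorted(g.nodes)[:2]:
                a = shortest_dag(g, src, algorithm="dijkstra")
                b = shortest_dag(g, src, algorithm="bellman-ford")
                assert a == b

    def test_unit_weights_equal_unweighted(self):
        for g in seeded_instances(10, base_seed=5000):
            if g.is_weighted:
                continue
            unit = Graph(g.nodes, g.edges, g.directed, {(u, v): 1.0 for u, v in g.edge_pairs()})
            for src in sorted(g.nodes):
                du = shortest_dag(g, src)
                dw = shortest_dag(unit, src)
                assert du.dist == dw.dist and du.preds == dw.preds

    def test_dijkstra_refused_on_negative_weights(self):
        g = Graph(edges=[("a", "b", "pd")], directed=True, weights={("a", "b"): -1.0})
        with pytest.raises(ValueError):
            shortest_dag(g, "a", algorithm="dijkstra")

    def test_negative_weights_correct_on_dag(self):
        # b is cheaper through the negative detour a->c->b than directly
        g = Graph(
            edges=[("a", "b", "pd"), ("a", "c", "pd"), ("c", "b", "pd")],
            directed=True,
            weights={("a", "b"): 1.0, ("a", "c"): 2.0, ("c", "b"): -1.5},
        )
        dag = shortest_dag(g, "a")
        assert dag.dist["b"] == pytest.approx(0.5)
        assert dag.preds["b"] == {"c"}

    def test_negative_cycle_error_names_cycle(self):
        g = Graph(
            edges=[("s", "a", "pd"), ("a", "b", "pd"), ("b", "a", "pd")],
            directed=True,
            weights={("s", "a"): 1.0, ("a", "b"): 1.0, ("b", "a"): -3.0},
        )
        with pytest.raises(NegativeCycleError) as exc:
            shortest_dag(g, "s")
        assert set(exc.value.cycle) == {"a", "b"}

    def test_undirected_negative_edge_is_negative_cycle(self):
        g = Graph(edges=[("a", "b", "pp")], directed=False, weights={("a", "b"): -1.0})
        with pytest.raises(NegativeCycleError):
            shortest_dag(g, "a")

    def test_unreachable_negative_cycle_ignored(self):
        g = Graph(
            edges=[("s", "t", "pd"), ("a", "b", "pd"), ("b", "a", "pd")],
            directed=True,
            weights={("s", "t"): 1.0, ("a", "b"): 1.0, ("b", "a"): -3.0},
        )
        assert shortest_dag(g, "s").dist == {"s": 0, "t": 1.0}

    def test_zero_weight_cycle_on_shortest_path_raises(self):
        g = Graph(
            edges=[("s", "a", "pd"), ("a", "b", "pd"), ("b", "a", "pd")],
            directed=True,
            weights={("s", "a"): 1.0, ("a", "b"): 0.0, ("b", "a"): 0.0},
        )
        with pytest.raises(DegenerateCycleError):
            shortest_dag(g, "s")

    def test_zero_weight_edge_without_cycle_is_fine(self):
        g = Graph(
            edges=[("s", "a", "pd"), ("a", "b", "pd")],
            directed=True,
            weights={("s", "a"): 0.0, ("a", "b"): 0.0},
        )
        dag = shortest_dag(g, "s")
        assert dag.dist == {"s": 0, "a": 0.0, "b": 0.0}


class TestAllPairs:
    def test_single_node_graph(self):
        g = Graph(nodes=["x"])
        pairs = all_pairs(g)
        assert list(pairs) == [("x", "x")]
        assert pairs[("x", "x")][0].nodes == ("x",)

    def test_undirected_symmetry(self):
        for g in seeded_instances(10, base_seed=6000):
            if g.directed:
                continue
            pairs = all_pairs(g)
            for (s, t), paths in pairs.items():
                rev = sorted(tuple(reversed(p.nodes)) for p in paths)
                assert rev == sorted(p.nodes for p in pairs[(t, s)])

    def test_matches_networkx_all_shortest_paths(self, cluster_net):
        nxg = nx.Graph()
        nxg.add_nodes_from(cluster_net.nodes)
        nxg.add_edges_from(cluster_net.edge_pairs())
        pairs = all_pairs(cluster_net)
        for s in sorted(cluster_net.nodes):
            for t in sorted(cluster_net.nodes):
                if s == t:
                    continue
                expected = sorted(tuple(p) for p in nx.all_shortest_paths(nxg, s, t))
                assert path_nodes(pairs[(s, t)]) == expected
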