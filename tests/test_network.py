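"""Network construction, topology indices, module detection."""

import itertools

import networkx as nx
import numpy as np
import pytest

from pmen.network import (build_network, degree_frequency_r2, detect_modules,
                          global_indices, modularity_q, module_composition,
                          power_law_r2)
from pmen.similarity import SimilarityMatrix

from conftest import bfs_distances, make_network


def _sim(matrix, signs=None):
    matrix = np.asarray(matrix, float)
    signs = np.ones_like(matrix, dtype=int) if signs is None else np.asarray(signs)
    return SimilarityMatrix([f"o{i}" for i in range(len(matrix))], matrix, signs)


class TestBuildNetwork:
    def test_threshold_rule_is_inclusive(self):
        sim = _sim([[1, 0.9, 0.3], [0.9, 1, 0.7], [0.3, 0.7, 1]])
        net = build_network(sim, 0.66)
        assert net.n_nodes == 3 and net.n_edges == 2
        assert net.graph.has_edge("o0", "o1") and net.graph.has_edge("o1", "o2")
        # boundary: weight exactly at the threshold is kept
        net_b = build_network(sim, 0.7)
        assert net_b.graph.has_edge("o1", "o2")

    def test_isolated_nodes_dropped(self):
        sim = _sim([[1, 0.9, 0.1], [0.9, 1, 0.1], [0.1, 0.1, 1]])
        net = build_network(sim, 0.66)
        assert set(net.nodes) == {"o0", "o1"}

    def test_signs_carried_from_similarity(self):
        sim = _sim([[1, 0.9], [0.9, 1]], signs=[[1, -1], [-1, 1]])
        net = build_network(sim, 0.5)
        assert net.graph.edges["o0", "o1"]["sign"] == -1
        assert net.negative_fraction() == 1.0

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            build_network(_sim(np.eye(4)), 0.66)

    @pytest.mark.parametrize("st", [0.0, 1.5])
    def test_threshold_out_of_range_rejected(self, st):
        with pytest.raises(ValueError):
            build_network(_sim(np.eye(2)), st)


class TestGlobalIndices:
    def test_triangle(self):
        net = make_network([("a", "b"), ("b", "c"), ("a", "c")])
        idx = global_indices(net)
        assert idx.average_degree == pytest.approx(2.0)
        assert idx.average_path_distance == pytest.approx(1.0)
        assert idx.average_clustering == pytest.approx(1.0)
        assert idx.harmonic_geodesic_distance == pytest.approx(1.0)

    def test_three_node_path(self):
        net = make_network([("a", "b"), ("b", "c")])
        idx = global_indices(net)
        assert idx.average_path_distance == pytest.approx(4 / 3)
        assert idx.harmonic_geodesic_distance == pytest.approx(1.2)

    def test_average_degree_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            g = nx.gnp_random_graph(30, 0.15, seed=int(rng.integers(1 << 30)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_edges() == 0:
                continue
            net = make_network(list(g.edges()))
            idx = global_indices(net)
            assert idx.average_degree == pytest.approx(
                2 * idx.total_links / idx.network_size, abs=1e-12)

    def test_distances_match_brute_force_bfs_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            g = nx.gnp_random_graph(int(rng.integers(8, 41)), 0.15,
                                    seed=int(rng.integers(1 << 30)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_edges() < 2:
                continue
            net = make_network(list(g.edges()))
            idx = global_indices(net)
            adj = {u: set(g.neighbors(u)) for u in g}
            total = reciprocal = pairs = 0
            nodes = list(g)
            for u in nodes:
                dist = bfs_distances(adj, u)
                for v in nodes:
                    if v != u and v in dist:
                        total += dist[v]
                        reciprocal += 1.0 / dist[v]
                        pairs += 1
            n = len(nodes)
            assert idx.average_path_distance == pytest.approx(total / pairs)
            assert idx.harmonic_geodesic_distance == pytest.approx(
                n * (n - 1) / reciprocal)
            # clustering against the direct triangle formula
            expected_c = []
            for u in nodes:
                k = len(adj[u])
                if k < 2:
                    expected_c.append(0.0)
                    continue
                links = sum(1 for a, b in itertools.combinations(adj[u], 2)
                            if b in adj[a])
                expected_c.append(2 * links / (k * (k - 1)))
            assert idx.average_clustering == pytest.approx(np.mean(expected_c))

    def test_harmonic_never_exceeds_average_path_on_connected_graphs(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            g = nx.connected_watts_strogatz_graph(20, 4, 0.3,
                                                  seed=int(rng.integers(1 << 30)))
            idx = global_indices(make_network(list(g.edges())))
            assert idx.harmonic_geodesic_distance <= idx.average_path_distance + 1e-12


class TestModules:
    def test_two_disjoint_triangles(self):
        net = make_network([("a", "b"), ("b", "c"), ("a", "c"),
                            ("x", "y"), ("y", "z"), ("x", "z")])
        part = detect_modules(net)
        assert part.n_modules == 2
        assert part.q == pytest.approx(0.5)

    def test_complete_graph_single_module(self):
        net = make_network([(i, j) for i, j in itertools.combinations(range(5), 2)])
        part = detect_modules(net)
        assert part.n_modules == 1
        assert part.q == pytest.approx(0.0)

    def test_greedy_q_equals_direct_formula_and_igraph(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            g = nx.gnp_random_graph(40, 0.1, seed=int(rng.integers(1 << 30)))
            g.remove_nodes_from(list(nx.isolates(g)))
            net = make_network(list(g.edges()))
            part = detect_modules(net)
            assert part.q == pytest.approx(
                modularity_q(net.graph, part.membership), abs=1e-12)
            # independent cross-check with igraph's modularity evaluation
            import igraph as ig

            nodes = sorted(net.graph.nodes)
            index = {v: i for i, v in enumerate(nodes)}
            h = ig.Graph([(index[u], index[v]) for u, v in net.graph.edges()],
                         n=len(nodes))
            labels = [part.membership[v] for v in nodes]
            assert part.q == pytest.approx(h.modularity(labels), abs=1e-9)

    def test_planted_two_block_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        hits = 0
        for seed in range(20):
            g = nx.planted_partition_graph(2, 30, 0.5, 0.02, seed=seed)
            g.remove_nodes_from(list(nx.isolates(g)))
            net = make_network(list(g.edges()))
            part = detect_modules(net)
            truth = [0 if v < 30 else 1 for v in net.graph.nodes]
            pred = [part.membership[v] for v in net.graph.nodes]
            if adjusted_rand_score(truth, pred) >= 0.9:
                hits += 1
        assert hits >= 18

    def test_detection_deterministic(self):
        net = make_network([("b", "a"), ("c", "b"), ("d", "c"), ("a", "d"),
                            ("e", "f"), ("f", "g"), ("g", "e")])
        a, b = detect_modules(net), detect_modules(net)
        assert a.membership == b.membership


class TestPowerLaw:
    def test_exact_power_law_gives_r2_one(self):
        # f(k) = 64 k^-2 at k = 1, 2, 4, 8
        assert degree_frequency_r2([1, 2, 4, 8], [64, 16, 4, 1]) == pytest.approx(1.0)

    def test_regular_graph_undefined(self):
        net = make_network([("a", "b"), ("b", "c"), ("c", "a")])
        assert power_law_r2(net) is None

    def test_erdos_renyi_is_not_scale_free(self):
        hits = 0
        for seed in range(50):
            g = nx.gnp_random_graph(200, 0.05, seed=seed)
            g.remove_nodes_from(list(nx.isolates(g)))
            r2 = power_law_r2(make_network(list(g.edges())))
            if r2 is not None and r2 < 0.9:
                hits += 1
        assert hits >= 45


class TestModuleComposition:
    def test_phylum_counts_and_min_size(self):
        edges = [(f"f{i}", f"f{j}") for i, j in itertools.combinations(range(5), 2)]
        edges += [("x1", "x2"), ("x2", "x3"), ("x3", "x1"), ("x1", "x4")]
        net = make_network(edges)
        part = detect_modules(net)
        taxonomy = {f"f{i}": ("Bacteria", "Firmicutes") for i in range(5)}
        comp = module_composition(net, part, taxonomy, min_size=5)
        assert len(comp) == 1  # the 4-node module is excluded
        assert comp.iloc[0]["composition"] == {"Firmicutes": 5}

    def test_unannotated_nodes_tallied_unclassified(self):
        edges = [(i, j) for i, j in itertools.combinations(range(5), 2)]
        net = make_network(edges)
        comp = module_composition(net, detect_modules(net), {}, min_size=5)
        assert comp.iloc[0]["composition"] == {"unclassified": 5}

    def test_planted_negative_ratio_exact(self):
        # clique of 5 with 6 of its 10 intra links negative
        pairs = list(itertools.combinations(range(5), 2))
        edges = [(u, v, 0.8, -1 if k < 6 else 1) for k, (u, v) in enumerate(pairs)]
        net = make_network(edges)
        comp = module_composition(net, detect_modules(net), {}, min_size=5)
        assert comp.iloc[0]["negative_ratio"] == pytest.approx(0.6)
        assert comp.iloc[0]["negative_links"] == 6
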