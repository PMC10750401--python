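"""Network generator and small-world metrics against brute-force oracles."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from pacenet.netgen import (
    GeneratorParams, characteristic_path_length, clustering_coefficient,
    degree_histogram, generate_network, read_edge_list, read_graphml,
    small_world_sigma, write_edge_list, write_graphml,
)
from pacenet.io_cli import toy_graph


# --- independent oracles ----------------------------------------------------

def brute_clustering(g: nx.Graph) -> float:
    """Exhaustive triple count per node."""
    total = 0.0
    for v in g.nodes:
        nb = list(g.neighbors(v))
        k = len(nb)
        if k < 2:
            continue
        tri = sum(1 for a, b in combinations(nb, 2) if g.has_edge(a, b))
        total += tri / (k * (k - 1) / 2)
    return total / g.number_of_nodes()


def bfs_path_length(g: nx.Graph) -> float:
    """All-pairs BFS mean shortest path, written from scratch."""
    nodes = list(g.nodes)
    total, pairs = 0, 0
    for s in nodes:
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in g.neighbors(u):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for t_, d in dist.items():
            if t_ != s:
                total += d
                pairs += 1
    return total / pairs


class TestMetrics:
    def test_triangle_clustering_is_one(self):
        assert clustering_coefficient(toy_graph("triangle")) == 1.0

    def test_star_clustering_is_zero(self):
        assert clustering_coefficient(toy_graph("star", n=4)) == 0.0

    def test_clustering_matches_brute_force(self, rng):
        g = nx.gnp_random_graph(10, 0.5, seed=7)
        assert clustering_coefficient(g) == pytest.approx(
            brute_clustering(g), rel=1e-12)

    def test_path_graph_path_length(self):
        # 3-node path: (1 + 1 + 2)/3
        assert characteristic_path_length(toy_graph("path", n=3)) \
            == pytest.approx(4.0 / 3.0)

    def test_complete_graph_path_length(self):
        assert characteristic_path_length(toy_graph("complete", n=7)) == 1.0

    def test_path_length_matches_bfs_oracle(self):
        g = nx.connected_watts_strogatz_graph(12, 4, 0.3, seed=3)
        assert characteristic_path_length(g) == pytest.approx(
            bfs_path_length(g), rel=1e-12)

    def test_disconnected_graph_rejected(self):
        g = nx.Graph([(0, 1), (2, 3)])
        with pytest.raises(ValueError):
            characteristic_path_length(g)

    def test_sigma_of_complete_graph_is_one(self):
        m = small_world_sigma(toy_graph("complete", n=10), n_random=5, seed=0)
        assert m.sigma == pytest.approx(1.0, abs=1e-12)
        assert m.C == m.C_r == m.L == m.L_r == 1.0

    def test_sigma_components_match_brute_force(self):
        """Rewired ring lattice: C and L agree with the from-scratch
        implementations, and sigma is consistent with its definition."""
        g = nx.connected_watts_strogatz_graph(50, 4, 0.1, seed=11)
        m = small_world_sigma(g, n_random=20, seed=5)
        assert m.C == pytest.approx(brute_clustering(g), rel=1e-12)
        assert m.L == pytest.approx(bfs_path_length(g), rel=1e-12)
        assert m.sigma == pytest.approx((m.C / m.C_r) / (m.L / m.L_r))
        assert m.sigma > 1.0  # rewired lattice is small-world

    def test_er_graph_against_itself_near_one(self):
        """A dense random graph compared with its own ensemble gives
        sigma close to 1 (within sampling spread)."""
        g = nx.gnm_random_graph(40, 200, seed=1)
        m = small_world_sigma(g, n_random=30, seed=2)
        assert 0.8 < m.sigma < 1.2

    def test_degree_histogram_examples(self):
        assert degree_histogram(toy_graph("triangle")) == {2: 3}
        g2 = nx.Graph([(0, 1)])
        assert degree_histogram(g2) == {1: 2}

    def test_degree_histogram_sums_to_node_count(self):
        g = generate_network(GeneratorParams(module_sizes=(20, 20), seed=3))
        h = degree_histogram(g)
        assert sum(h.values()) == g.number_of_nodes()


class TestGenerator:
    def test_two_node_forced_edge(self):
        g = generate_network(GeneratorParams(module_sizes=(2,), degree_cap=1,
                                             seed=0))
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1

    def test_reference_size_connected_with_capped_degrees(self):
        g = generate_network(GeneratorParams(seed=1))
        assert g.number_of_nodes() == 485
        assert nx.is_connected(g)
        degs = [d for _, d in g.degree()]
        assert min(degs) >= 1 and max(degs) <= 5

    def test_module_sizes_honored(self):
        g = generate_network(GeneratorParams(module_sizes=(30, 20, 10),
                                             seed=4))
        counts = {}
        for _, d in g.nodes(data=True):
            counts[d["module"]] = counts.get(d["module"], 0) + 1
        assert counts == {0: 30, 1: 20, 2: 10}

    def test_determinism_and_seed_sensitivity(self):
        for seed in range(5):
            g1 = generate_network(GeneratorParams(module_sizes=(40, 40),
                                                  seed=seed))
            g2 = generate_network(GeneratorParams(module_sizes=(40, 40),
                                                  seed=seed))
            assert set(g1.edges) == set(g2.edges)
            g3 = generate_network(GeneratorParams(module_sizes=(40, 40),
                                                  seed=seed + 100))
            assert set(g1.edges) != set(g3.edges)

    def test_handshake_lemma(self):
        for seed in (0, 1, 2):
            g = generate_network(GeneratorParams(module_sizes=(50, 50),
                                                 seed=seed))
            assert sum(d for _, d in g.degree()) == 2 * g.number_of_edges()

    def test_modular_wiring_dominates(self):
        """Within-module edges outnumber between-module edges."""
        for seed in (1, 2, 3):
            g = generate_network(GeneratorParams(seed=seed))
            intra = sum(1 for a, b in g.edges
                        if g.nodes[a]["module"] == g.nodes[b]["module"])
            inter = g.number_of_edges() - intra
            assert intra > inter

    def test_edges_carry_configured_resistance(self):
        g = generate_network(GeneratorParams(module_sizes=(10, 10), seed=0,
                                             resistance=1234.0))
        assert all(d["resistance"] == 1234.0 for _, _, d in g.edges(data=True))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            generate_network(GeneratorParams(module_sizes=(1,)))
        with pytest.raises(ValueError):
            generate_network(GeneratorParams(module_sizes=(5, 5),
                                             degree_cap=0))


class TestSerialization:
    def test_graphml_round_trip(self, tmp_path):
        g = generate_network(GeneratorParams(module_sizes=(15, 15), seed=9))
        path = tmp_path / "net.graphml"
        write_graphml(g, path)
        g2 = read_graphml(path)
        assert set(g.edges) == set(g2.edges)
        for n in g.nodes:
            for key in ("module", "x", "y", "z"):
                assert g2.nodes[n][key] == pytest.approx(g.nodes[n][key])
        for a, b in g.edges:
            assert g2.edges[a, b]["resistance"] == g.edges[a, b]["resistance"]

    def test_edge_list_round_trip(self, tmp_path):
        g = generate_network(GeneratorParams(module_sizes=(8, 8), seed=2))
        path = tmp_path / "edges.csv"
        write_edge_list(g, path)
        g2 = read_edge_list(path)
        assert set(map(frozenset, g.edges)) == set(map(frozenset, g2.edges))
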