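"""Weighted graph metrics against enumerated toys and brute-force oracles."""

import networkx as nx
import numpy as np
import pytest

from conftest import random_weight_matrix
from megnet.connectivity import ThresholdedNetwork
from megnet.graph_metrics import (
    average_path_length,
    clustering_coefficient,
    compute_metrics,
    network_clustering,
    network_degree,
    network_strength,
    node_strength,
    path_length_matrix,
)


def floyd_warshall_oracle(W):
    """All-pairs shortest paths with 1/w lengths; 0 for unreachable / diagonal."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if W[i, j] > 0:
                D[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    D[np.isinf(D)] = 0.0
    return D


def clustering_oracle(W):
    """Triple-loop geometric-mean clustering with max-weight normalization."""
    n = W.shape[0]
    wmax = W.max()
    Wn = W / wmax if wmax > 0 else W
    C = np.zeros(n)
    for i in range(n):
        d = int((W[i] > 0).sum())
        if d < 2:
            continue
        total = 0.0
        for j in range(n):
            for k in range(n):
                if j != i and k != i and j != k:
                    total += (Wn[i, j] * Wn[j, k] * Wn[k, i]) ** (1.0 / 3.0)
        C[i] = total / (d * (d - 1))
    return C


def triangle(w=0.5):
    W = np.array([[0, w, w], [w, 0, w], [w, w, 0]], dtype=float)
    return W


def star4():
    W = np.zeros((4, 4))
    W[0, 1:] = W[1:, 0] = 1.0
    return W


class TestToyGraphs:
    def test_triangle_strength(self):
        W = triangle(0.5)
        assert np.allclose(node_strength(W), 1.0 / 3.0)
        assert network_strength(W) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_star_strength_and_degree(self):
        W = star4()
        s = node_strength(W)
        assert s[0] == pytest.approx(0.75) and np.allclose(s[1:], 0.25)
        assert network_strength(W) == pytest.approx(0.375)
        assert network_degree(W) == pytest.approx(1.5)

    def test_triangle_degree(self):
        assert network_degree(triangle()) == pytest.approx(2.0)

    def test_isolated_node_zero_strength(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        assert node_strength(W, 2) == 0.0

    def test_unnormalized_strength_option(self):
        assert node_strength(triangle(0.5), 0, normalized=False) == pytest.approx(1.0)

    def test_two_node_path_length(self):
        W = np.array([[0, 0.5], [0.5, 0]])
        assert np.allclose(path_length_matrix(W), [[0, 2], [2, 0]])
        assert average_path_length(W) == pytest.approx(2.0)

    def test_triangle_route_tie(self):
        # direct a-c edge of weight .5 (length 2) ties the a-b-c route (1+1)
        W = np.array([[0, 1, 0.5], [1, 0, 1], [0.5, 1, 0]], dtype=float)
        assert path_length_matrix(W)[0, 2] == pytest.approx(2.0)

    def test_disconnected_pair_contributes_zero(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        D = path_length_matrix(W)
        assert D[0, 2] == 0.0 and D[2, 0] == 0.0
        assert average_path_length(W) == pytest.approx(2.0 / 6.0)

    def test_triangle_clustering_is_one(self):
        assert np.allclose(clustering_coefficient(triangle(0.7)), 1.0)
        assert network_clustering(triangle(0.7)) == pytest.approx(1.0)

    def test_path_graph_no_triangles(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 0.8
        assert np.allclose(clustering_coefficient(W), 0.0)

    def test_four_node_clustering_closed_form(self):
        # edges ab=1, ac=1, bc=0.5, ad=1; exact values via cube roots
        W = np.zeros((4, 4))
        for i, j, w in [(0, 1, 1.0), (0, 2, 1.0), (1, 2, 0.5), (0, 3, 1.0)]:
            W[i, j] = W[j, i] = w
        C = clustering_coefficient(W)
        c_half = 0.5 ** (1.0 / 3.0)
        assert C[0] == pytest.approx(2 * c_half / 6, abs=1e-12)
        assert C[1] == pytest.approx(c_half, abs=1e-12)
        assert C[2] == pytest.approx(c_half, abs=1e-12)
        assert C[3] == 0.0
        assert network_clustering(W) == pytest.approx((2 * c_half / 6 + 2 * c_half) / 4, abs=1e-12)

    def test_empty_network(self):
        W = np.zeros((4, 4))
        assert network_strength(W) == 0.0
        assert network_degree(W) == 0.0
        assert average_path_length(W) == 0.0
        assert network_clustering(W) == 0.0


class TestOracles:
    def test_dijkstra_matches_floyd_warshall(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 13))
            W = random_weight_matrix(rng, n, density=float(rng.uniform(0.1, 0.9)))
            assert np.allclose(path_length_matrix(W), floyd_warshall_oracle(W), atol=1e-12)

    def test_clustering_matches_triple_loop(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 11))
            W = random_weight_matrix(rng, n, density=float(rng.uniform(0.2, 0.9)))
            assert np.allclose(clustering_coefficient(W), clustering_oracle(W), atol=1e-12)

    def test_binary_case_reduces_to_unweighted(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 10))
            W = random_weight_matrix(rng, n, density=0.5, binary=True)
            G = nx.from_numpy_array(W)
            nx_clust = np.array([nx.clustering(G, i) for i in range(n)])
            assert np.allclose(clustering_coefficient(W), nx_clust, atol=1e-12)
            # unweighted shortest paths with the zero-unreachable convention
            D = path_length_matrix(W)
            sp = dict(nx.all_pairs_shortest_path_length(G))
            for i in range(n):
                for j in range(n):
                    expected = sp[i].get(j, 0)
                    assert D[i, j] == pytest.approx(float(expected), abs=1e-12)


class TestScalingProperties:
    def test_uniform_weight_scaling(self, rng):
        W = random_weight_matrix(rng, 8, density=0.6)
        c = 3.7
        assert np.allclose(clustering_coefficient(c * W), clustering_coefficient(W))
        assert np.allclose(node_strength(c * W), c * node_strength(W))
        assert np.allclose(path_length_matrix(c * W), path_length_matrix(W) / c)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            network_strength(np.array([[0, -1.0], [-1.0, 0]]))


class TestComputeMetrics:
    def test_network_container_and_policy(self):
        edges = [(0, 1, 0.8, 1, 5.0), (1, 2, 0.6, -1, -4.0), (0, 2, 0.4, 1, 3.0)]
        net = ThresholdedNetwork(
            N=3, edges=edges, tp_crit=2.6, alpha=0.01, K=100, band="alpha",
            node_labels=["a", "b", "c"],
        )
        res_pos = compute_metrics(net, subject_id="s1", edge_policy="positive")
        res_abs = compute_metrics(net, edge_policy="absolute")
        assert res_pos.DA == pytest.approx(4.0 / 3.0)  # negative edge excluded
        assert res_abs.DA == pytest.approx(2.0)
        assert res_pos.SA == pytest.approx((0.8 + 0.4) * 2 / 9)
        assert res_pos.subject_id == "s1"
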