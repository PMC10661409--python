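"""Graph construction and topology metrics, with networkx and
brute-force enumeration as independent oracles."""

import math

import networkx as nx
import numpy as np
import pytest

from eegdx.network import (NetworkConfig, binarize, clustering_coefficient,
                           connectivity, global_efficiency, mean_degree,
                           network_features, path_length, rewired_null,
                           small_worldness)
from oracles import brute_clustering, brute_efficiency, brute_path_length


def _random_adj(rng, n_max=8):
    n = int(rng.integers(2, n_max + 1))
    p = rng.uniform(0.1, 0.9)
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    return a + a.T


def _complete(n):
    return (np.ones((n, n), dtype=np.int8) - np.eye(n, dtype=np.int8))


def _path3():
    a = np.zeros((3, 3), dtype=np.int8)
    a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1
    return a


class TestConnectivity:
    def test_duplicated_channel_fully_correlated(self, rng):
        x = rng.standard_normal(500)
        conn = connectivity(np.vstack([x, x, rng.standard_normal(500)]))
        assert conn[0, 1] == pytest.approx(1.0)
        assert conn[0, 0] == 0.0

    def test_independent_channels_nearly_uncorrelated(self):
        vals = []
        for s in range(10):
            data = np.random.default_rng(s).standard_normal((4, 2000))
            conn = connectivity(data)
            vals.append(conn[np.triu_indices(4, 1)].max())
        assert np.median(vals) < 0.1

    def test_sign_flip_invariance(self, rng):
        data = rng.standard_normal((3, 500))
        flipped = data.copy()
        flipped[1] *= -1.0
        assert np.allclose(connectivity(data), connectivity(flipped))

    def test_constant_channel_zeroed(self, rng):
        data = rng.standard_normal((3, 500))
        data[2] = 4.2
        conn = connectivity(data)
        assert np.all(conn[2] == 0.0) and np.all(conn[:, 2] == 0.0)


class TestBinarize:
    def test_dense_matrix_gives_complete_graph(self):
        conn = np.full((5, 5), 0.9)
        np.fill_diagonal(conn, 0.0)
        assert np.array_equal(binarize(conn, 0.7), _complete(5))

    def test_subthreshold_gives_empty_graph(self):
        conn = np.full((5, 5), 0.3)
        np.fill_diagonal(conn, 0.0)
        adj = binarize(conn, 0.7)
        assert adj.sum() == 0
        assert math.isnan(path_length(adj))
        assert global_efficiency(adj) == 0.0

    def test_boundary_value_included(self):
        conn = np.zeros((2, 2))
        conn[0, 1] = conn[1, 0] = 0.7
        assert binarize(conn, 0.7)[0, 1] == 1


class TestMetricsClosedForms:
    def test_complete_graph(self):
        adj = _complete(5)
        assert clustering_coefficient(adj) == pytest.approx(1.0)
        assert path_length(adj) == pytest.approx(1.0)
        assert global_efficiency(adj) == pytest.approx(1.0)
        assert mean_degree(adj) == pytest.approx(4.0)

    def test_star_graph_clustering_zero(self):
        adj = np.zeros((5, 5), dtype=np.int8)
        adj[0, 1:] = adj[1:, 0] = 1
        assert clustering_coefficient(adj) == 0.0

    def test_path_graph_p3(self):
        adj = _path3()
        assert path_length(adj) == pytest.approx(4.0 / 3.0)
        assert global_efficiency(adj) == pytest.approx(5.0 / 6.0)

    def test_disjoint_pairs_exclude_disconnected(self):
        adj = np.zeros((4, 4), dtype=np.int8)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = 1
        assert path_length(adj) == pytest.approx(1.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(100))
    def test_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        adj = _random_adj(rng)
        assert clustering_coefficient(adj) == pytest.approx(
            brute_clustering(adj), abs=1e-12)
        expected_l = brute_path_length(adj)
        actual_l = path_length(adj)
        if math.isnan(expected_l):
            assert math.isnan(actual_l)
        else:
            assert actual_l == pytest.approx(expected_l, abs=1e-12)
        assert global_efficiency(adj) == pytest.approx(
            brute_efficiency(adj), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_networkx(self, seed):
        rng = np.random.default_rng(1000 + seed)
        adj = _random_adj(rng)
        g = nx.from_numpy_array(adj)
        assert clustering_coefficient(adj) == pytest.approx(
            nx.average_clustering(g), abs=1e-12)
        assert global_efficiency(adj) == pytest.approx(
            nx.global_efficiency(g), abs=1e-12)


class TestSmallWorldness:
    def test_complete_graph_sigma_one(self):
        assert small_worldness(_complete(6)) == 1.0

    def test_erdos_renyi_sigma_near_one(self):
        vals = []
        for s in range(20):
            g = nx.erdos_renyi_graph(19, 0.3, seed=s)
            adj = nx.to_numpy_array(g).astype(np.int8)
            v = small_worldness(adj, n_random=10, seed=s)
            if not math.isnan(v):
                vals.append(v)
        assert np.mean(vals) == pytest.approx(1.0, abs=0.3)

    def test_watts_strogatz_sigma_above_one(self):
        vals = []
        for s in range(10):
            g = nx.watts_strogatz_graph(19, 4, 0.1, seed=s)
            adj = nx.to_numpy_array(g).astype(np.int8)
            vals.append(small_worldness(adj, n_random=10, seed=s))
        assert np.mean(vals) > 1.0

    def test_seeded_determinism(self):
        g = nx.watts_strogatz_graph(19, 4, 0.1, seed=3)
        adj = nx.to_numpy_array(g).astype(np.int8)
        a = small_worldness(adj, n_random=5, seed=9)
        b = small_worldness(adj, n_random=5, seed=9)
        assert a == b

    def test_rewired_null_preserves_degree_sequence(self, rng):
        adj = _random_adj(np.random.default_rng(77), n_max=8)
        null = rewired_null(adj, rng)
        assert np.array_equal(adj.sum(axis=1), null.sum(axis=1))
        assert np.array_equal(null, null.T)
        assert np.all(np.diag(null) == 0)


def test_network_features_bundle(rng):
    data = rng.standard_normal((6, 500))
    feats = network_features(data, NetworkConfig(threshold=0.3, n_random=5),
                             seed=1)
    assert set(feats) == {"mean_degree", "clustering", "path_length",
                         "efficiency", "small_worldness"}
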