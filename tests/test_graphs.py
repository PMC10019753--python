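"""Graph metrics vs exhaustive enumeration and independent algorithms."""

from itertools import permutations

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from meditfc import (
    WeightedGraph,
    characteristic_path_length,
    clustering_coefficient,
    shortest_paths,
    to_weighted_graph,
)
from meditfc.connectivity import ConnectivityMatrix
from meditfc.preprocessing import BAND_BY_NAME


def _graph(w):
    w = np.asarray(w, dtype=float)
    return WeightedGraph(nodes=[f"n{i}" for i in range(w.shape[0])], weights=w)


def _random_graph(rng, n, density=0.7):
    w = rng.uniform(0, 1, size=(n, n))
    w[rng.uniform(size=(n, n)) > density] = 0.0
    w = np.triu(w, 1)
    w = w + w.T
    return _graph(w)


def _cm(matrix, method="plv"):
    n = matrix.shape[0]
    return ConnectivityMatrix(
        method=method, band=BAND_BY_NAME["alpha"], state="meditation",
        subject_id="s", group="NM", epoch_index=0,
        matrix=np.asarray(matrix, dtype=float),
        channel_index=[(f"c{i}", "left" if i < n // 2 else "right") for i in range(n)],
    )


def clustering_by_enumeration(w):
    """Oracle: explicit triple loop over neighbor pairs of each node."""
    n = w.shape[0]
    out = np.zeros(n)
    for j in range(n):
        nbrs = [k for k in range(n) if w[j, k] > 0]
        k_j = len(nbrs)
        if k_j < 2:
            continue
        s = 0.0
        for a in range(len(nbrs)):
            for b in range(len(nbrs)):
                if a == b:
                    continue
                k, l = nbrs[a], nbrs[b]
                s += (w[j, k] * w[j, l] * w[k, l]) ** (1 / 3)
        out[j] = s / (k_j * (k_j - 1))
    return out


def distances_by_path_enumeration(w):
    """Oracle for small graphs: try every simple path between each pair."""
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    nodes = list(range(n))
    for src in nodes:
        for dst in nodes:
            if src == dst:
                continue
            inner = [v for v in nodes if v not in (src, dst)]
            for r in range(len(inner) + 1):
                for mid in permutations(inner, r):
                    path = (src, *mid, dst)
                    d = 0.0
                    ok = True
                    for a, b in zip(path[:-1], path[1:]):
                        if w[a, b] <= 0:
                            ok = False
                            break
                        d += 1.0 / w[a, b]
                    if ok:
                        dist[src, dst] = min(dist[src, dst], d)
    return dist


class TestToWeightedGraph:
    def test_all_ones_plv_gives_complete_unit_graph(self):
        g = to_weighted_graph(_cm(np.ones((4, 4))))
        assert np.all(np.diag(g.weights) == 0)
        off = g.weights[~np.eye(4, dtype=bool)]
        np.testing.assert_array_equal(off, 1.0)

    def test_negative_correlation_enters_as_magnitude(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = -0.8
        m[0, 2] = m[2, 0] = 0.3
        m[1, 2] = m[2, 1] = 0.1
        g = to_weighted_graph(_cm(m, method="correlation"))
        assert g.weights[0, 1] == pytest.approx(0.8)

    def test_proportional_threshold_keeps_strongest_edges(self):
        m = np.eye(4)
        vals = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]
        iu = np.triu_indices(4, 1)
        m[iu] = vals
        m = np.maximum(m, m.T)
        g = to_weighted_graph(_cm(m), threshold_q=0.5)
        kept = g.weights[iu]
        assert sorted(kept[kept > 0], reverse=True) == [0.9, 0.8, 0.7]
        np.testing.assert_array_equal(g.weights, g.weights.T)


class TestClustering:
    def test_unit_triangle_has_unit_clustering(self):
        w = np.ones((3, 3)) - np.eye(3)
        cc, mean = clustering_coefficient(_graph(w))
        np.testing.assert_allclose(cc, 1.0)
        assert mean == pytest.approx(1.0)

    def test_star_graph_has_zero_clustering(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 0.8
        cc, mean = clustering_coefficient(_graph(w))
        np.testing.assert_array_equal(cc, 0.0)
        assert mean == 0.0

    def test_random_graphs_match_enumeration_oracle(self, rng):
        for _ in range(200):
            g = _random_graph(rng, int(rng.integers(3, 7)))
            cc, _ = clustering_coefficient(g)
            np.testing.assert_allclose(cc, clustering_by_enumeration(g.weights), atol=1e-12)

    def test_binary_weights_reduce_to_binary_clustering(self, rng):
        for _ in range(20):
            g = _random_graph(rng, 6)
            w = (g.weights > 0.4).astype(float)
            np.fill_diagonal(w, 0.0)
            cc, _ = clustering_coefficient(_graph(w))
            G = nx.from_numpy_array(w)
            expected = np.array([nx.clustering(G, i) for i in range(6)])
            np.testing.assert_allclose(cc, expected, atol=1e-12)

    def test_matches_networkx_onnela_weighted_clustering(self, rng):
        """networkx normalizes by the max weight; with max weight 1 the
        two definitions coincide."""
        for _ in range(20):
            g = _random_graph(rng, 6)
            w = g.weights.copy()
            if w.max() == 0:
                continue
            w = w / w.max()
            cc, _ = clustering_coefficient(_graph(w))
            G = nx.from_numpy_array(w)
            expected = np.array([nx.clustering(G, i, weight="weight") for i in range(6)])
            np.testing.assert_allclose(cc, expected, atol=1e-10)

    def test_negative_weights_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = -0.5
        with pytest.raises(ValueError, match="negative"):
            _graph(w)


class TestShortestPaths:
    def test_detour_beats_weak_direct_edge(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        w[0, 2] = w[2, 0] = 0.25  # direct distance 4, detour 1 + 1
        d = shortest_paths(_graph(w))
        assert d[0, 2] == pytest.approx(2.0)

    def test_complete_unit_graph_distances_one(self):
        w = np.ones((5, 5)) - np.eye(5)
        d = shortest_paths(_graph(w))
        off = d[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)

    def test_disconnected_components_infinite(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        w[2, 3] = w[3, 2] = 0.5
        d = shortest_paths(_graph(w))
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])

    def test_random_graphs_match_floyd_warshall_and_enumeration(self, rng):
        for i in range(200):
            g = _random_graph(rng, int(rng.integers(2, 7)), density=0.6)
            d = shortest_paths(g)
            dense = np.where(g.weights > 0, 1.0 / np.where(g.weights > 0, g.weights, 1), 0.0)
            fw = floyd_warshall(dense, directed=False)
            np.testing.assert_allclose(d, fw, atol=1e-10)
            if i < 50:  # enumeration is factorial; a subset suffices
                np.testing.assert_allclose(
                    d, distances_by_path_enumeration(g.weights), atol=1e-10
                )

    def test_raising_a_weight_never_increases_distances(self, rng):
        for _ in range(50):
            g = _random_graph(rng, 6)
            d0 = shortest_paths(g)
            w = g.weights.copy()
            iu = np.transpose(np.triu_indices(6, 1))
            i, j = iu[rng.integers(len(iu))]
            w[i, j] = w[j, i] = min(1.0, w[i, j] + rng.uniform(0, 0.5))
            d1 = shortest_paths(_graph(w))
            assert np.all(d1 <= d0 + 1e-12)


class TestCharacteristicPathLength:
    def test_complete_unit_graph_has_length_one(self):
        w = np.ones((6, 6)) - np.eye(6)
        spl, frac = characteristic_path_length(shortest_paths(_graph(w)))
        assert spl == pytest.approx(1.0)
        assert frac == 1.0

    def test_stronger_graph_has_shorter_paths(self, rng):
        g = _random_graph(rng, 6, density=0.9)
        stronger = _graph(np.clip(g.weights * 1.5, 0, 1) * (g.weights > 0))
        spl_weak, _ = characteristic_path_length(shortest_paths(g))
        spl_strong, _ = characteristic_path_length(shortest_paths(stronger))
        assert spl_strong <= spl_weak + 1e-12

    def test_mean_over_finite_pairs_matches_all_pairs_oracle(self, rng):
        g = _random_graph(rng, 5, density=0.5)
        d = shortest_paths(g)
        vals = [d[i, j] for i in range(5) for j in range(5)
                if i != j and np.isfinite(d[i, j])]
        spl, frac = characteristic_path_length(d)
        if vals:
            assert spl == pytest.approx(np.mean(vals))
        assert frac == pytest.approx(len(vals) / 20)

    def test_no_finite_pairs_gives_infinity(self):
        spl, frac = characteristic_path_length(shortest_paths(_graph(np.zeros((3, 3)))))
        assert np.isinf(spl)
        assert frac == 0.0


def test_edge_list_round_trips_weights(rng):
    from meditfc.graphs import edge_list

    g = _random_graph(rng, 5)
    edges = edge_list(g)
    assert len(edges) == int((g.weights > 0).sum() / 2)
    for a, b, w in edges:
        i, j = g.nodes.index(a), g.nodes.index(b)
        assert g.weights[i, j] == pytest.approx(w)
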