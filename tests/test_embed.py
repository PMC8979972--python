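"""Laplacian-Eigenmaps embedding: graph construction, kernel, eigenproblem,
orientation.  Includes the dense brute-force oracle for the sparse solver."""

import numpy as np
import pytest
from scipy.linalg import eigh
from scipy.stats import spearmanr

import respsort as rs
from respsort.embed import TemporalGraph, objective


def edges_to_set(edges):
    return {tuple(e) for e in edges}


class TestTemporalGraph:
    def test_k2_connects_immediate_neighbours(self):
        edges = edges_to_set(rs.build_temporal_knn_graph(5, 2))
        # node 2 -> {1, 3}; full edge set for N=5, k=2 enumerated by hand
        assert edges == {(0, 1), (1, 2), (2, 3), (3, 4)}

    def test_k3_asymmetric_split(self):
        edges = edges_to_set(rs.build_temporal_knn_graph(7, 3))
        # node 2: floor(3/2)=1 before (1), ceil(3/2)=2 after (3, 4)
        assert {(1, 2), (2, 3), (2, 4)} <= edges
        # reach is 2 forward / 1 back, so 0-3 can arise from neither endpoint
        assert (0, 3) not in edges

    def test_boundary_truncation(self):
        edges = edges_to_set(rs.build_temporal_knn_graph(5, 2))
        # node 0 has only node 1 after truncation; symmetrized by union
        assert (0, 1) in edges and (0, 2) not in edges

    @pytest.mark.parametrize("n,k,msg", [(5, 1, "k too small"), (5, 5, "k too large")])
    def test_k_bounds(self, n, k, msg):
        with pytest.raises(ValueError, match=msg):
            rs.build_temporal_knn_graph(n, k)

    def test_intensity_graph_links_similar_frames(self):
        # two interleaved intensity levels: intensity neighbours are same-level
        X = np.array([[0.0], [10.0], [0.1], [10.1], [0.2], [10.2]])
        edges = edges_to_set(rs.build_intensity_knn_graph(X, 2))
        assert (0, 2) in edges and (1, 3) in edges
        assert (0, 1) not in edges


class TestSigma2AndKernel:
    def test_median_of_edge_distances(self):
        X = np.array([[0.0], [1.0], [4.0]])  # squared dists: 1 and 9
        edges = np.array([[0, 1], [1, 2]])
        assert rs.estimate_sigma2(X, edges) == pytest.approx(2.5)

    def test_identical_frames_degenerate(self):
        X = np.ones((5, 3))
        edges = np.array([[0, 1], [1, 2], [2, 3]])
        with pytest.raises(ValueError, match="degenerate sequence"):
            rs.estimate_sigma2(X, edges)

    def test_intensity_scaling_scales_sigma2_quadratically(self):
        rng = np.random.default_rng(0)
        X = rng.random((10, 4))
        edges = rs.build_temporal_knn_graph(10, 2)
        s1 = rs.estimate_sigma2(X, edges)
        s3 = rs.estimate_sigma2(3.0 * X, edges)
        assert s3 == pytest.approx(9.0 * s1)

    def test_gaussian_weight_values(self):
        assert rs.gaussian_weight(0.0, 1.0) == pytest.approx(1.0)
        assert rs.gaussian_weight(2.0, 1.0) == pytest.approx(np.exp(-1.0))
        assert rs.gaussian_weight(5.0, 1.0, connected=False) == 0.0
        with pytest.raises(ValueError, match="invalid bandwidth"):
            rs.gaussian_weight(1.0, 0.0)


def random_connected_graph(n, rng):
    """Random weighted graph guaranteed connected via a spanning path."""
    edges = {(i, i + 1) for i in range(n - 1)}
    m_extra = rng.integers(n, 3 * n)
    for _ in range(m_extra):
        i, j = sorted(rng.choice(n, size=2, replace=False))
        edges.add((int(i), int(j)))
    edges = np.array(sorted(edges))
    weights = rng.uniform(0.05, 1.0, size=len(edges))
    return TemporalGraph(n_nodes=n, k=2, edges=edges, weights=weights, sigma2=1.0)


class TestEmbedding:
    def test_two_level_toy_sign_separates_halves(self):
        X = np.r_[np.zeros((5, 4)), np.ones((5, 4))]
        graph = TemporalGraph.from_sub_images(X, k=2, mode="temporal")
        curve = rs.laplacian_embedding_1d(graph)
        y = curve.values
        assert np.all(np.sign(y[:5]) == np.sign(y[0]))
        assert np.all(np.sign(y[5:]) == -np.sign(y[0]))

    def test_matches_dense_oracle_and_beats_random_feasible(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            n = int(rng.integers(10, 51))
            graph = random_connected_graph(n, rng)
            curve = rs.laplacian_embedding_1d(graph)
            y = curve.values

            W = graph.adjacency().toarray()
            deg = W.sum(axis=1)
            L = np.diag(deg) - W
            vals, vecs = eigh(L, np.diag(deg))
            yd = vecs[:, 1]
            yd = yd - (yd @ deg) / deg.sum()
            yd = yd / np.sqrt(yd @ (deg * yd))
            if yd @ y < 0:
                yd = -yd
            assert np.max(np.abs(y - yd)) < 1e-8

            phi_y = objective(y, graph)
            z = rng.standard_normal((1000, n))
            z = z - (z @ deg)[:, None] / deg.sum()
            z = z / np.sqrt(np.einsum("ij,ij->i", z * deg, z))[:, None]
            i, j = graph.edges[:, 0], graph.edges[:, 1]
            phi_z = 2 * np.sum(graph.weights * (z[:, i] - z[:, j]) ** 2, axis=1)
            assert np.all(phi_y <= phi_z + 1e-10)

    def test_disconnected_graph_raises(self):
        edges = np.array([[0, 1], [2, 3]])
        graph = TemporalGraph(4, 2, edges, np.ones(2), 1.0)
        with pytest.raises(ValueError, match="graph not connected"):
            rs.laplacian_embedding_1d(graph)

    def test_identical_frames_fail_upstream(self):
        X = np.ones((10, 4))
        with pytest.raises(ValueError, match="degenerate sequence"):
            TemporalGraph.from_sub_images(X, k=2, mode="temporal")

    def test_offset_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.random((30, 16))
        g1 = TemporalGraph.from_sub_images(X, k=4)
        g2 = TemporalGraph.from_sub_images(X + 7.5, k=4)
        assert np.array_equal(g1.edges, g2.edges)
        assert np.allclose(g1.weights, g2.weights)
        y1 = rs.laplacian_embedding_1d(g1).values
        y2 = rs.laplacian_embedding_1d(g2).values
        assert np.allclose(y1, y2, atol=1e-7)


class TestPhantomEmbedding:
    def test_noise_free_curve_tracks_displacement(self, noise_free_slice):
        series, truth = noise_free_slice
        from conftest import RESP_ROI
        curve = rs.respiratory_curve(series, RESP_ROI)
        rho = spearmanr(curve.values, truth.displacement_px).statistic
        assert abs(rho) >= 0.95

    def test_noisy_curve_tracks_displacement(self, phantom_slice):
        series, truth = phantom_slice
        from conftest import RESP_ROI
        curve = rs.respiratory_curve(series, RESP_ROI)
        rho = spearmanr(curve.values, truth.displacement_px).statistic
        assert abs(rho) >= 0.95
        # oriented so that maxima are end expiration: high y = cranial diaphragm
        assert curve.orientation == "expiration-up"
        assert spearmanr(curve.values, truth.displacement_px).statistic > 0

    def test_monotone_between_extrema(self, phantom_slice):
        series, truth = phantom_slice
        from conftest import RESP_ROI
        curve = rs.respiratory_curve(series, RESP_ROI)
        # between consecutive opposite extrema the curve is monotone in
        # displacement (checked via strong rank correlation per segment)
        ev = sorted(np.r_[truth.expiration_extrema, truth.inspiration_extrema])
        for a, b in zip(ev[:-1], ev[1:]):
            if b - a < 10:
                continue
            seg = slice(a + 3, b - 2)  # clear of plateau ties
            rho = spearmanr(curve.values[seg], truth.displacement_px[seg]).statistic
            assert abs(rho) >= 0.95


class TestOrientation:
    def test_sign_symmetric(self, phantom_slice):
        series, _ = phantom_slice
        from conftest import RESP_ROI
        X = rs.crop_roi(series, RESP_ROI)
        graph = TemporalGraph.from_sub_images(X, k=10)
        raw = rs.laplacian_embedding_1d(graph)
        flipped = rs.RespCurve(-raw.values, provenance=dict(raw.provenance))
        o1 = rs.orient_curve(raw, X, RESP_ROI.shape)
        o2 = rs.orient_curve(flipped, X, RESP_ROI.shape)
        assert np.allclose(o1.values, o2.values)
        assert o1.orientation == o2.orientation == "expiration-up"

    def test_symmetric_signal_without_centroid_is_undetermined(self):
        # pure sinusoid in a synthetic feature space uncorrelated with rows
        n = 200
        y = np.sin(2 * np.pi * np.arange(n) / 40)
        rng = np.random.default_rng(0)
        X = rng.random((n, 64))  # centroid uncorrelated with y
        curve = rs.RespCurve(y)
        out = rs.orient_curve(curve, X, (8, 8))
        assert out.orientation == "undetermined"
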