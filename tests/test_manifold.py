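import numpy as np
import pandas as pd
import pytest

from curvetracks import TrackSet
from curvetracks.directional import (AngleDistribution, deviation_distance,
                                     persistence_angles)
from curvetracks.exceptions import (DimensionalityError,
                                    DisconnectedGraphError, ParameterError,
                                    UndefinedAngleError)
from curvetracks.manifold import (MetricManifold, build_graph,
                                  estimate_metric, graph_laplacian,
                                  riemannian_angle, riemannian_inner,
                                  riemannian_norm, spectral_embed)


def flat_cloud(n, rng, side=2.0):
    P = rng.uniform(-side / 2, side / 2, size=(n, 2))
    return P, np.column_stack([P, np.zeros(n)])


class TestGraph:
    def test_three_equidistant_points_complete(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0.0]])
        g = build_graph(pts, k=2, bandwidth=1.0)
        W = g.weights.toarray()
        off = W[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0]) and off[0] > 0
        assert np.allclose(np.diag(W), 1.0)

    def test_weights_monotone_in_distance(self, rng):
        pts = rng.normal(size=(50, 3))
        g = build_graph(pts, k=10, bandwidth=0.5)
        W = g.weights.tocoo()
        D = np.sqrt(g.dist2.toarray())
        mask = (W.row != W.col)
        d = D[W.row[mask], W.col[mask]]
        w = W.data[mask]
        order = np.argsort(d)
        assert np.all(np.diff(w[order]) <= 1e-12)

    def test_two_distant_clusters_disconnected(self, rng):
        a = rng.normal(scale=0.1, size=(30, 3))
        b = rng.normal(scale=0.1, size=(20, 3)) + 100
        with pytest.raises(DisconnectedGraphError) as ei:
            build_graph(np.vstack([a, b]), k=5, bandwidth=0.2)
        assert ei.value.component_sizes == [30, 20]


class TestLaplacian:
    def test_annihilates_constants(self, rng):
        _, X = flat_cloud(400, rng)
        lap = graph_laplacian(build_graph(X, k=40, bandwidth=0.15))
        assert np.max(np.abs(lap(np.ones(400)))) < 1e-10

    def test_flat_quadratic_curvature(self, rng):
        P, X = flat_cloud(2000, rng)
        lap = graph_laplacian(build_graph(X, k=64, bandwidth=0.12))
        val = lap(P[:, 0] ** 2)
        interior = np.all(np.abs(P) < 0.6, axis=1)
        assert abs(np.median(val[interior]) - 2.0) < 0.3

    def test_circle_eigenfunction_error_decreases(self):
        """L sin = -sin on the unit circle, with error shrinking as n
        grows (bandwidth scaled as n^(-1/5))."""
        rng = np.random.default_rng(1)
        errs = []
        for n in (200, 800, 3200):
            th = rng.uniform(0, 2 * np.pi, n)
            X = np.column_stack([np.cos(th), np.sin(th), np.zeros(n)])
            eps = n ** -0.2
            k = min(n - 1, int(np.ceil(3 * eps * n / np.pi)))
            lap = graph_laplacian(build_graph(X, k=k, bandwidth=eps),
                                  intrinsic_dim=1)
            f = np.sin(th)
            errs.append(np.sqrt(np.mean((lap(f) + f) ** 2))
                        / np.sqrt(np.mean(f ** 2)))
        assert errs[2] < errs[1] < errs[0]


class TestMetricEstimation:
    def test_flat_linear_map_pullback(self, rng):
        """g recovers (A^-1)' A^-1 for an affinely distorted flat
        chart, median relative Frobenius error < 5%."""
        P, X = flat_cloud(2000, rng)
        A = np.array([[1.3, 0.4], [-0.2, 0.7]])
        Y = P @ A.T
        lap = graph_laplacian(build_graph(X))
        # averaging is bias-free on an affine chart (constant h field)
        mf = estimate_metric(Y, lap, points3d=X, smooth=1)
        G = np.linalg.inv(A @ A.T)
        interior = ~mf.boundary
        err = np.linalg.norm(mf.g[interior] - G, axis=(1, 2)) \
            / np.linalg.norm(G)
        assert np.median(err) < 0.05
        assert np.all(mf.rank[interior] == 2)

    def test_scaling_inverts_as_s_squared(self, rng):
        P, X = flat_cloud(1500, rng)
        s = 3.0
        lap = graph_laplacian(build_graph(X))
        mf = estimate_metric(s * P, lap, points3d=X)
        interior = ~mf.boundary
        med = np.median(mf.g[interior], axis=0)
        assert np.allclose(med, np.eye(2) / s ** 2, atol=0.05 / s ** 2)

    def test_pullback_equivariance_property(self, rng):
        """For any invertible linear reparameterization A of a flat
        embedding, g transforms as the pullback (A^-1)' g A^-1."""
        P, X = flat_cloud(1500, rng)
        lap = graph_laplacian(build_graph(X))
        g0 = estimate_metric(P, lap, points3d=X).g
        for _ in range(3):
            A = rng.normal(size=(2, 2)) + 2 * np.eye(2)
            gA = estimate_metric(P @ A.T, lap, points3d=X).g
            Ainv = np.linalg.inv(A)
            expected = Ainv.T @ np.median(g0, axis=0) @ Ainv
            assert np.allclose(np.median(gA, axis=0), expected,
                               atol=0.08 * np.linalg.norm(expected))

    def test_angle_statistics_affine_invariant_on_flat_tracks(
            self, plane_brownian_small):
        """The whole point of the metric: angle distributions computed
        with (embedding, metric) do not depend on how the chart is
        affinely reparameterized."""
        ts = plane_brownian_small.tracks3d
        X = ts.positions()
        P = X[:, :2]
        lap = graph_laplacian(build_graph(X))
        A = np.array([[2.0, 0.9], [0.0, 0.4]])
        devs = []
        for emb in (P, P @ A.T):
            mf = estimate_metric(emb, lap, points3d=X)
            t2 = ts.with_positions(emb, method_tag="manifold")
            d = persistence_angles(t2, metric=mf)
            devs.append(d)
        tv = 0.5 * np.sum(np.abs(devs[0].density - devs[1].density)) \
            * devs[0].bin_width
        assert tv < 0.02


class TestRiemannianOps:
    def test_identity_metric_reduces_to_euclidean(self):
        g = np.eye(2)
        assert riemannian_angle([1, 0], [0, 1], g) == pytest.approx(
            np.pi / 2)
        assert riemannian_angle([1, 0], [1, 1], g) == pytest.approx(
            np.pi / 4)

    def test_diagonal_metric_norms(self):
        g = np.diag([4.0, 1.0])
        assert riemannian_inner([1, 0], [0, 1], g) == 0.0
        assert riemannian_norm(np.array([1.0, 0.0]), g) == 2.0
        assert riemannian_norm(np.array([0.0, 1.0]), g) == 1.0

    def test_cauchy_schwarz_random_psd(self, rng):
        for _ in range(50):
            B = rng.normal(size=(2, 2))
            g = B @ B.T + 1e-6 * np.eye(2)
            u, v = rng.normal(size=2), rng.normal(size=2)
            lhs = abs(riemannian_inner(u, v, g))
            rhs = riemannian_norm(u, g) * riemannian_norm(v, g)
            assert lhs <= rhs * (1 + 1e-12)

    def test_zero_vector_angle_undefined(self):
        with pytest.raises(UndefinedAngleError):
            riemannian_angle([0.0, 0.0], [1.0, 0.0], np.eye(2))

    def test_sign_follows_orientation(self):
        g = np.eye(2)
        assert riemannian_angle([1, 0], [0, 1], g) > 0
        assert riemannian_angle([0, 1], [1, 0], g) < 0


class TestModelInterface:
    def test_hemisphere_fit_and_summary(self, hemisphere_brownian):
        res = MetricManifold(hemisphere_brownian.tracks3d).fit()
        assert res.embedding.shape == (hemisphere_brownian.tracks3d.n_points,
                                       2)
        assert np.mean(res.metric.rank == 2) > 0.9
        assert "eigenmaps" in res.summary()

    def test_extra_points_embedded(self, hemisphere_brownian):
        tgt = np.array([0.0, 0.0, 1.0])
        res = MetricManifold(hemisphere_brownian.tracks3d,
                             extra_points=[tgt]).fit()
        assert res.extra_embedded.shape == (1, 2)
        # the pole's image lies inside the embedded cloud
        lo = res.embedding.min(axis=0)
        hi = res.embedding.max(axis=0)
        assert np.all(res.extra_embedded[0] > lo)
        assert np.all(res.extra_embedded[0] < hi)

    def test_sparse_thin_ellipsoid_collapses_to_1d(self):
        from curvetracks.walks import preset_model, preset_surface, \
            simulate_walk
        surface, region, L, _ = preset_surface("ellipsoid_thin")
        m = preset_model("brownian", "ellipsoid_thin")
        sim = simulate_walk(surface, m, 20, 60, 7, start_region=region)
        with pytest.raises(DimensionalityError):
            MetricManifold(sim.tracks3d).fit()

    def test_invalid_embedding_name(self, hemisphere_brownian):
        with pytest.raises(ParameterError):
            MetricManifold(hemisphere_brownian.tracks3d,
                           embedding="umap")
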