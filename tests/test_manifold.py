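import numpy as np
import pytest
from scipy import linalg as sla

from spikedet import (
    EmbeddingModel,
    GraphParams,
    build_graph,
    estimate_intrinsic_dim,
    fit_lpp,
    transform,
)


def _ball_in_ambient(intrinsic, ambient, n, seed, noise=0.01):
    """Uniform sample of an intrinsic-D ball linearly embedded in ambient-D."""
    rng = np.random.default_rng(seed)
    p = rng.standard_normal((n, intrinsic))
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    radii = rng.uniform(0, 1, n) ** (1 / intrinsic)
    pts = p * radii[:, None]
    B = rng.standard_normal((ambient, intrinsic))
    return B @ pts.T + noise * rng.standard_normal((ambient, n))


class TestIntrinsicDim:
    def test_line_in_10d_estimates_one(self):
        t = np.linspace(0, 1, 500)
        X = np.outer(np.arange(1, 11), t)
        X += 1e-9 * np.random.default_rng(0).standard_normal(X.shape)
        assert estimate_intrinsic_dim(X) == 1

    def test_3d_ball_in_20d_estimates_three(self):
        X = _ball_in_ambient(3, 20, 1000, seed=42)
        assert abs(estimate_intrinsic_dim(X) - 3) <= 1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            estimate_intrinsic_dim(np.zeros((5, 12)), k_min=6, k_max=12)

    def test_duplicate_points_warn_not_crash(self):
        X = np.ones((4, 30))
        X[:, ::2] += np.random.default_rng(1).standard_normal((4, 15)) * 0.1
        with pytest.warns(UserWarning, match="duplicate"):
            est = estimate_intrinsic_dim(X, k_min=2, k_max=4)
        assert est >= 1


class TestBuildGraph:
    def test_symmetric_zero_diagonal(self):
        X = np.random.default_rng(2).standard_normal((5, 40))
        W, D, L = build_graph(X)
        np.testing.assert_array_equal(W, W.T)
        assert np.all(np.diag(W) == 0)

    def test_laplacian_rows_sum_to_zero(self):
        X = np.random.default_rng(3).standard_normal((4, 25))
        _W, _D, L = build_graph(X)
        np.testing.assert_allclose(L.sum(axis=1), 0.0, atol=1e-12)

    def test_two_points_closed_form(self):
        X = np.array([[0.0, 3.0], [0.0, 4.0]])  # distance 5
        params = GraphParams(n_neighbors=1, heat_t=10.0)
        W, D, L = build_graph(X, params)
        expected = np.exp(-25.0 / 10.0)
        assert W[0, 1] == pytest.approx(expected)
        assert D[0, 0] == pytest.approx(expected)
        assert D[1, 1] == pytest.approx(expected)

    def test_binary_mode(self):
        X = np.random.default_rng(4).standard_normal((3, 20))
        W, _, _ = build_graph(X, GraphParams(n_neighbors=3, weight_mode="binary"))
        assert set(np.unique(W)) <= {0.0, 1.0}


@pytest.fixture(scope="module")
def seeded_fit():
    X = np.random.default_rng(5).standard_normal((5, 20))
    return X, fit_lpp(X, 3)


class TestFitLpp:
    def test_generalized_eigen_residual(self, seeded_fit):
        X, model = seeded_fit
        _W, D, L = build_graph(X, model.graph)
        Sl, Sd = X @ L @ X.T, X @ D @ X.T
        for j in range(model.l):
            a, lam = model.A[:, j], model.eigenvalues[j]
            res = np.linalg.norm(Sl @ a - lam * Sd @ a) / np.linalg.norm(Sd @ a)
            assert res < 1e-6

    def test_eigenvalues_ascending_and_nonnegative(self, seeded_fit):
        _, model = seeded_fit
        assert np.all(np.diff(model.eigenvalues) >= -1e-12)
        assert np.all(model.eigenvalues >= -1e-10)

    def test_d_normalisation_and_sign(self, seeded_fit):
        X, model = seeded_fit
        _W, D, _L = build_graph(X, model.graph)
        Sd = X @ D @ X.T
        for j in range(model.l):
            a = model.A[:, j]
            assert a @ Sd @ a == pytest.approx(1.0, abs=1e-8)
            nz = np.flatnonzero(np.abs(a) > 1e-12)
            assert a[nz[0]] > 0

    def test_matches_dense_generalized_eigensolver(self):
        """Independent oracle: scipy's general (non-symmetric) eig route."""
        X = np.random.default_rng(6).standard_normal((8, 25))
        model = fit_lpp(X, 4)
        _W, D, L = build_graph(X, model.graph)
        Sl, Sd = X @ L @ X.T, X @ D @ X.T
        w, v = sla.eig(Sl, Sd)
        order = np.argsort(w.real)
        w, v = w.real[order], v.real[:, order]
        for j in range(model.l):
            assert w[j] == pytest.approx(model.eigenvalues[j], abs=1e-8)
            a = v[:, j] / np.sqrt(v[:, j] @ Sd @ v[:, j])
            nz = np.flatnonzero(np.abs(a) > 1e-12)
            if a[nz[0]] < 0:
                a = -a
            np.testing.assert_allclose(a, model.A[:, j], atol=1e-8)

    def test_separated_clusters_separate_in_1d(self):
        rng = np.random.default_rng(7)
        c1 = rng.standard_normal((10, 30)) + 20.0
        c2 = rng.standard_normal((10, 30)) - 20.0
        X = np.concatenate([c1, c2], axis=1)
        model = fit_lpp(X, 1)
        y = transform(model, X)[0]
        assert max(y[:30].min(), y[30:].min()) > min(y[:30].max(), y[30:].max()) \
            or max(y[30:].min(), y[:30].min()) > min(y[30:].max(), y[:30].max())
        # no overlap between the two embedded clusters
        lo1, hi1 = y[:30].min(), y[:30].max()
        lo2, hi2 = y[30:].min(), y[30:].max()
        assert hi1 < lo2 or hi2 < lo1

    def test_column_permutation_invariance_up_to_sign(self):
        X = np.random.default_rng(8).standard_normal((6, 30))
        perm = np.random.default_rng(9).permutation(30)
        m1 = fit_lpp(X, 2)
        m2 = fit_lpp(X[:, perm], 2)
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-8)
        np.testing.assert_allclose(np.abs(m1.A), np.abs(m2.A), atol=1e-6)

    def test_locality_preserved_better_than_random_projection(self):
        rng = np.random.default_rng(10)
        centers = rng.standard_normal((4, 12)) * 15
        pts = np.concatenate(
            [centers[i] + rng.standard_normal((25, 12)) for i in range(4)]
        )
        X = pts.T
        l = 2
        model = fit_lpp(X, l)
        Y = transform(model, X)
        R = rng.standard_normal((l, 12))
        Y_rand = R @ X

        def knn_overlap(A, B, k=5):
            from sklearn.neighbors import NearestNeighbors

            na = NearestNeighbors(n_neighbors=k + 1).fit(A.T)
            nb = NearestNeighbors(n_neighbors=k + 1).fit(B.T)
            ia = na.kneighbors(A.T, return_distance=False)[:, 1:]
            ib = nb.kneighbors(B.T, return_distance=False)[:, 1:]
            return np.mean(
                [len(set(r1) & set(r2)) / k for r1, r2 in zip(ia, ib)]
            )

        assert knn_overlap(X, Y) >= knn_overlap(X, Y_rand)


class TestTransform:
    def test_training_columns_reproduced(self):
        X = np.random.default_rng(11).standard_normal((5, 20))
        model = fit_lpp(X, 2)
        Y = transform(model, X)
        np.testing.assert_array_equal(Y[:, 3], transform(model, X[:, 3]).ravel())

    def test_linearity(self):
        X = np.random.default_rng(12).standard_normal((5, 20))
        model = fit_lpp(X, 2)
        x = X[:, 0]
        np.testing.assert_allclose(
            transform(model, 2 * x), 2 * transform(model, x), atol=1e-12
        )
        np.testing.assert_array_equal(transform(model, np.zeros(5)), 0.0)

    def test_dimension_mismatch_rejected(self):
        X = np.random.default_rng(13).standard_normal((5, 20))
        model = fit_lpp(X, 2)
        with pytest.raises(ValueError):
            transform(model, np.zeros((4, 3)))


def test_embedding_model_json_round_trip(tmp_path):
    X = np.random.default_rng(14).standard_normal((5, 20))
    model = fit_lpp(X, 2)
    p = tmp_path / "emb.json"
    model.to_json(p)
    back = EmbeddingModel.from_json(p)
    np.testing.assert_array_equal(back.A, model.A)
    np.testing.assert_array_equal(back.eigenvalues, model.eigenvalues)
    assert back.graph.n_neighbors == model.graph.n_neighbors
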