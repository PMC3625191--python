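"""LLE: weight constraints, exact recovery of locally flat data,
out-of-sample mapping, invariances; PCA baseline against a covariance
eigendecomposition oracle."""

import numpy as np
import pytest

import fcmvpa as f
from fcmvpa.embedding import (
    lle_fit_arrays,
    reconstruction_cost,
    solve_reconstruction_weights,
)


def plane_data(n=200, p=10, seed=0):
    rng = np.random.default_rng(seed)
    coords = rng.normal(size=(n, 2))
    A = rng.normal(size=(2, p))
    offset = rng.normal(size=p)
    return coords @ A + offset, coords


class TestLLEFit:
    def test_weight_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 12))
        lle = f.OutOfSampleLLE(n_neighbors=8, n_components=4).fit(X)
        np.testing.assert_allclose(lle.weights_.sum(axis=1), 1.0, atol=1e-8)
        assert lle.weights_.shape == (60, 8)

    def test_planar_data_recovered_exactly(self):
        X, coords = plane_data()
        lle = f.OutOfSampleLLE(n_neighbors=8, n_components=2).fit(X)
        assert reconstruction_cost(lle._model) <= 1e-10
        assert f.affine_alignment_residual(lle.embedding_, coords) <= 1e-6

    def test_constant_eigenvector_excluded(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 6))
        lle = f.OutOfSampleLLE(n_neighbors=6, n_components=3).fit(X)
        # smallest eigenvalue ~0 belongs to the constant vector, which must
        # not appear in the embedding: columns are orthogonal to 1
        assert lle.eigenvalues_[0] == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(lle.embedding_.sum(axis=0), 0.0, atol=1e-6)
        # columns orthonormal
        np.testing.assert_allclose(
            lle.embedding_.T @ lle.embedding_, np.eye(3), atol=1e-8
        )

    def test_collinear_points_embed_monotonically(self):
        t = np.arange(10.0)
        X = np.outer(t, np.array([1.0, -2.0, 0.5]))
        lle = f.OutOfSampleLLE(n_neighbors=2, n_components=1).fit(X)
        y = lle.embedding_[:, 0]
        d = np.diff(y)
        assert (d > 0).all() or (d < 0).all()

    def test_rigid_motion_invariance(self):
        # on data with a clean eigengap (locally flat manifold) a rotated
        # and shifted copy must yield the same embedding up to affine map
        X, coords = plane_data(n=120, p=6, seed=2)
        rng = np.random.default_rng(2)
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        shift = rng.normal(size=6)
        a = f.OutOfSampleLLE(n_neighbors=8, n_components=2).fit(X)
        b = f.OutOfSampleLLE(n_neighbors=8, n_components=2).fit(X @ Q + shift)
        assert f.affine_alignment_residual(a.embedding_, coords) <= 1e-6
        assert f.affine_alignment_residual(b.embedding_, coords) <= 1e-6

    def test_exact_weights_are_local_minimizers(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 20))  # k < p: full-rank local Grams
        model = lle_fit_arrays(X, k=5, d=2, reg=1e-3)
        base = reconstruction_cost(model)
        for trial in range(20):
            i = int(rng.integers(40))
            delta = rng.normal(size=5) * 0.01
            delta -= delta.mean()  # keep the sum-to-one constraint
            w = model["weights"][i] + delta
            Z = X[model["neighbors"][i]]
            cost_i = float(((X[i] - w @ Z) ** 2).sum())
            base_i = float(((X[i] - model["weights"][i] @ Z) ** 2).sum())
            assert cost_i >= base_i - 1e-12

    def test_duplicate_points_warn_but_fit(self):
        X = np.zeros((10, 3))
        X[5:] = 1.0
        with pytest.warns(UserWarning, match="duplicate"):
            lle = f.OutOfSampleLLE(n_neighbors=3, n_components=1).fit(X)
        np.testing.assert_allclose(lle.weights_.sum(axis=1), 1.0, atol=1e-8)

    def test_parameter_validation(self):
        X = np.random.default_rng(4).normal(size=(10, 4))
        with pytest.raises(ValueError):
            f.OutOfSampleLLE(n_neighbors=10, n_components=2).fit(X)
        with pytest.raises(ValueError):
            f.OutOfSampleLLE(n_neighbors=4, n_components=9).fit(X)

    def test_neighbors_match_sklearn_and_cost_not_worse(self):
        # dual route: same k-NN graph as sklearn, and our exact weight
        # solver never reconstructs worse than sklearn's ridge weights
        from sklearn.manifold._locally_linear import barycenter_kneighbors_graph
        from sklearn.neighbors import NearestNeighbors

        rng = np.random.default_rng(5)
        X = rng.normal(size=(45, 8))
        model = lle_fit_arrays(X, k=6, d=2, reg=1e-3)
        nn = NearestNeighbors(n_neighbors=7).fit(X)
        sk_neigh = nn.kneighbors(X, return_distance=False)[:, 1:]
        assert np.array_equal(np.sort(model["neighbors"], 1), np.sort(sk_neigh, 1))
        ours = reconstruction_cost(model)
        Wg = barycenter_kneighbors_graph(X, n_neighbors=6, reg=1e-3)
        theirs = float(np.sum(np.asarray(X - Wg @ X) ** 2))
        assert ours <= theirs + 1e-10


class TestWeightSolver:
    def test_well_conditioned_matches_direct_solve(self):
        rng = np.random.default_rng(0)
        B = rng.normal(size=(6, 6))
        G = B @ B.T + 0.5 * np.eye(6)
        w = solve_reconstruction_weights(G)
        direct = np.linalg.solve(G, np.ones(6))
        np.testing.assert_allclose(w, direct / direct.sum(), atol=1e-10)

    def test_all_zero_gram_gives_uniform(self):
        w = solve_reconstruction_weights(np.zeros((4, 4)))
        np.testing.assert_allclose(w, 0.25, atol=1e-12)


class TestOutOfSample:
    def test_training_point_with_exact_reconstruction_maps_to_itself(self):
        X, coords = plane_data(n=150, seed=1)
        lle = f.OutOfSampleLLE(n_neighbors=8, n_components=2).fit(X)
        z = lle.transform(X[17][None, :])
        np.testing.assert_allclose(z[0], lle.embedding_[17], atol=1e-6)

    def test_barycenter_maps_to_barycenter(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 6))
        k = 5
        lle = f.OutOfSampleLLE(n_neighbors=k, n_components=2).fit(X)
        from scipy.spatial.distance import cdist

        x_new = X[:k].mean(axis=0)
        d = cdist(x_new[None], X)[0]
        nearest = np.argsort(d, kind="stable")[:k]
        # construct a point that IS the barycenter of its k nearest points
        x_new = X[nearest].mean(axis=0)
        d2 = cdist(x_new[None], X)[0]
        nearest2 = np.sort(np.argsort(d2, kind="stable")[:k])
        if not np.array_equal(np.sort(nearest), nearest2):
            pytest.skip("barycenter moved outside its neighborhood")
        z = lle.transform(x_new[None, :])
        np.testing.assert_allclose(
            z[0], lle.embedding_[nearest2].mean(axis=0), atol=1e-8
        )

    def test_held_out_plane_point_lands_on_plane(self):
        X, coords = plane_data(n=200, seed=3)
        lle = f.OutOfSampleLLE(n_neighbors=8, n_components=2).fit(X)
        rng = np.random.default_rng(4)
        new_coords = rng.normal(size=(30, 2)) * 0.8
        A = np.linalg.lstsq(
            np.column_stack([coords, np.ones(200)]), X, rcond=None
        )[0]
        X_new = np.column_stack([new_coords, np.ones(30)]) @ A
        Z = lle.transform(X_new)
        resid = f.affine_alignment_residual(
            np.vstack([lle.embedding_, Z]), np.vstack([coords, new_coords])
        )
        assert resid <= 1e-3

    def test_unfitted_model_rejected(self):
        with pytest.raises(Exception):
            f.OutOfSampleLLE().transform(np.zeros((1, 3)))

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 5))
        lle = f.OutOfSampleLLE(n_neighbors=5, n_components=2).fit(X)
        lle.save(tmp_path / "model")
        back = f.OutOfSampleLLE.load(tmp_path / "model")
        x = rng.normal(size=(3, 5))
        np.testing.assert_allclose(back.transform(x), lle.transform(x), atol=1e-10)


class TestPCA:
    def test_exact_subspace_zero_test_error(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(3, 12))
        train = rng.normal(size=(40, 3)) @ basis + 5.0
        test = rng.normal(size=(10, 3)) @ basis + 5.0
        Ztr, Zte = f.pca_fit_transform(train, test, 3)
        mean = train.mean(0)
        # reconstruct from scores: projection must be lossless on the subspace
        U = np.linalg.lstsq(Ztr, train - mean, rcond=None)[0]
        np.testing.assert_allclose(Zte @ U + mean, test, atol=1e-8)

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 10))
        Ztr, _ = f.pca_fit_transform(X, X[:1], 3)
        Xc = X - X.mean(0)
        lam, V = np.linalg.eigh(Xc.T @ Xc / (50 - 1))
        V = V[:, ::-1][:, :3]
        oracle = Xc @ V
        for j in range(3):  # sign per component is arbitrary
            assert min(
                np.abs(Ztr[:, j] - oracle[:, j]).max(),
                np.abs(Ztr[:, j] + oracle[:, j]).max(),
            ) < 1e-8

    def test_d_out_of_range_rejected(self):
        X = np.zeros((10, 4))
        with pytest.raises(ValueError):
            f.pca_fit_transform(X, X, 11)
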