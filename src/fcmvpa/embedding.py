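"""Locally linear embedding with an out-of-sample extension, plus a PCA
baseline.

LLE proceeds in three steps: (1) Euclidean k-nearest neighbors of every
point; (2) reconstruction weights W minimizing

    E(W) = sum_i || x_i - sum_j W_ij x_j ||^2,   sum_j W_ij = 1,

with W_ij nonzero only over the k neighbors of i; (3) the embedding Y
given by the eigenvectors of M = (I - W)^T (I - W) for the d smallest
nonzero eigenvalues.  The constant eigenvector (eigenvalue 0, guaranteed
by row-stochastic W) is discarded.

Held-out subjects are mapped by the standard reconstruction-weight
extension: solve the same constrained weight problem over the new point's
k nearest *training* points and combine those points' embedding rows.
Refitting with the new point included would leak it into the manifold, so
it is never done here.

The local weight systems are solved through an eigendecomposition of the
k x k Gram matrix: well-conditioned systems are solved exactly (the
weights are then exact minimizers of E); singular systems whose
constraint vector has a null-space component get the exact zero-cost
null-space solution (this is what makes locally flat data reproduce
exactly); only the remaining degenerate cases fall back to the usual
trace-scaled ridge.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "OutOfSampleLLE",
    "lle_fit_arrays",
    "lle_transform_arrays",
    "reconstruction_cost",
    "solve_reconstruction_weights",
    "pca_fit_transform",
    "affine_alignment_residual",
]

_RANK_RTOL = 1e-10  # relative eigenvalue cutoff separating null space from range
_NULL_ATOL = 1e-6  # minimum ||P_null(1)|| / sqrt(k) to trust the null-space solution


def solve_reconstruction_weights(G: np.ndarray, reg: float = 1e-3) -> np.ndarray:
    """Sum-to-one weights minimizing w^T G w for a stack of local Gram
    matrices G of shape (m, k, k).  Returns (m, k) weight rows.
    """
    G = np.asarray(G, dtype=float)
    squeeze = G.ndim == 2
    if squeeze:
        G = G[None]
    m, k, _ = G.shape
    lam, V = np.linalg.eigh(G)
    lam = np.clip(lam, 0.0, None)
    a = V.sum(axis=1)  # a_j = v_j . 1
    lam_max = lam[:, -1]
    null = lam <= (_RANK_RTOL * lam_max)[:, None]
    has_null = null.any(axis=1)
    null_a2 = np.where(null, a**2, 0.0).sum(axis=1)
    use_null = has_null & (null_a2 > (_NULL_ATOL**2) * k)

    with np.errstate(divide="ignore", invalid="ignore"):
        coef_exact = a / np.where(lam > 0, lam, 1.0)
        ridge = reg * lam.sum(axis=1, keepdims=True)
        ridge = np.where(ridge > 0, ridge, 1.0)  # all-zero Gram -> handled by null path
        coef_ridge = a / (lam + ridge)
    coef_null = np.where(null, a, 0.0)
    coef = np.where(
        use_null[:, None], coef_null, np.where(has_null[:, None], coef_ridge, coef_exact)
    )
    w = np.einsum("mij,mj->mi", V, coef)
    s = w.sum(axis=1, keepdims=True)
    if np.any(np.abs(s) < 1e-300):  # pragma: no cover - pathological
        raise np.linalg.LinAlgError("degenerate local weight system")
    w = w / s
    return w[0] if squeeze else w


def _neighbor_indices(D2: np.ndarray, k: int) -> np.ndarray:
    """k smallest entries per row of a squared-distance matrix, ties broken
    by the smaller column index (stable sort)."""
    order = np.argsort(D2, axis=1, kind="stable")
    return order[:, :k]


def _local_grams(points: np.ndarray, reference: np.ndarray, neigh: np.ndarray) -> np.ndarray:
    Z = reference[neigh] - points[:, None, :]
    return np.einsum("mkp,mlp->mkl", Z, Z)


def lle_fit_arrays(
    X: np.ndarray, k: int, d: int, reg: float = 1e-3
) -> dict[str, np.ndarray]:
    """Array-level LLE fit returning neighbors, weight rows, the embedding
    and the eigenvalues of M.  Used by :class:`OutOfSampleLLE` and by the
    cross-validation fast path."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not (1 <= k < n):
        raise ValueError(f"need 1 <= k < n, got k={k}, n={n}")
    if not (1 <= d <= n - 2):
        raise ValueError(f"need 1 <= d <= n-2 eigenvectors, got d={d}, n={n}")
    D2 = cdist(X, X, metric="sqeuclidean")
    np.fill_diagonal(D2, np.inf)
    neigh = _neighbor_indices(D2, k)
    G = _local_grams(X, X, neigh)
    if np.any(np.all(G == 0.0, axis=(1, 2))):
        warnings.warn(
            "duplicate points produced degenerate neighborhoods; "
            "weights fall back to the uniform null-space solution",
            stacklevel=2,
        )
    W_rows = solve_reconstruction_weights(G, reg)
    Wd = np.zeros((n, n))
    np.put_along_axis(Wd, neigh, W_rows, axis=1)
    IW = np.eye(n) - Wd
    M = IW.T @ IW
    lam, U = np.linalg.eigh(M)
    # eigenvalue 0 with the constant eigenvector always exists; skip it
    Y = U[:, 1 : d + 1]
    return {
        "X": X,
        "neighbors": neigh,
        "weights": W_rows,
        "embedding": Y,
        "eigenvalues": lam,
        "k": k,
        "d": d,
        "reg": reg,
    }


def lle_transform_arrays(model: dict, X_new: np.ndarray) -> np.ndarray:
    """Out-of-sample mapping: constrained reconstruction weights over each
    new point's k nearest training points, applied to their embedding rows."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    X_train = model["X"]
    k = model["k"]
    D2 = cdist(X_new, X_train, metric="sqeuclidean")
    neigh = _neighbor_indices(D2, k)
    G = _local_grams(X_new, X_train, neigh)
    w = np.atleast_2d(solve_reconstruction_weights(G, model["reg"]))
    return np.einsum("mk,mkd->md", w, model["embedding"][neigh])


def reconstruction_cost(model: dict) -> float:
    """E(W): summed squared distances between training points and their
    neighbor reconstructions."""
    X = model["X"]
    recon = np.einsum("mk,mkp->mp", model["weights"], X[model["neighbors"]])
    return float(((X - recon) ** 2).sum())


class OutOfSampleLLE(TransformerMixin, BaseEstimator):
    """Locally linear embedding that can map unseen points.

    Parameters
    ----------
    n_neighbors : int, default 8
        Neighborhood size k of the Euclidean k-NN graph.
    n_components : int, default 10
        Embedding dimension d (the d smallest nonzero eigenvectors of M).
    reg : float, default 1e-3
        Trace-scaled ridge used only for degenerate local Gram systems.

    Attributes
    ----------
    embedding_ : ndarray (n, d)
        Training embedding; columns are orthonormal eigenvectors of M.
    weights_ : ndarray (n, k)
        Reconstruction weight rows (each sums to 1).
    neighbors_ : ndarray (n, k)
        Training neighbor indices of every training point.
    eigenvalues_ : ndarray (n,)
        Spectrum of M = (I - W)^T (I - W), ascending.
    """

    def __init__(self, n_neighbors: int = 8, n_components: int = 10, reg: float = 1e-3):
        self.n_neighbors = n_neighbors
        self.n_components = n_components
        self.reg = reg

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        model = lle_fit_arrays(X, self.n_neighbors, self.n_components, self.reg)
        self.X_train_ = model["X"]
        self.neighbors_ = model["neighbors"]
        self.weights_ = model["weights"]
        self.embedding_ = model["embedding"]
        self.eigenvalues_ = model["eigenvalues"]
        self._model = model
        return self

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.embedding_

    def transform(self, X):
        check_is_fitted(self, "embedding_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.X_train_.shape[1]:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fitted with "
                f"{self.X_train_.shape[1]}"
            )
        return lle_transform_arrays(self._model, X)

    # -- audit serialization -------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Serialize the fitted state to a directory of TSVs."""
        check_is_fitted(self, "embedding_")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "training_points.tsv", self.X_train_, delimiter="\t")
        np.savetxt(directory / "neighbors.tsv", self.neighbors_, delimiter="\t", fmt="%d")
        np.savetxt(directory / "weights.tsv", self.weights_, delimiter="\t")
        np.savetxt(directory / "embedding.tsv", self.embedding_, delimiter="\t")
        np.savetxt(directory / "eigenvalues.tsv", self.eigenvalues_, delimiter="\t")
        (directory / "params.tsv").write_text(
            "n_neighbors\tn_components\treg\n"
            f"{self.n_neighbors}\t{self.n_components}\t{self.reg}\n",
            encoding="utf-8",
        )

    @classmethod
    def load(cls, directory: str | Path) -> "OutOfSampleLLE":
        directory = Path(directory)
        lines = (directory / "params.tsv").read_text(encoding="utf-8").splitlines()
        k_s, d_s, reg_s = lines[1].split("\t")
        est = cls(n_neighbors=int(k_s), n_components=int(d_s), reg=float(reg_s))
        est.X_train_ = np.loadtxt(directory / "training_points.tsv", delimiter="\t", ndmin=2)
        est.neighbors_ = np.loadtxt(
            directory / "neighbors.tsv", delimiter="\t", dtype=int, ndmin=2
        )
        est.weights_ = np.loadtxt(directory / "weights.tsv", delimiter="\t", ndmin=2)
        est.embedding_ = np.loadtxt(directory / "embedding.tsv", delimiter="\t", ndmin=2)
        est.eigenvalues_ = np.loadtxt(directory / "eigenvalues.tsv", delimiter="\t")
        est._model = {
            "X": est.X_train_,
            "neighbors": est.neighbors_,
            "weights": est.weights_,
            "embedding": est.embedding_,
            "eigenvalues": est.eigenvalues_,
            "k": est.n_neighbors,
            "d": est.n_components,
            "reg": est.reg,
        }
        return est


def pca_fit_transform(
    X_train: np.ndarray, X_test: np.ndarray, d: int
) -> tuple[np.ndarray, np.ndarray]:
    """Linear baseline: center by the training mean and project both sets
    on the top-d right singular directions of the centered training data."""
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    n, p = X_train.shape
    if not (1 <= d <= min(n - 1, p)):
        raise ValueError(f"need 1 <= d <= min(n-1, p) = {min(n - 1, p)}, got {d}")
    pca = PCA(n_components=d, svd_solver="full").fit(X_train)
    return pca.transform(X_train), pca.transform(X_test)


def affine_alignment_residual(Y: np.ndarray, target: np.ndarray) -> float:
    """RMS residual of the best affine map Y -> target (least squares).

    Used to compare embeddings that are only defined up to an affine
    transform, e.g. LLE output against known manifold coordinates.
    """
    Y = np.asarray(Y, dtype=float)
    target = np.asarray(target, dtype=float)
    A = np.column_stack([Y, np.ones(len(Y))])
    beta, *_ = np.linalg.lstsq(A, target, rcond=None)
    resid = target - A @ beta
    return float(np.sqrt((resid**2).mean()))
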