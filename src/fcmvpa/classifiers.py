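"""Back-end classifiers of the comparison grid: RBF-kernel SVM, Fisher
linear discriminant analysis, and fuzzy C-means clustering used as a
two-class classifier.

The SVM is scikit-learn's SVC with the radial basis kernel
K(x, y) = exp(-gamma ||x - y||^2); its default width gamma = 1 / (d *
var(X_train)) ("scale") since no width is part of the reference
operating point.  LDA and fuzzy C-means are implemented here: LDA in its
closed form (they are each a dozen lines, and tests cross-check them
against scikit-learn / brute-force oracles), C-means because no installed
package provides the fuzzy variant.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "make_svm",
    "svm_fit_predict_fast",
    "FisherLDA",
    "FuzzyCMeans",
    "export_classifier",
]


def make_svm(C: float = 2.0, gamma: float | str = "scale") -> SVC:
    """Soft-margin SVM with the RBF kernel exp(-gamma ||x-y||^2)."""
    if C <= 0:
        raise ValueError("C must be positive")
    if isinstance(gamma, (int, float)) and gamma <= 0:
        raise ValueError("gamma must be positive")
    return SVC(kernel="rbf", C=C, gamma=gamma, tol=1e-6)


def svm_fit_predict_fast(
    Z_train: np.ndarray,
    y_train: np.ndarray,
    Z_test: np.ndarray,
    C: float = 2.0,
    gamma: float | str = "scale",
) -> np.ndarray:
    """RBF-SVM fit + predict through scikit-learn's libsvm binding directly.

    Identical results to ``make_svm(C, gamma).fit(Z_train, y_train)
    .predict(Z_test)`` (same solver, same label encoding, same "scale"
    gamma), but without the per-call estimator validation overhead --
    the permutation test refits an SVM in every fold of every permuted
    LOOCV, so that overhead dominates otherwise.  A unit test pins the
    equivalence with the public estimator path.
    """
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
    Z_train = np.ascontiguousarray(Z_train, dtype=np.float64)
    Z_test = np.ascontiguousarray(Z_test, dtype=np.float64)
    classes, y_enc = np.unique(y_train, return_inverse=True)
    if gamma == "scale":
        var = Z_train.var()
        g = 1.0 / (Z_train.shape[1] * var) if var > 0 else 1.0
    else:
        g = float(gamma)
    model = _libsvm.fit(
        Z_train,
        y_enc.astype(np.float64),
        svm_type=0,
        kernel="rbf",
        gamma=g,
        C=float(C),
        tol=1e-6,
    )
    pred = _libsvm.predict(
        Z_test, *model[:7], svm_type=0, kernel="rbf", gamma=g
    )
    return classes[pred.astype(int)]


class FisherLDA(ClassifierMixin, BaseEstimator):
    """Fisher's linear discriminant for two classes.

    The discriminant direction is w = S_w^{-1} (mu_+ - mu_-) with S_w the
    pooled within-class covariance; the threshold sits at the midpoint of
    the projected class means (equal-prior rule).  When S_w is
    ill-conditioned a ridge of ``ridge * trace(S_w) / d`` is added to the
    diagonal.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("FisherLDA requires exactly two classes")
        self.classes_ = classes
        neg, pos = (X[y == c] for c in classes)
        mu_neg, mu_pos = neg.mean(axis=0), pos.mean(axis=0)
        n, d = X.shape
        scatter = (neg - mu_neg).T @ (neg - mu_neg) + (pos - mu_pos).T @ (pos - mu_pos)
        sw = scatter / max(n - 2, 1)
        lam = np.linalg.eigvalsh(sw)
        if lam[0] <= 1e-12 * max(lam[-1], 1e-300):
            warnings.warn(
                "pooled covariance is ill-conditioned; applying ridge",
                stacklevel=2,
            )
            sw = sw + (self.ridge * np.trace(sw) / d + 1e-300) * np.eye(d)
        w = np.linalg.solve(sw, mu_pos - mu_neg)
        self.coef_ = w
        self.means_ = np.vstack([mu_neg, mu_pos])
        self.intercept_ = -float(w @ (mu_pos + mu_neg) / 2.0)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict(self, X):
        score = self.decision_function(X)
        return np.where(score >= 0, self.classes_[1], self.classes_[0])


class FuzzyCMeans(ClassifierMixin, BaseEstimator):
    """Two-cluster fuzzy C-means used as a classifier.

    Clustering ignores the labels; they are only used afterwards to map
    each cluster to the training label holding its membership majority.
    Initialization is deterministic (centers at the two training points
    farthest apart), so results do not depend on a seed.

    Parameters
    ----------
    m : float, default 2.0
        Fuzziness exponent (> 1).
    tol : float, default 1e-6
        Convergence threshold on the max membership change.
    """

    def __init__(self, m: float = 2.0, max_iter: int = 300, tol: float = 1e-6):
        self.m = m
        self.max_iter = max_iter
        self.tol = tol

    def _memberships(self, X, centers):
        d2 = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        expo = 1.0 / (self.m - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-expo)
        u = inv / inv.sum(axis=1, keepdims=True)
        if zero.any():
            rows = zero.any(axis=1)
            u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
        return u

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if self.m <= 1:
            raise ValueError("fuzziness m must be > 1")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("FuzzyCMeans classification requires two classes")
        self.classes_ = classes
        n = X.shape[0]
        # deterministic init: the two points farthest apart (first such pair)
        d2 = ((X[:, None, :] - X[None]) ** 2).sum(axis=2)
        i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
        centers = X[[min(i, j), max(i, j)]].copy()
        u = self._memberships(X, centers)
        for it in range(self.max_iter):
            um = u**self.m
            centers = (um.T @ X) / um.sum(axis=0)[:, None]
            u_new = self._memberships(X, centers)
            delta = float(np.abs(u_new - u).max())
            u = u_new
            if delta < self.tol:
                break
        self.n_iter_ = it + 1
        self.centers_ = centers
        self.membership_ = u
        # majority membership mapping cluster -> label
        totals = np.vstack([u[y == c].sum(axis=0) for c in classes])  # (2 labels, 2 clusters)
        cluster_labels = classes[np.argmax(totals, axis=0)]
        if cluster_labels[0] == cluster_labels[1]:
            warnings.warn(
                "both clusters map to one label; forcing distinct labels by margin",
                stacklevel=2,
            )
            margins = totals.max(axis=0) - totals.min(axis=0)
            keep = int(np.argmax(margins))  # cluster with the stronger majority
            other = classes[classes != cluster_labels[keep]][0]
            cluster_labels = cluster_labels.copy()
            cluster_labels[1 - keep] = other
        self.cluster_labels_ = cluster_labels
        return self

    def predict(self, X):
        check_is_fitted(self, "centers_")
        X = check_array(X, dtype=float)
        u = self._memberships(X, self.centers_)
        return self.cluster_labels_[np.argmax(u, axis=1)]


def export_classifier(clf, path: str | Path) -> None:
    """Serialize a fitted classifier's state to JSON for audit."""
    path = Path(path)
    if isinstance(clf, SVC):
        state = {
            "kind": "svm_rbf",
            "C": clf.C,
            "gamma": clf._gamma if hasattr(clf, "_gamma") else clf.gamma,
            "support_vectors": clf.support_vectors_.tolist(),
            "dual_coef": clf.dual_coef_.tolist(),
            "intercept": clf.intercept_.tolist(),
            "classes": clf.classes_.tolist(),
        }
    elif isinstance(clf, FisherLDA):
        state = {
            "kind": "lda",
            "coef": clf.coef_.tolist(),
            "intercept": clf.intercept_,
            "class_means": clf.means_.tolist(),
            "classes": clf.classes_.tolist(),
        }
    elif isinstance(clf, FuzzyCMeans):
        state = {
            "kind": "cmeans",
            "m": clf.m,
            "centers": clf.centers_.tolist(),
            "cluster_labels": clf.cluster_labels_.tolist(),
            "classes": clf.classes_.tolist(),
        }
    else:
        raise TypeError(f"cannot export classifier of type {type(clf).__name__}")
    path.write_text(json.dumps(state, indent=1), encoding="utf-8")
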