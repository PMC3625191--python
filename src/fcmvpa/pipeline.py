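"""The end-to-end connectivity classifier as a scikit-learn estimator.

``ConnectomeClassifier`` chains Kendall-tau feature selection, an
optional nonlinear (LLE) or linear (PCA) dimensionality reduction, and a
two-class back end (RBF-SVM, Fisher LDA, or fuzzy C-means).  It operates
on the Fisher-z connectivity feature matrix (subjects x R(R-1)/2) built
by :mod:`fcmvpa.connectivity`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .classifiers import FisherLDA, FuzzyCMeans, make_svm
from .embedding import OutOfSampleLLE
from .feature_selection import KendallTauSelector

__all__ = ["ConnectomeClassifier"]


class ConnectomeClassifier(ClassifierMixin, BaseEstimator):
    """Kendall-tau selection + manifold embedding + two-class back end.

    Parameters
    ----------
    n_features : int, default 22
        Connectivity features retained by |tau| rank.
    reducer : {"lle", "pca", "none"}, default "lle"
        Dimensionality reduction applied to the selected features.
    classifier : {"svm", "lda", "cmeans"}, default "svm"
    n_neighbors, n_components : int
        LLE neighborhood size k and embedding dimension d (PCA uses
        ``n_components`` too).
    C, gamma : SVM cost and RBF width ("scale" = 1 / (d * var)).
    cmeans_m : fuzziness exponent of the C-means back end.
    lle_reg, lda_ridge : numerical conditioning constants.

    Attributes
    ----------
    selector_ : fitted :class:`KendallTauSelector`
    reducer_ : fitted :class:`OutOfSampleLLE`, :class:`PCA` or None
    clf_ : fitted back-end classifier
    tau_ : per-feature Kendall tau on the training data
    selected_positions_ : retained feature positions (descending power)
    """

    def __init__(
        self,
        n_features: int = 22,
        reducer: str = "lle",
        classifier: str = "svm",
        n_neighbors: int = 8,
        n_components: int = 10,
        C: float = 2.0,
        gamma: float | str = "scale",
        cmeans_m: float = 2.0,
        lle_reg: float = 1e-3,
        lda_ridge: float = 1e-6,
    ):
        self.n_features = n_features
        self.reducer = reducer
        self.classifier = classifier
        self.n_neighbors = n_neighbors
        self.n_components = n_components
        self.C = C
        self.gamma = gamma
        self.cmeans_m = cmeans_m
        self.lle_reg = lle_reg
        self.lda_ridge = lda_ridge

    def _make_backend(self):
        if self.classifier == "svm":
            return make_svm(self.C, self.gamma)
        if self.classifier == "lda":
            return FisherLDA(ridge=self.lda_ridge)
        if self.classifier == "cmeans":
            return FuzzyCMeans(m=self.cmeans_m)
        raise ValueError(f"unknown classifier {self.classifier!r}")

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("ConnectomeClassifier requires exactly two classes")
        self.selector_ = KendallTauSelector(n_features=self.n_features).fit(X, y)
        self.tau_ = self.selector_.tau_
        self.selected_positions_ = self.selector_.selected_positions_
        Xs = self.selector_.transform(X)
        if self.reducer == "lle":
            self.reducer_ = OutOfSampleLLE(
                n_neighbors=self.n_neighbors,
                n_components=self.n_components,
                reg=self.lle_reg,
            ).fit(Xs)
            Z = self.reducer_.embedding_
        elif self.reducer == "pca":
            self.reducer_ = PCA(n_components=self.n_components, svd_solver="full").fit(Xs)
            Z = self.reducer_.transform(Xs)
        elif self.reducer in (None, "none"):
            self.reducer_ = None
            Z = Xs
        else:
            raise ValueError(f"unknown reducer {self.reducer!r}")
        self.clf_ = self._make_backend().fit(Z, y)
        return self

    def _embed(self, X):
        Xs = self.selector_.transform(X)
        if self.reducer_ is None:
            return Xs
        return self.reducer_.transform(Xs)

    def predict(self, X):
        check_is_fitted(self, "clf_")
        X = check_array(X, dtype=float)
        return self.clf_.predict(self._embed(X))

    def decision_function(self, X):
        check_is_fitted(self, "clf_")
        X = check_array(X, dtype=float)
        return self.clf_.decision_function(self._embed(X))
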