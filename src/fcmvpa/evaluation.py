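"""Leave-one-out cross-validation, permutation significance testing,
parameter sweeps, the 9-way classifier comparison, and mass-univariate
t-tests with FDR correction.

Every fold of the LOOCV re-runs feature selection (and the embedding) on
the n-1 training subjects only, so the held-out subject never influences
which features are used to classify it.  The permutation test re-runs
that *entire* procedure, including per-fold selection, for every
permuted label vector; anything less inflates significance.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .classifiers import FisherLDA, FuzzyCMeans, svm_fit_predict_fast
from .embedding import lle_fit_arrays, lle_transform_arrays
from .feature_selection import rank_features, tau_b_from_ranks
from .io import rng_from
from .pipeline import ConnectomeClassifier

__all__ = [
    "Metrics",
    "FoldRecord",
    "CVResult",
    "PermutationResult",
    "compute_metrics",
    "loocv",
    "loocv_nested",
    "permutation_test",
    "sweep",
    "compare_classifiers",
    "mass_univariate",
]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metrics:
    """Generalization rate plus per-class rates.

    ``rate_pos``/``rate_neg`` are the correctly-predicted proportions of
    the higher- and lower-labeled class (with the +1 control / -1 patient
    coding: controls and patients).  ``ss``/``sc`` are those rates under
    the chosen naming convention: ``"patient"`` reports sensitivity over
    the patient (-1) class, as the definition of sensitivity reads;
    ``"printed"`` reports it over the +1 class, which is the only
    arithmetic consistent with some published rate pairs.
    """

    gr: float
    rate_pos: float
    rate_neg: float
    ss: float
    sc: float
    n_pos: int
    n_neg: int
    convention: str = "patient"


def compute_metrics(y_true, y_pred, ss_convention: str = "patient") -> Metrics:
    """GR / SS / SC from true and predicted labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("no folds to score")
    classes = np.unique(y_true)
    if classes.size == 1:
        classes = np.array([classes[0], classes[0]])
    correct = y_true == y_pred
    gr = float(correct.mean())
    pos, neg = y_true == classes[-1], y_true == classes[0]
    rate_pos = float(correct[pos].mean()) if pos.any() else float("nan")
    rate_neg = float(correct[neg].mean()) if neg.any() else float("nan")
    if ss_convention == "patient":
        ss, sc = rate_neg, rate_pos
    elif ss_convention == "printed":
        ss, sc = rate_pos, rate_neg
    else:
        raise ValueError("ss_convention must be 'patient' or 'printed'")
    return Metrics(
        gr=gr,
        rate_pos=rate_pos,
        rate_neg=rate_neg,
        ss=ss,
        sc=sc,
        n_pos=int(pos.sum()),
        n_neg=int(neg.sum()),
        convention=ss_convention,
    )


# ---------------------------------------------------------------------------
# LOOCV core
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldRecord:
    held_out: str
    true_label: int
    predicted_label: int
    selected_positions: np.ndarray  # descending discriminative power
    taus: np.ndarray  # training-only tau of the selected features


@dataclass
class CVResult:
    folds: list[FoldRecord]
    metrics: Metrics
    params: dict
    subject_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray

    @property
    def gr(self) -> float:
        return self.metrics.gr

    @property
    def ss(self) -> float:
        return self.metrics.ss

    @property
    def sc(self) -> float:
        return self.metrics.sc

    def folds_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "held_out": [f.held_out for f in self.folds],
                "true_label": [f.true_label for f in self.folds],
                "predicted_label": [f.predicted_label for f in self.folds],
                "selected_positions": [
                    ",".join(map(str, f.selected_positions)) for f in self.folds
                ],
                "taus": [
                    ",".join(f"{t:.6f}" for t in f.taus) for f in self.folds
                ],
            }
        )

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        """Write a run record (config, metrics, per-fold log, versions)."""
        import numpy
        import scipy
        import sklearn

        import fcmvpa

        record = {
            "package_version": getattr(fcmvpa, "__version__", "unknown"),
            "dependency_versions": {
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "scikit-learn": sklearn.__version__,
            },
            "params": {k: str(v) for k, v in self.params.items()},
            "metrics": {
                "gr": self.metrics.gr,
                "rate_pos": self.metrics.rate_pos,
                "rate_neg": self.metrics.rate_neg,
                "ss": self.metrics.ss,
                "sc": self.metrics.sc,
                "convention": self.metrics.convention,
            },
            "folds": [
                {
                    "held_out": f.held_out,
                    "true": int(f.true_label),
                    "predicted": int(f.predicted_label),
                    "selected": [int(p) for p in f.selected_positions],
                    "taus": [float(t) for t in f.taus],
                }
                for f in self.folds
            ],
        }
        if extra:
            record.update(extra)
        Path(path).write_text(json.dumps(record, indent=1), encoding="utf-8")


@dataclass(frozen=True)
class PermutationResult:
    gr0: float
    null_grs: np.ndarray
    p_value: float
    n_permutations: int
    seed: int


class _FoldCache:
    """Per-fold training-row ranks and tie counts, reused across the
    permutations and parameter sweeps that only relabel or reparametrize."""

    def __init__(self, X: np.ndarray):
        self.X = np.asarray(X, dtype=float)
        n = self.X.shape[0]
        self.n = n
        self.train_idx: list[np.ndarray] = []
        self.ranks: list[np.ndarray] = []
        self.ties: list[np.ndarray] = []
        for i in range(n):
            tr = np.delete(np.arange(n), i)
            ranks, ties = rank_features(self.X[tr])
            self.train_idx.append(tr)
            self.ranks.append(ranks)
            self.ties.append(ties)


def _check_two_class(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    if (y == classes[0]).sum() < 2 or (y == classes[1]).sum() < 2:
        raise ValueError("each class needs at least 2 subjects for LOOCV")
    return classes


def _fold_predict(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    x_te: np.ndarray,
    tau: np.ndarray,
    p: dict,
):
    """Select -> embed -> classify one fold; returns (prediction,
    selected positions by descending power, their taus)."""
    power = np.abs(tau)
    nf = p["n_features"]
    if not (1 <= nf <= power.size):
        raise ValueError(f"n_features must be in [1, {power.size}], got {nf}")
    order = np.lexsort((np.arange(power.size), -power))[:nf]
    sel = np.sort(order)  # column-order as the mask-based selector produces
    X_sel = X_tr[:, sel]
    x_sel = x_te[sel][None, :]

    reducer = p["reducer"]
    if reducer == "lle":
        model = lle_fit_arrays(
            X_sel, p["n_neighbors"], p["n_components"], p["lle_reg"]
        )
        Z_tr = model["embedding"]
        z_te = lle_transform_arrays(model, x_sel)
    elif reducer == "pca":
        pca = PCA(n_components=p["n_components"], svd_solver="full").fit(X_sel)
        Z_tr = pca.transform(X_sel)
        z_te = pca.transform(x_sel)
    elif reducer in (None, "none"):
        Z_tr, z_te = X_sel, x_sel
    else:
        raise ValueError(f"unknown reducer {reducer!r}")

    kind = p["classifier"]
    if kind == "svm":
        pred = svm_fit_predict_fast(Z_tr, y_tr, z_te, p["C"], p["gamma"])[0]
        return pred, order, tau[order]
    elif kind == "lda":
        clf = FisherLDA(ridge=p["lda_ridge"])
    elif kind == "cmeans":
        clf = FuzzyCMeans(m=p["cmeans_m"])
    else:
        raise ValueError(f"unknown classifier {kind!r}")
    pred = clf.fit(Z_tr, y_tr).predict(z_te)[0]
    return pred, order, tau[order]


def _loocv_cached(
    cache: _FoldCache,
    y: np.ndarray,
    params: dict,
    record: bool = True,
):
    classes = np.unique(y)
    pos_label = classes[1]
    preds = np.empty(cache.n, dtype=y.dtype)
    records = []
    for i in range(cache.n):
        tr = cache.train_idx[i]
        y_tr = y[tr]
        if np.unique(y_tr).size < 2:
            raise ValueError(f"fold {i} has a single-class training set")
        tau = tau_b_from_ranks(cache.ranks[i], cache.ties[i], y_tr == pos_label)
        pred, sel, taus = _fold_predict(cache.X[tr], y_tr, cache.X[i], tau, params)
        preds[i] = pred
        if record:
            records.append((i, sel, taus))
    return preds, records


def _full_params(estimator: ConnectomeClassifier) -> dict:
    return estimator.get_params()


def loocv(
    X,
    y,
    estimator: ConnectomeClassifier | None = None,
    subject_ids: list[str] | None = None,
    ss_convention: str = "patient",
    _cache: _FoldCache | None = None,
    **param_overrides,
) -> CVResult:
    """Leave-one-out cross-validation of the connectivity classifier.

    Feature selection and the embedding are re-fit inside every fold on
    training subjects only.  ``param_overrides`` are
    :class:`ConnectomeClassifier` parameters (n_features, reducer,
    classifier, n_neighbors, n_components, C, gamma, ...).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if n < 4:
        raise ValueError("LOOCV needs at least 4 subjects")
    _check_two_class(y)
    if estimator is None:
        estimator = ConnectomeClassifier(**param_overrides)
    elif param_overrides:
        estimator = clone(estimator).set_params(**param_overrides)
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(n)]
    params = _full_params(estimator)
    cache = _cache if _cache is not None else _FoldCache(X)
    preds, records = _loocv_cached(cache, y, params, record=True)
    folds = [
        FoldRecord(
            held_out=subject_ids[i],
            true_label=int(y[i]),
            predicted_label=int(preds[i]),
            selected_positions=sel,
            taus=taus,
        )
        for i, sel, taus in records
    ]
    metrics = compute_metrics(y, preds, ss_convention)
    return CVResult(
        folds=folds,
        metrics=metrics,
        params=params,
        subject_ids=list(subject_ids),
        y_true=y,
        y_pred=preds,
    )


def permutation_test(
    X,
    y,
    n_permutations: int = 10000,
    seed: int = 0,
    estimator: ConnectomeClassifier | None = None,
    **param_overrides,
) -> PermutationResult:
    """Empirical null for the generalization rate.

    The labels are shuffled ``n_permutations`` times; for each shuffle the
    full LOOCV -- including per-fold feature selection -- is re-run with
    the hyperparameters fixed at their real-label values.  The p-value is
    the permutation-inclusive (add-one) estimator

        p = (1 + #{null GR >= GR0}) / (1 + n_permutations),

    whose floor at 10,000 permutations is 1/10001 < 1e-4.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    _check_two_class(y)
    if estimator is None:
        estimator = ConnectomeClassifier(**param_overrides)
    elif param_overrides:
        estimator = clone(estimator).set_params(**param_overrides)
    params = _full_params(estimator)
    cache = _FoldCache(X)
    preds0, _ = _loocv_cached(cache, y, params, record=False)
    gr0 = float((preds0 == y).mean())
    rng = rng_from(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        y_perm = rng.permutation(y)
        preds, _ = _loocv_cached(cache, y_perm, params, record=False)
        null[b] = (preds == y_perm).mean()
    p = (1.0 + float((null >= gr0).sum())) / (1.0 + n_permutations)
    return PermutationResult(
        gr0=gr0,
        null_grs=null,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Parameter sweep and the classifier comparison grid
# ---------------------------------------------------------------------------

def sweep(
    X,
    y,
    grid: dict[str, list],
    ss_convention: str = "patient",
    **base_params,
) -> tuple[pd.DataFrame, dict]:
    """One LOOCV per grid point; returns the result table and the best
    parameter combination (max GR, ties resolved toward fewer features,
    then first in grid order)."""
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("sweep grid must be non-empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cache = _FoldCache(X)
    keys = list(grid)
    combos = list(itertools.product(*(grid[k] for k in keys)))
    rows = []
    for combo in combos:
        params = dict(base_params)
        params.update(dict(zip(keys, combo)))
        cv = loocv(X, y, ss_convention=ss_convention, _cache=cache, **params)
        row = dict(zip(keys, combo))
        row.update(gr=cv.gr, ss=cv.ss, sc=cv.sc)
        rows.append(row)
    table = pd.DataFrame(rows)
    nf_pos = keys.index("n_features") if "n_features" in keys else None

    def rank_key(i: int):
        nf = combos[i][nf_pos] if nf_pos is not None else 0
        return (-rows[i]["gr"], nf, i)

    best_i = min(range(len(combos)), key=rank_key)
    best = dict(zip(keys, combos[best_i]))
    return table, best


#: the nine dimensionality-reduction x classifier combinations
COMPARISON_GRID = [
    ("lle", "svm"),
    ("pca", "svm"),
    ("none", "svm"),
    ("lle", "lda"),
    ("pca", "lda"),
    ("none", "lda"),
    ("lle", "cmeans"),
    ("pca", "cmeans"),
    ("none", "cmeans"),
]


def compare_classifiers(
    X,
    y,
    n_features: int | dict = 22,
    ss_convention: str = "patient",
    **base_params,
) -> pd.DataFrame:
    """Run the 9-way reducer x back-end comparison grid.

    ``n_features`` may be a single count or a mapping like
    ``{"lle+svm": 22, "pca+svm": 24, ...}``.  Returns one row per
    combination with SS/SC/GR in percent.
    """
    rows = []
    for reducer, clf in COMPARISON_GRID:
        name = f"{reducer}+{clf}" if reducer != "none" else clf
        nf = n_features[name] if isinstance(n_features, dict) else n_features
        cv = loocv(
            X,
            y,
            reducer=reducer,
            classifier=clf,
            n_features=nf,
            ss_convention=ss_convention,
            **base_params,
        )
        rows.append(
            {
                "classifier": name,
                "n_features": nf,
                "SS": 100.0 * cv.ss,
                "SC": 100.0 * cv.sc,
                "GR": 100.0 * cv.gr,
            }
        )
    return pd.DataFrame(rows)


def loocv_nested(
    X,
    y,
    grid: dict[str, list],
    ss_convention: str = "patient",
    **base_params,
) -> CVResult:
    """Nested variant: hyperparameters are chosen inside every outer fold
    by an inner LOOCV sweep over ``grid``, removing the optimistic bias of
    tuning on the full sample.  Considerably slower; offered alongside the
    whole-sample optimization, which mirrors the reference analysis."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    _check_two_class(y)
    preds = np.empty(n, dtype=y.dtype)
    folds = []
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        _, best = sweep(X[tr], y[tr], grid, ss_convention=ss_convention, **base_params)
        params = dict(base_params)
        params.update(best)
        est = ConnectomeClassifier(**params).fit(X[tr], y[tr])
        preds[i] = est.predict(X[i][None, :])[0]
        folds.append(
            FoldRecord(
                held_out=f"s{i:03d}",
                true_label=int(y[i]),
                predicted_label=int(preds[i]),
                selected_positions=est.selected_positions_,
                taus=est.tau_[est.selected_positions_],
            )
        )
    metrics = compute_metrics(y, preds, ss_convention)
    return CVResult(
        folds=folds,
        metrics=metrics,
        params={"nested_grid": grid, **base_params},
        subject_ids=[f"s{i:03d}" for i in range(n)],
        y_true=y,
        y_pred=preds,
    )


# ---------------------------------------------------------------------------
# Mass-univariate analysis
# ---------------------------------------------------------------------------

def mass_univariate(
    X, y, q: float = 0.05, equal_var: bool = True
) -> pd.DataFrame:
    """Two-sample t-test per connectivity feature with Benjamini-Hochberg
    FDR control at level ``q``.

    ``equal_var=True`` gives the pooled-variance Student test (the
    convention of classical neuroimaging group analyses); set False for
    Welch.  The t statistic is signed as higher-label group minus
    lower-label group, matching the tau sign convention.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = _check_two_class(y)
    pos, neg = X[y == classes[1]], X[y == classes[0]]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(pos, neg, axis=0, equal_var=equal_var)
    bad = ~np.isfinite(p)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} feature(s) with zero within-class variance; p set to 1",
            stacklevel=2,
        )
        t = np.where(bad, 0.0, t)
        p = np.where(bad, 1.0, p)
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return pd.DataFrame(
        {
            "feature_position": np.arange(X.shape[1]),
            "t": t,
            "p": p,
            "p_fdr": p_adj,
            "fdr_significant": reject,
        }
    )
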