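"""Kendall-tau feature selection for two-group connectivity features.

Each Fisher-z connectivity feature is scored by the tie-corrected Kendall
tau-b rank correlation between its values and the class labels (+1
control, -1 patient).  |tau| is the feature's discriminative power; with
the +1/-1 coding, a positive tau means the feature is larger in the +1
(control) group, i.e. the connection is weakened in patients.

With binary labels tau-b has a closed form through the Mann-Whitney
statistic, which lets the whole feature matrix be scored in one pass over
column ranks: for n1 positives and n2 negatives,

    C - D  = 2 * U1 - n1 * n2,          U1 = R1 - n1 (n1 + 1) / 2,
    tau_b  = (C - D) / sqrt((n0 - t_x) (n0 - t_y)),

where R1 is the midrank sum of the positive group, n0 = n(n-1)/2, and
t_x, t_y are the tied-pair counts of the feature and of the labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

__all__ = [
    "kendall_tau",
    "kendall_tau_matrix",
    "rank_features",
    "tau_b_from_ranks",
    "TauScore",
    "SelectedFeatureSet",
    "rank_and_select",
    "KendallTauSelector",
]


def rank_features(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks of every column plus the tied-pair count t_x per column."""
    X = np.asarray(X, dtype=float)
    ranks = rankdata(X, axis=0, method="average")
    n, p = X.shape
    tie_pairs = np.zeros(p)
    Xs = np.sort(X, axis=0)
    has_tie = np.flatnonzero((Xs[1:] == Xs[:-1]).any(axis=0))
    for j in has_tie:
        _, counts = np.unique(Xs[:, j], return_counts=True)
        tie_pairs[j] = (counts * (counts - 1) // 2).sum()
    return ranks, tie_pairs


def tau_b_from_ranks(
    ranks: np.ndarray, tie_pairs: np.ndarray, pos_mask: np.ndarray
) -> np.ndarray:
    """Vectorized tau-b of every (already ranked) column against a binary
    grouping given by ``pos_mask`` (True = positive class)."""
    n = ranks.shape[0]
    n1 = int(pos_mask.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present to score features")
    r1 = ranks[pos_mask].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    num = 2.0 * u1 - n1 * n2  # concordant minus discordant pairs
    n0 = n * (n - 1) / 2.0
    t_y = n1 * (n1 - 1) / 2.0 + n2 * (n2 - 1) / 2.0
    denom_sq = (n0 - tie_pairs) * (n0 - t_y)
    tau = np.zeros_like(num)
    ok = denom_sq > 0
    tau[ok] = num[ok] / np.sqrt(denom_sq[ok])
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} constant feature(s) scored tau = 0", stacklevel=2
        )
    return np.clip(tau, -1.0, 1.0)


def kendall_tau_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Tau-b of every feature column of X against binary labels y."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be n x p with one row per label")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    ranks, ties = rank_features(X)
    return tau_b_from_ranks(ranks, ties, y == classes[1])


def kendall_tau(values, labels) -> float:
    """Tau-b between one feature and the +1/-1 labels.

    Positive when the feature tends to be larger in the higher-labeled
    (+1, control) group.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape[0] < 2:
        raise ValueError("need at least two observations")
    return float(kendall_tau_matrix(values[:, None], labels)[0])


@dataclass(frozen=True)
class TauScore:
    feature_position: int
    tau: float

    @property
    def power(self) -> float:
        return abs(self.tau)


@dataclass(frozen=True)
class SelectedFeatureSet:
    """Feature positions ordered by descending |tau|, ties broken by the
    smaller position so repeated selections are deterministic."""

    positions: tuple[int, ...]
    threshold_rule: str

    def __len__(self) -> int:
        return len(self.positions)


def _ranked_positions(power: np.ndarray) -> np.ndarray:
    # descending power; ties -> smaller feature position first
    return np.lexsort((np.arange(power.size), -power))


def rank_and_select(scores: list[TauScore], n_features: int) -> SelectedFeatureSet:
    """Top-N features by discriminative power |tau|."""
    if not (1 <= n_features <= len(scores)):
        raise ValueError(
            f"n_features must be in [1, {len(scores)}], got {n_features}"
        )
    power = np.array([s.power for s in scores])
    positions = np.array([s.feature_position for s in scores])
    order = np.lexsort((positions, -power))
    return SelectedFeatureSet(
        positions=tuple(int(positions[i]) for i in order[:n_features]),
        threshold_rule=f"top-{n_features}",
    )


class KendallTauSelector(SelectorMixin, BaseEstimator):
    """Select the connectivity features most relevant to the group labels.

    Parameters
    ----------
    n_features : int, default 22
        Number of top-|tau| features to retain (primary rule).
    power_threshold : float, optional
        If given, retain features with |tau| >= threshold instead of a
        fixed count.

    Attributes
    ----------
    tau_ : ndarray of shape (n_features_in_,)
        Tau-b of each feature against the labels.
    power_ : ndarray
        |tau_|, the discriminative power.
    selected_positions_ : ndarray
        Retained feature positions, in descending power (ties by position).
    """

    def __init__(self, n_features: int = 22, power_threshold: float | None = None):
        self.n_features = n_features
        self.power_threshold = power_threshold

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("KendallTauSelector requires exactly two classes")
        self.classes_ = classes
        self.tau_ = kendall_tau_matrix(X, y)
        self.power_ = np.abs(self.tau_)
        order = _ranked_positions(self.power_)
        if self.power_threshold is not None:
            keep = order[self.power_[order] >= self.power_threshold]
        else:
            if not (1 <= self.n_features <= X.shape[1]):
                raise ValueError(
                    f"n_features must be in [1, {X.shape[1]}], got {self.n_features}"
                )
            keep = order[: self.n_features]
        self.selected_positions_ = keep
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[keep] = True
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def scores_table(self, idx=None, atlas=None):
        """Per-feature score table (feature_position, region_pair, tau,
        power, selected); pair names are filled in when a feature index
        (and optionally an atlas) is supplied."""
        import pandas as pd

        check_is_fitted(self, "support_")
        table = pd.DataFrame(
            {
                "feature_position": np.arange(self.tau_.size),
                "tau": self.tau_,
                "power": self.power_,
                "selected": self.support_,
            }
        )
        if idx is not None:
            table.insert(
                1,
                "region_pair",
                [idx.pair_name(p, atlas) for p in range(self.tau_.size)],
            )
        return table
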