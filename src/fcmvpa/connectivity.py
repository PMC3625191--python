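"""Regional BOLD time series -> Fisher-z connectivity feature vector.

The per-subject pipeline is nuisance regression -> zero-phase Chebyshev
band-pass -> Pearson correlation -> Fisher z-transform of the upper
triangle.  Upstream volume processing (motion correction, normalization,
smoothing) is out of scope: the contract starts at a T x R matrix of
regional mean time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .io import FeatureIndex, RunConfig, feature_index, logger

__all__ = [
    "RegionTimeSeries",
    "load_timeseries",
    "load_nuisance",
    "regress_nuisance",
    "bandpass",
    "correlation_matrix",
    "fisher_vectorize",
    "subject_features",
    "extract_from_nifti",
    "write_matrix",
    "write_feature_vector",
]

#: correlations are clipped to +-(1 - FISHER_EPS) before atanh so that
#: collinear columns yield large-but-finite features
FISHER_EPS = 1e-7


@dataclass
class RegionTimeSeries:
    """T x R matrix of regional mean BOLD signals sampled every ``tr`` seconds."""

    values: np.ndarray
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x R) array")
        if self.values.shape[0] < 3:
            raise ValueError("need at least 3 time points")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


def load_timeseries(path: str | Path, tr: float = 2.0) -> RegionTimeSeries:
    """Read a headerless T x R TSV of regional time series."""
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    return RegionTimeSeries(values=values, tr=tr)


def load_nuisance(path: str | Path) -> np.ndarray:
    """Read a headerless T x Q TSV of nuisance regressors."""
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def regress_nuisance(
    ts: RegionTimeSeries, nuisance: np.ndarray | None = None
) -> RegionTimeSeries:
    """Residualize every region on [intercept | nuisance columns] by OLS.

    The output columns are orthogonal to the intercept and to every
    retained regressor; rank-deficient regressor matrices are repaired by
    dropping linearly dependent columns (with a warning).  With no
    nuisance columns this reduces to removing each column's mean, and the
    operation is idempotent.
    """
    Y = ts.values
    T = Y.shape[0]
    if nuisance is None:
        nuisance = np.empty((T, 0))
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.ndim == 1:
        nuisance = nuisance[:, None]
    if nuisance.shape[0] != T:
        raise ValueError(
            f"nuisance rows ({nuisance.shape[0]}) do not match time points ({T})"
        )
    X = np.column_stack([np.ones(T), nuisance])
    if T <= X.shape[1]:
        raise ValueError(
            f"cannot regress {X.shape[1]} regressors from {T} time points"
        )
    # drop dependent columns (never the intercept) via rank-revealing QR
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if np.any(diag < tol):
        keep = [0]
        for j in range(1, X.shape[1]):
            cand = X[:, keep + [j]]
            if np.linalg.matrix_rank(cand, tol=None) > len(keep):
                keep.append(j)
        dropped = X.shape[1] - len(keep)
        warnings.warn(
            f"nuisance matrix is rank-deficient; dropped {dropped} dependent column(s)",
            stacklevel=2,
        )
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return RegionTimeSeries(values=resid, tr=ts.tr)


def bandpass(
    ts: RegionTimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 5,
    ripple_db: float = 0.1,
) -> RegionTimeSeries:
    """Zero-phase Chebyshev type-I band-pass of every region column.

    The filter is applied forward and backward (``sosfiltfilt``), which
    squares the magnitude response and cancels the phase, preserving the
    relative timing of regional signals that the correlations depend on.
    """
    fs = 1.0 / ts.tr
    nyquist = fs / 2.0
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz infeasible: need "
            f"0 < low < high < Nyquist = {nyquist:.4g} Hz at TR = {ts.tr} s"
        )
    sos = signal.cheby1(
        order, ripple_db, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, ts.values, axis=0)
    return RegionTimeSeries(values=filtered, tr=ts.tr)


def correlation_matrix(ts: RegionTimeSeries) -> np.ndarray:
    """R x R Pearson correlation matrix of the region columns."""
    values = ts.values
    dead = np.flatnonzero(np.ptp(values, axis=0) == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance region column(s) (1-based): {(dead + 1).tolist()}"
        )
    C = np.corrcoef(values, rowvar=False)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def fisher_vectorize(
    cm: np.ndarray, idx: FeatureIndex, eps: float = FISHER_EPS
) -> np.ndarray:
    """Fisher z-transform (atanh) of the upper-triangle correlations.

    Correlations are clipped to +-(1 - eps) first so that exactly
    collinear regions produce finite features.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.shape != (idx.n_regions, idx.n_regions):
        raise ValueError(
            f"connectivity matrix shape {cm.shape} does not match "
            f"feature index for R={idx.n_regions}"
        )
    r = cm[idx.rows, idx.cols]
    return np.arctanh(np.clip(r, -1.0 + eps, 1.0 - eps))


def subject_features(
    ts: RegionTimeSeries,
    nuisance: np.ndarray | None = None,
    idx: FeatureIndex | None = None,
    cfg: RunConfig | None = None,
) -> np.ndarray:
    """Full per-subject pipeline: regression -> band-pass -> correlation ->
    Fisher-z upper triangle."""
    cfg = cfg or RunConfig()
    if idx is None:
        idx = feature_index(ts.n_regions)
    clean = regress_nuisance(ts, nuisance)
    filtered = bandpass(
        clean, cfg.low_hz, cfg.high_hz, cfg.filter_order, cfg.filter_ripple_db
    )
    return fisher_vectorize(correlation_matrix(filtered), idx)


def extract_from_nifti(
    functional_path: str | Path, atlas_path: str | Path, tr: float | None = None
) -> RegionTimeSeries:
    """Convenience reader: average a 4-D NIfTI over the voxels of each
    positive integer label of a 3-D atlas image (labels = region index)."""
    import nibabel as nib  # optional dependency

    func_img = nib.load(str(functional_path))
    atlas_img = nib.load(str(atlas_path))
    data = np.asarray(func_img.dataobj, dtype=float)
    labels = np.asarray(atlas_img.dataobj).astype(int)
    if data.shape[:3] != labels.shape:
        raise ValueError("functional and atlas images have different grids")
    region_ids = np.arange(1, labels.max() + 1)
    series = np.column_stack(
        [data[labels == rid, :].mean(axis=0) for rid in region_ids]
    )
    if tr is None:
        tr = float(func_img.header.get_zooms()[3]) if len(func_img.header.get_zooms()) > 3 else 2.0
    logger.info("extracted %d regional time series from %s", len(region_ids), functional_path)
    return RegionTimeSeries(values=series, tr=tr)


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, matrix, delimiter="\t", fmt="%.10g")


def write_feature_vector(
    vec: np.ndarray, idx: FeatureIndex, path: str | Path, atlas=None
) -> None:
    df = pd.DataFrame(
        {
            "feature_position": np.arange(len(idx)),
            "region_pair": [idx.pair_name(p, atlas) for p in range(len(idx))],
            "fisher_z": vec,
        }
    )
    df.to_csv(path, sep="\t", index=False)
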