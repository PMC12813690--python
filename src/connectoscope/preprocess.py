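"""Post-alignment BOLD time-series cleaning and motion quality control.

The cleaning chain applied to each run is: drop initial volumes, voxelwise
linear detrend, ideal FFT-domain bandpass (optionally skipped for the
amplitude-metric branch), and nuisance regression against the six rigid-body
motion parameters, white-matter and CSF mean series, and the whole-brain
mean signal. Motion QC excludes a run when any translation exceeds the
translation limit or any rotation exceeds the rotation limit (strictly).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


class QCError(ValueError):
    """Raised when motion quality control cannot be evaluated."""


class CollinearityError(ValueError):
    """Raised when a nuisance design matrix is rank deficient."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"rank-deficient nuisance design; offending columns: {columns}")


@dataclass
class BoldRun:
    """One subject's 4D BOLD grid plus acquisition metadata.

    ``data`` is indexed [x, y, z, t]; ``motion`` holds one row per time
    point (three translations in mm, three rotations in degrees);
    ``confounds`` optionally carries white-matter and CSF mean series.
    """

    data: np.ndarray
    tr_seconds: float
    mask: np.ndarray
    motion: pd.DataFrame | None = None
    subject_id: str = "sub-00"
    confounds: pd.DataFrame | None = None

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("BoldRun.data must be 4D [x, y, z, t]")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match data grid")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class NuisanceSet:
    """Nuisance regressors (T x K) with column labels."""

    regressors: np.ndarray
    labels: list[str]

    def __post_init__(self):
        if self.regressors.ndim != 2 or self.regressors.shape[1] != len(self.labels):
            raise ValueError("regressors must be T x K with K labels")
        if self.regressors.shape[1] < 1:
            raise ValueError("need at least one regressor")
        norms = np.abs(self.regressors).max(axis=0)
        if np.any(norms == 0):
            dead = [l for l, nz in zip(self.labels, norms) if nz == 0]
            raise ValueError(f"all-zero nuisance columns: {dead}")


@dataclass
class QCResult:
    exclude: bool
    max_translation_mm: np.ndarray
    max_rotation_deg: np.ndarray
    subject_id: str = ""

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "exclude": bool(self.exclude),
            "max_translation_mm": [float(v) for v in self.max_translation_mm],
            "max_rotation_deg": [float(v) for v in self.max_rotation_deg],
        }


def motion_qc(run: BoldRun, trans_limit_mm: float = 3.0,
              rot_limit_deg: float = 3.0) -> QCResult:
    """Retain/exclude decision from per-axis motion maxima.

    A run is excluded iff any translation magnitude strictly exceeds
    ``trans_limit_mm`` or any rotation magnitude strictly exceeds
    ``rot_limit_deg``. Runs at exactly the limit are retained.
    """
    if run.motion is None:
        raise QCError(f"{run.subject_id}: missing motion table")
    m = run.motion[MOTION_COLUMNS].to_numpy(float)
    max_t = np.abs(m[:, :3]).max(axis=0)
    max_r = np.abs(m[:, 3:]).max(axis=0)
    exclude = bool((max_t > trans_limit_mm).any() or (max_r > rot_limit_deg).any())
    return QCResult(exclude, max_t, max_r, subject_id=run.subject_id)


def drop_initial_volumes(run: BoldRun, k: int) -> BoldRun:
    """Remove the first ``k`` volumes (and matching motion rows)."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    if run.n_volumes <= k:
        raise ValueError(f"cannot drop {k} of {run.n_volumes} volumes")
    if k == 0:
        return run
    motion = None if run.motion is None else run.motion.iloc[k:].reset_index(drop=True)
    confounds = None if run.confounds is None else run.confounds.iloc[k:].reset_index(drop=True)
    return dataclasses.replace(run, data=run.data[..., k:], motion=motion,
                               confounds=confounds)


def linear_detrend(series: np.ndarray) -> np.ndarray:
    """Least-squares removal of intercept + linear trend along the last axis."""
    series = np.asarray(series, float)
    n = series.shape[-1]
    if n < 3:
        raise ValueError("need at least 3 time points to fit a line")
    t = np.arange(n, dtype=float)
    t = t - t.mean()
    denom = (t * t).sum()
    mean = series.mean(axis=-1, keepdims=True)
    slope = (series * t).sum(axis=-1, keepdims=True) / denom
    return series - mean - slope * t


def bandpass(series: np.ndarray, tr_seconds: float, low_hz: float,
             high_hz: float) -> np.ndarray:
    """Ideal spectral-mask bandpass along the last axis.

    Frequency bins with low <= f <= high are retained; all others
    (including DC when low > 0) are zeroed. Idempotent by construction.
    """
    series = np.asarray(series, float)
    n = series.shape[-1]
    nyquist = 0.5 / tr_seconds
    if not (0 <= low_hz < high_hz <= nyquist + 1e-12):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) outside [0, Nyquist={nyquist:.4f}]")
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    keep = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    spec = np.fft.rfft(series, axis=-1)
    spec[..., ~keep] = 0
    return np.fft.irfft(spec, n=n, axis=-1)


def _rank_deficient_columns(X: np.ndarray, labels: list[str]) -> list[str]:
    # columns whose removal restores full rank among the remainder
    full_rank = np.linalg.matrix_rank(X)
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(others) == full_rank:
            bad.append(labels[j])
    return bad


def regress_nuisance(series: np.ndarray, nuisance: NuisanceSet) -> np.ndarray:
    """Residual of ``series`` after projecting out regressors + intercept.

    ``series`` may be a vector of length T or an array whose last axis is
    time; residuals are orthogonal to every regressor column.
    """
    series = np.asarray(series, float)
    T = series.shape[-1]
    R = nuisance.regressors
    if R.shape[0] != T:
        raise ValueError("regressor rows do not match series length")
    X = np.column_stack([np.ones(T), R])
    labels = ["intercept"] + list(nuisance.labels)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(_rank_deficient_columns(X, labels))
    Y = series.reshape(-1, T).T  # T x V
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return resid.T.reshape(series.shape)


def build_nuisance(run: BoldRun, band: tuple[float, float] | None) -> NuisanceSet:
    """Assemble motion + WM + CSF + global-mean regressors for a run.

    Regressors are detrended (and bandpass-filtered when ``band`` is given)
    to match the treatment of the data they will be regressed from.
    Columns that become numerically zero after filtering are dropped.
    """
    cols, labels = [], []
    if run.motion is not None:
        for c in MOTION_COLUMNS:
            cols.append(run.motion[c].to_numpy(float))
            labels.append(c)
    if run.confounds is not None:
        for c in run.confounds.columns:
            cols.append(run.confounds[c].to_numpy(float))
            labels.append(str(c))
    gs = run.data[run.mask].mean(axis=0)
    cols.append(np.asarray(gs, float))
    labels.append("global_signal")
    R = np.column_stack(cols)
    R = linear_detrend(R.T).T
    if band is not None:
        R = bandpass(R.T, run.tr_seconds, band[0], band[1]).T
    keep = np.abs(R).max(axis=0) > 1e-10 * max(1.0, np.abs(R).max())
    R = R[:, keep]
    labels = [l for l, k in zip(labels, keep) if k]
    return NuisanceSet(R, labels)


def clean_run(run: BoldRun, drop: int = 10,
              band: tuple[float, float] | None = (0.01, 0.08)) -> tuple[BoldRun, NuisanceSet]:
    """Full cleaning chain: trim -> detrend -> [bandpass] -> nuisance regression.

    Returns the cleaned run and the nuisance set that was regressed out.
    With ``band=None`` the bandpass step is skipped (the broadband branch
    that feeds ALFF/fALFF, whose denominator needs the full spectrum).
    """
    run = drop_initial_volumes(run, drop)
    mask = run.mask
    Y = run.data[mask].astype(float)  # V x T
    Y = linear_detrend(Y)
    if band is not None:
        Y = bandpass(Y, run.tr_seconds, band[0], band[1])
    interim = dataclasses.replace(run, data=_scatter(Y, mask, run.data.shape))
    nuis = build_nuisance(interim, band)
    Y = regress_nuisance(Y, nuis)
    return dataclasses.replace(run, data=_scatter(Y, mask, run.data.shape)), nuis


def _scatter(Y: np.ndarray, mask: np.ndarray, shape: tuple) -> np.ndarray:
    out = np.zeros(shape, dtype=float)
    out[mask] = Y
    return out
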