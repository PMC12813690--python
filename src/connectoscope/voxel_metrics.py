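"""Voxelwise ALFF, fALFF, and ReHo maps with the standard smoothing order.

Conventions:

* The one-sided periodogram amplitude at bin k is ``|X_k| / sqrt(T)``
  (square root of the periodogram power ``|X_k|^2 / T``); the DC bin is
  excluded from both the ALFF numerator and the fALFF denominator.
* ALFF/fALFF smooth the 4D data *before* computing the spectrum; ReHo
  computes the concordance map first and smooths the *map* afterwards.
* "Z-standardization" of a finished map is within-mask (x - mean) / sd,
  the convention of the usual resting-state toolchains (atanh is not
  defined for unbounded amplitude values).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import rankdata

from .preprocess import BoldRun

_NEIGHBOR_OFFSETS = {
    7: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
        for dz in (-1, 0, 1) if abs(dx) + abs(dy) + abs(dz) <= 1],
    19: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
         for dz in (-1, 0, 1) if abs(dx) + abs(dy) + abs(dz) <= 2],
    27: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
         for dz in (-1, 0, 1)],
}


@dataclass
class VoxelMap:
    values: np.ndarray
    mask: np.ndarray
    metric_name: str
    standardized: bool = False


def _sqrt_power(series: np.ndarray, tr_seconds: float):
    """One-sided sqrt-periodogram along the last axis, with frequencies."""
    series = np.asarray(series, float)
    T = series.shape[-1]
    spec = np.abs(np.fft.rfft(series, axis=-1)) / np.sqrt(T)
    freqs = np.fft.rfftfreq(T, d=tr_seconds)
    return spec, freqs


def _band_bins(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    keep = (freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12)
    keep[0] = False  # DC never counts
    return keep


def alff(series: np.ndarray, tr_seconds: float,
         band: tuple[float, float] = (0.01, 0.08)) -> float | np.ndarray:
    """Mean square-root spectral power over the in-band bins.

    Accepts a vector or an array whose last axis is time (vectorized over
    leading axes).
    """
    spec, freqs = _sqrt_power(series, tr_seconds)
    keep = _band_bins(freqs, band)
    if not keep.any():
        raise ValueError("no frequency bins inside the band at this length/TR")
    out = spec[..., keep].mean(axis=-1)
    return float(out) if out.ndim == 0 else out


def falff(series: np.ndarray, tr_seconds: float,
          band: tuple[float, float] = (0.01, 0.08)) -> float | np.ndarray:
    """In-band fraction of total (DC-excluded) square-root spectral power."""
    spec, freqs = _sqrt_power(series, tr_seconds)
    keep = _band_bins(freqs, band)
    if not keep.any():
        raise ValueError("no frequency bins inside the band at this length/TR")
    total = spec[..., 1:].sum(axis=-1)
    if np.any(total <= 0):
        raise ValueError("zero-variance series: fALFF undefined")
    out = spec[..., keep].sum(axis=-1) / total
    return float(out) if out.ndim == 0 else out


def kendall_w(series_set: np.ndarray) -> float:
    """Kendall's coefficient of concordance across m time series.

    Each of the m series of length n is rank-transformed along time
    (midranks for ties); with rank sums R_t over the m series,
    W = 12 * sum_t (R_t - mean R)^2 / (m^2 (n^3 - n)).
    """
    S = np.asarray(series_set, float)
    if S.ndim != 2:
        raise ValueError("series_set must be m x n")
    m, n = S.shape
    if m < 2 or n < 2:
        raise ValueError("need m >= 2 series of length n >= 2")
    ranks = rankdata(S, axis=1)
    R = ranks.sum(axis=0)
    ss = ((R - R.mean()) ** 2).sum()
    return float(12.0 * ss / (m ** 2 * (n ** 3 - n)))


def reho_map(run: BoldRun, neighborhood: int = 27) -> VoxelMap:
    """Voxelwise Kendall concordance over each voxel and its in-mask neighbors.

    Boundary voxels use whatever neighbors fall inside the mask. Computed
    fully vectorized from per-voxel time ranks: with m in-mask series of
    length n and rank-sum R_t, sum_t (R_t - mean)^2 = sum R_t^2 -
    n m^2 (n+1)^2 / 4.
    """
    if neighborhood not in _NEIGHBOR_OFFSETS:
        raise ValueError("neighborhood must be one of 7, 19, 27")
    mask = run.mask
    T = run.n_volumes
    ranks = np.zeros(run.data.shape, float)
    ranks[mask] = rankdata(run.data[mask], axis=-1)
    rank_sum = np.zeros_like(ranks)
    m_count = np.zeros(mask.shape, float)
    maskf = mask.astype(float)
    for off in _NEIGHBOR_OFFSETS[neighborhood]:
        rank_sum += _shift(ranks, off)
        m_count += _shift(maskf[..., None], off)[..., 0]
    m_in = m_count[mask]
    if np.any(m_in < 2):
        raise ValueError("some in-mask voxels have fewer than 2 series "
                         "(single-voxel neighborhoods); enlarge the mask")
    R = rank_sum[mask]
    ss = (R ** 2).sum(axis=-1) - T * (m_in ** 2) * (T + 1) ** 2 / 4.0
    w = 12.0 * ss / (m_in ** 2 * (T ** 3 - T))
    values = np.zeros(mask.shape, float)
    values[mask] = w
    return VoxelMap(values, mask.copy(), "ReHo")


def _shift(arr: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Shift a (padded) spatial array by an offset, zero-filling edges."""
    out = np.zeros_like(arr)
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    for ax, o in enumerate(offset):
        n = arr.shape[ax]
        if o == 0:
            continue
        if o > 0:
            dst[ax], src[ax] = slice(o, n), slice(0, n - o)
        else:
            dst[ax], src[ax] = slice(0, n + o), slice(-o, n)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def gaussian_smooth(volume: np.ndarray, fwhm_mm: float,
                    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)) -> np.ndarray:
    """Separable spatial Gaussian smoothing of a 3D or 4D grid.

    sigma per axis is fwhm / (voxel size * 2 sqrt(2 ln 2)); the kernel is
    truncated at 4 sigma and renormalized, so constant fields are fixed
    points and ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if any(v <= 0 for v in voxel_mm):
        raise ValueError("voxel sizes must be positive")
    if fwhm_mm == 0:
        return np.asarray(volume, float).copy()
    factor = 2.0 * np.sqrt(2.0 * np.log(2.0))
    sigma = [fwhm_mm / (v * factor) for v in voxel_mm]
    if volume.ndim == 4:
        sigma = sigma + [0.0]
    elif volume.ndim != 3:
        raise ValueError("volume must be 3D or 4D")
    return gaussian_filter(np.asarray(volume, float), sigma=sigma,
                           mode="reflect", truncate=4.0)


def standardize_map(vmap: VoxelMap) -> VoxelMap:
    """Within-mask standardization to mean 0, sd 1 (out-of-mask untouched)."""
    vals = vmap.values[vmap.mask]
    if vals.size < 2 or vals.std() == 0:
        raise ValueError(f"{vmap.metric_name}: zero in-mask variance, "
                         "cannot standardize")
    out = vmap.values.copy()
    out[vmap.mask] = (vals - vals.mean()) / vals.std()
    return replace(vmap, values=out, standardized=True)


def alff_falff_maps(run_broad: BoldRun, band: tuple[float, float] = (0.01, 0.08),
                    fwhm_mm: float = 6.0,
                    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
                    ) -> tuple[VoxelMap, VoxelMap]:
    """ALFF and fALFF maps from the broadband (non-bandpassed) branch.

    The 4D data are smoothed first, then the spectrum is computed per
    voxel. fALFF needs the full spectrum in its denominator, which is why
    this branch must not be bandpass filtered.
    """
    data = gaussian_smooth(run_broad.data, fwhm_mm, voxel_mm)
    mask = run_broad.mask
    series = data[mask]
    a = alff(series, run_broad.tr_seconds, band)
    f = falff(series, run_broad.tr_seconds, band)
    amap = np.zeros(mask.shape, float)
    fmap = np.zeros(mask.shape, float)
    amap[mask] = a
    fmap[mask] = f
    return (VoxelMap(amap, mask.copy(), "ALFF"),
            VoxelMap(fmap, mask.copy(), "fALFF"))


def smoothed_reho_map(run_band: BoldRun, neighborhood: int = 27,
                      fwhm_mm: float = 6.0,
                      voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)) -> VoxelMap:
    """ReHo from the bandpassed branch, smoothed after metric computation."""
    vmap = reho_map(run_band, neighborhood)
    smoothed = gaussian_smooth(vmap.values, fwhm_mm, voxel_mm)
    smoothed[~vmap.mask] = 0.0
    return replace(vmap, values=smoothed)
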