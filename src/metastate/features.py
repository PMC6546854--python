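"""Voxel-wise rs-fMRI feature maps: ReHo, degree centrality and fALFF.

Three complementary views of spontaneous BOLD fluctuations:

* **ReHo** (regional homogeneity) — Kendall's coefficient of concordance (W)
  of a voxel's time series with its 26 face/edge/corner neighbors; local
  synchronization of the low-frequency signal.
* **DC** (degree centrality) — the number of other masked voxels whose
  time series correlate with the voxel at Pearson r >= 0.25; global
  connectedness of the voxel.
* **fALFF** — the summed spectral amplitude (sqrt of the power spectrum)
  inside the 0.01–0.08 Hz band divided by the summed amplitude over the
  whole positive-frequency axis up to Nyquist; the band-limited fraction of
  total fluctuation power.

The module also provides the two preprocessing stages that wrap the maps —
an ideal frequency-domain band-pass and Gaussian spatial smoothing — and the
pipeline-order contract tying them together: ReHo is computed on band-passed
data and its *map* is smoothed afterwards; DC is computed on smoothed then
band-passed runs; fALFF is computed on smoothed, *unfiltered* runs (band-pass
would trivialize the ratio).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .datatypes import (
    BoldRun,
    FeatureTable,
    Parcellation,
    RegionVector,
    VoxelMap,
)

logger = logging.getLogger(__name__)

LOW_BAND = (0.01, 0.08)
DC_THRESHOLD = 0.25
_EDGE_TOL = 1e-12  # relative tolerance when testing band-edge membership

__all__ = [
    "bandpass", "smooth_run", "smooth_map", "kendall_w", "reho_map",
    "dc_map", "falff_map", "roi_means", "compute_feature_map",
    "build_feature_table", "LOW_BAND", "DC_THRESHOLD",
]


# ---------------------------------------------------------------------------
# preprocessing stages


def bandpass(run: BoldRun, f_lo: float = LOW_BAND[0], f_hi: float = LOW_BAND[1]) -> BoldRun:
    """Ideal (spectral-mask) temporal band-pass filter.

    Each voxel's series is demeaned, Fourier bins with center frequency
    k/(n*tr) outside the closed band [f_lo, f_hi] are zeroed, and the series
    is transformed back.  An ideal filter (rather than e.g. Butterworth)
    keeps the operation exactly consistent with the frequency-bin
    definitions used by fALFF and makes on-bin sinusoids pass untouched.
    """
    nyq = run.nyquist
    if not (0.0 <= f_lo < f_hi):
        raise ValueError("band edges must satisfy 0 <= f_lo < f_hi")
    if f_hi > nyq * (1.0 + _EDGE_TOL):
        raise ValueError(f"upper band edge {f_hi} Hz exceeds Nyquist {nyq} Hz")
    n = run.n_timepoints
    data = run.data - run.data.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(data, axis=-1)
    freqs = np.fft.rfftfreq(n, d=run.tr)
    keep = (freqs >= f_lo * (1.0 - _EDGE_TOL) - 1e-15) & (freqs <= f_hi * (1.0 + _EDGE_TOL))
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=n, axis=-1)
    return run.copy_with(out)


def _fwhm_to_sigma_vox(fwhm: float, voxel_size: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size


def smooth_run(run: BoldRun, fwhm: float, voxel_size: float = 3.0) -> BoldRun:
    """Gaussian spatial smoothing of a 4D run, applied per time point.

    ``fwhm`` and ``voxel_size`` are in mm (study: 6 mm kernel at 3 mm
    voxels); fwhm = 0 is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return run.copy_with(run.data.copy())
    sigma = _fwhm_to_sigma_vox(fwhm, voxel_size)
    out = ndimage.gaussian_filter(run.data, sigma=(sigma, sigma, sigma, 0.0))
    return run.copy_with(out)


def smooth_map(vmap: VoxelMap, fwhm: float, voxel_size: float = 3.0) -> VoxelMap:
    """Mask-aware Gaussian smoothing of a 3D feature map.

    Uses normalized (mask-weighted) convolution so values outside the mask
    never bleed into it; support stays exactly on the mask.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return VoxelMap(vmap.values.copy(), vmap.mask.copy(), vmap.feature_kind)
    sigma = _fwhm_to_sigma_vox(fwhm, voxel_size)
    filled = np.where(vmap.mask, vmap.values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sigma)
    den = ndimage.gaussian_filter(vmap.mask.astype(np.float64), sigma=sigma)
    out = np.full(vmap.values.shape, np.nan)
    inside = vmap.mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    return VoxelMap(out, vmap.mask.copy(), vmap.feature_kind)


# ---------------------------------------------------------------------------
# Kendall's W / ReHo


def kendall_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance of K time series.

    ``series`` is a K x n matrix, one row per voxel in the cluster.  Each
    voxel's series is ranked over time (average ranks on ties, with no tie
    correction term), rank sums R_i = sum_j r_ij are formed per time point,
    and

        W = (sum_i R_i^2 - n * Rbar^2) / ((1/12) * K^2 * (n^3 - n))

    which lies in [0, 1]: 1 for perfectly concordant rankings, ~0 for
    discordant ones.  W is invariant under any strictly monotone transform
    applied per voxel, since only ranks enter.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 2:
        raise ValueError("series must be a K x n matrix")
    K, n = series.shape
    if K < 2:
        raise ValueError("at least two series are required (K >= 2)")
    if n < 2:
        raise ValueError("time series must have at least 2 points (n >= 2)")
    ranks = rankdata(series, axis=1)
    n_tied = np.sum(rankdata(series, axis=1, method="min") != rankdata(series, axis=1, method="max"))
    if n_tied > 0.1 * series.size:
        logger.warning("kendall_w: %.0f%% of values are tied; the statistic uses "
                       "average ranks with no tie correction", 100 * n_tied / series.size)
    return _kendall_w_from_ranks(ranks)


def _kendall_w_from_ranks(ranks: np.ndarray) -> float:
    K, n = ranks.shape
    rank_sums = ranks.sum(axis=0)
    rbar = rank_sums.mean()
    num = float(np.sum(rank_sums ** 2) - n * rbar ** 2)
    den = (K ** 2) * (n ** 3 - n) / 12.0
    w = num / den
    if -1e-12 <= w < 0.0:
        w = 0.0
    elif 1.0 < w <= 1.0 + 1e-12:
        w = 1.0
    return w


def reho_map(run: BoldRun, mask: np.ndarray) -> VoxelMap:
    """ReHo: Kendall's W over each voxel's 3x3x3 neighborhood cluster.

    For every masked voxel, W is computed over the cluster of the voxel and
    its in-mask, in-volume immediate neighbors (K = actual cluster size,
    27 in the interior) and written at the center voxel.  Clusters truncated
    at mask or volume boundaries use their actual K, so the map's support
    equals the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != run.data.shape[:3]:
        raise ValueError("mask shape must match the spatial grid of the run")
    if not mask.any():
        raise ValueError("mask is empty")
    n = run.n_timepoints
    ranks = np.zeros(run.data.shape)
    ranks[mask] = rankdata(run.data[mask], axis=-1)

    # Accumulate neighbor rank sums and cluster sizes by shifting the padded
    # rank volume over the 27 offsets; mean rank sum is K*(n+1)/2 exactly
    # because each voxel's ranks sum to n*(n+1)/2.
    pr = np.pad(ranks, ((1, 1), (1, 1), (1, 1), (0, 0)))
    pm = np.pad(mask, 1)
    nx, ny, nz = mask.shape
    rank_sum = np.zeros(run.data.shape)
    cluster_k = np.zeros(mask.shape, dtype=np.int64)
    for dx in (0, 1, 2):
        for dy in (0, 1, 2):
            for dz in (0, 1, 2):
                rank_sum += pr[dx:dx + nx, dy:dy + ny, dz:dz + nz]
                cluster_k += pm[dx:dx + nx, dy:dy + ny, dz:dz + nz]

    K = cluster_k.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (rank_sum ** 2).sum(axis=-1) - n * (K * (n + 1) / 2.0) ** 2
        den = (K ** 2) * (n ** 3 - n) / 12.0
        w = num / den
    w = np.clip(w, 0.0, 1.0, where=np.isfinite(w), out=w)
    values = np.full(mask.shape, np.nan)
    values[mask] = w[mask]
    return VoxelMap(values, mask, "reho")


# ---------------------------------------------------------------------------
# degree centrality


def dc_map(run: BoldRun, mask: np.ndarray, r_threshold: float = DC_THRESHOLD,
           chunk_size: int = 1024) -> VoxelMap:
    """Degree centrality: connections with Pearson r >= threshold.

    Builds the voxel-by-voxel correlation graph over the mask, thresholds it
    at ``r_threshold`` and writes each voxel's degree.  The self-connection
    (r_ii = 1) is excluded, so degrees range over 0..N-1.  Voxels with zero
    temporal variance have no defined correlation; they are dropped from the
    map's mask with a logged warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != run.data.shape[:3]:
        raise ValueError("mask shape must match the spatial grid of the run")
    if not mask.any():
        raise ValueError("mask is empty")
    X = run.data[mask]
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    good = norms > 0
    if not good.all():
        logger.warning("dc_map: excluding %d zero-variance voxel(s) from the mask",
                       int((~good).sum()))
        idx = np.argwhere(mask)
        bad_idx = idx[~good]
        mask = mask.copy()
        mask[tuple(bad_idx.T)] = False
        X = X[good]
        norms = norms[good]
    Z = X / norms[:, None]
    N = Z.shape[0]
    degree = np.empty(N, dtype=np.int64)
    for start in range(0, N, chunk_size):
        stop = min(start + chunk_size, N)
        corr = Z[start:stop] @ Z.T
        degree[start:stop] = (corr >= r_threshold).sum(axis=1) - 1  # drop self
    values = np.full(mask.shape, np.nan)
    values[mask] = degree.astype(np.float64)
    return VoxelMap(values, mask, "dc")


# ---------------------------------------------------------------------------
# fALFF


def _band_masks(n: int, tr: float, low_band: tuple[float, float],
                include_dc_bin: bool) -> tuple[np.ndarray, np.ndarray]:
    freqs = np.fft.rfftfreq(n, d=tr)
    lo, hi = low_band
    in_low = (freqs >= lo * (1.0 - _EDGE_TOL) - 1e-15) & (freqs <= hi * (1.0 + _EDGE_TOL))
    in_full = freqs > 0
    if include_dc_bin:
        in_full = in_full | (freqs == 0)
        in_low = in_low | ((freqs == 0) & (lo <= 0))
    else:
        in_low &= freqs > 0
    return in_low, in_full


def falff_map(run: BoldRun, mask: np.ndarray, low_band: tuple[float, float] = LOW_BAND,
              include_dc_bin: bool = False) -> VoxelMap:
    """fALFF: fractional amplitude of low-frequency fluctuations.

    The amplitude spectrum of each demeaned voxel series is the square root
    of its power spectrum (|FFT|); fALFF is the summed amplitude over bins
    with center frequency in the closed low band divided by the summed
    amplitude over all bins in (0, Nyquist].  The zero-frequency bin is
    excluded from both sums by default (``include_dc_bin`` restores a
    dialect that keeps it in the denominator); demeaning makes it ~0 anyway
    and excluding it keeps the ratio scale-free.  The run must *not* be
    band-passed beforehand, or the ratio degenerates toward 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != run.data.shape[:3]:
        raise ValueError("mask shape must match the spatial grid of the run")
    if not mask.any():
        raise ValueError("mask is empty")
    if low_band[1] > run.nyquist * (1.0 + _EDGE_TOL):
        raise ValueError(f"low band upper edge {low_band[1]} Hz exceeds Nyquist {run.nyquist} Hz")
    X = run.data[mask]
    X = X - X.mean(axis=1, keepdims=True)
    amp = np.abs(np.fft.rfft(X, axis=1))
    in_low, in_full = _band_masks(run.n_timepoints, run.tr, low_band, include_dc_bin)
    num = amp[:, in_low].sum(axis=1)
    den = amp[:, in_full].sum(axis=1)
    vals = np.zeros(len(num))
    zero = den == 0
    if zero.any():
        logger.warning("falff_map: %d all-zero series set to fALFF = 0", int(zero.sum()))
    vals[~zero] = num[~zero] / den[~zero]
    values = np.full(mask.shape, np.nan)
    values[mask] = vals
    return VoxelMap(values, mask, "falff")


# ---------------------------------------------------------------------------
# aggregation and pipeline order


def roi_means(vmap: VoxelMap, parcellation: Parcellation) -> RegionVector:
    """Arithmetic mean of map values over each region, in region-table order."""
    if vmap.values.shape != parcellation.labels.shape:
        raise ValueError("map and parcellation grids differ")
    labels = parcellation.labels
    out = np.empty(parcellation.n_regions)
    for i, (label, name) in enumerate(parcellation.region_table):
        vox = (labels == label) & vmap.mask
        if not vox.any():
            raise ValueError(f"region {label} ({name}) has no masked voxels")
        out[i] = vmap.values[vox].mean()
    return RegionVector(out, parcellation.region_labels, vmap.feature_kind)


def compute_feature_map(run: BoldRun, parcellation: Parcellation, kind: str,
                        fwhm: float = 6.0, low_band: tuple[float, float] = LOW_BAND,
                        r_threshold: float = DC_THRESHOLD,
                        include_dc_bin: bool = False) -> VoxelMap:
    """One feature map with the correct preprocessing order for its kind.

    * reho:  band-pass -> ReHo on the unsmoothed run -> smooth the map
      (smoothing before ReHo would inflate neighborhood concordance);
    * dc:    smooth the run -> band-pass -> degree centrality;
    * falff: smooth the run -> fALFF on unfiltered data.
    """
    mask = parcellation.mask
    if kind == "reho":
        bp = bandpass(run, *low_band)
        vmap = reho_map(bp, mask)
        return smooth_map(vmap, fwhm, parcellation.voxel_size)
    if kind == "dc":
        sm = smooth_run(run, fwhm, parcellation.voxel_size)
        bp = bandpass(sm, *low_band)
        return dc_map(bp, mask, r_threshold)
    if kind == "falff":
        sm = smooth_run(run, fwhm, parcellation.voxel_size)
        return falff_map(sm, mask, low_band, include_dc_bin)
    raise ValueError(f"unknown feature kind {kind!r}")


def build_feature_table(runs: Sequence[BoldRun], parcellation: Parcellation, kind: str,
                        fwhm: float = 6.0, low_band: tuple[float, float] = LOW_BAND,
                        r_threshold: float = DC_THRESHOLD,
                        include_dc_bin: bool = False) -> FeatureTable:
    """Region vectors for every run, stacked into a samples x regions table."""
    rows, ys, subjects = [], [], []
    for run in runs:
        vmap = compute_feature_map(run, parcellation, kind, fwhm=fwhm,
                                   low_band=low_band, r_threshold=r_threshold,
                                   include_dc_bin=include_dc_bin)
        rows.append(roi_means(vmap, parcellation).values)
        ys.append(run.condition)
        subjects.append(run.subject_id)
    return FeatureTable(
        X=np.vstack(rows), y=np.array(ys, dtype=object),
        subject_id=np.array(subjects, dtype=object),
        region_labels=parcellation.region_labels, feature_kind=kind,
    )
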