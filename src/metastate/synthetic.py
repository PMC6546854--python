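"""Synthetic parcellations, BOLD cohorts and feature tables with ground truth.

No raw data accompany the study this package models, so every downstream
stage is exercised on simulated cohorts that carry the statistical structure
the three feature maps measure, with known ground truth:

* a latent band-limited (0.01–0.08 Hz) signal per region, shared by the
  region's voxels with a coupling weight, drives neighborhood concordance
  (ReHo) and in-band amplitude (fALFF);
* a brain-wide shared component drives cross-region correlation (DC);
* white voxel noise sets the floor for all three.

The paired within-subject design is modeled by letting the two runs of a
subject share a fraction ``subject_rho`` of their latent variance.  Condition
effects are injected only in the declared informative regions, by scaling the
latent amplitude (``amplitude``, targets fALFF), the voxel-to-latent coupling
(``local_coherence``, targets ReHo) or the shared component's weight
(``global_coupling``, targets DC).  The scaling factor is calibrated by
Monte-Carlo bisection on a small cluster-level proxy of the targeted
region-mean feature, so that the realized standardized mean difference
(Cohen's d) matches ``effect_size``.  The generators simulate neither head
motion nor physiological noise nor scanner drift — pipeline behavior, not
scanner realism, is the target.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .datatypes import (
    BoldRun,
    CohortSpec,
    EffectSpec,
    FeatureTable,
    GroundTruth,
    Parcellation,
    default_region_table,
)
from .features import LOW_BAND, _band_masks, _kendall_w_from_ranks

__all__ = ["make_toy_parcellation", "simulate_bold_cohort", "simulate_feature_table"]

_CALIBRATION_SEED = 202_01  # fixed internal seed; keeps generation deterministic
_CLUSTER = 27  # voxels in the calibration proxy cluster


# ---------------------------------------------------------------------------
# toy parcellation


def make_toy_parcellation(grid_shape: tuple[int, int, int], n_regions: int,
                          seed: int = 0, voxel_size: float = 3.0,
                          region_names: Sequence[str] | None = None) -> Parcellation:
    """Partition a rectangular grid into contiguous blocks of >= 27 voxels.

    The grid is split recursively along its longest feasible axis into
    near-proportional slabs, producing ``n_regions`` rectangular blocks that
    tile the grid exactly (mask = whole grid).  A (6, 6, 6) grid with eight
    regions yields the eight 3x3x3 octants.  The partition is a deterministic
    function of the inputs; ``seed`` is accepted for interface symmetry with
    the stochastic generators.

    Raises ``ValueError`` if the grid cannot host ``n_regions`` blocks of 27
    voxels each.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if len(grid_shape) != 3 or any(g < 1 for g in grid_shape):
        raise ValueError("grid_shape must be three positive integers")
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    total = math.prod(grid_shape)
    if total < 27 * n_regions:
        raise ValueError(
            f"grid of {total} voxels cannot host {n_regions} regions of >= 27 voxels")

    attempts = [0]

    def split(box: tuple[tuple[int, int], ...], m: int) -> list | None:
        """Backtracking bisection: split m regions into m1 + m2 along some
        axis, preferring balanced splits and long axes; each part must keep
        >= 27 voxels per region."""
        if m == 1:
            return [box]
        attempts[0] += 1
        if attempts[0] > 50_000:
            raise ValueError(
                f"grid {grid_shape} cannot be split into {n_regions} regions "
                "of >= 27 voxels (search exhausted)")
        lengths = [hi - lo for lo, hi in box]
        m1_candidates = sorted(range(1, m), key=lambda k: (abs(k - m / 2), k))
        for axis in sorted(range(3), key=lambda a: -lengths[a]):
            L = lengths[axis]
            area = math.prod(lengths) // L
            for m1 in m1_candidates:
                m2 = m - m1
                lo_cut = math.ceil(27 * m1 / area)
                hi_cut = L - math.ceil(27 * m2 / area)
                if lo_cut > hi_cut:
                    continue
                cut = min(max(round(L * m1 / m), lo_cut), hi_cut)
                a0, a1 = box[axis]
                left = tuple((a0, a0 + cut) if ax == axis else box[ax] for ax in range(3))
                right = tuple((a0 + cut, a1) if ax == axis else box[ax] for ax in range(3))
                got_left = split(left, m1)
                if got_left is None:
                    continue
                got_right = split(right, m2)
                if got_right is None:
                    continue
                return got_left + got_right
        return None

    blocks = split(tuple((0, g) for g in grid_shape), n_regions)
    if blocks is None:
        raise ValueError(
            f"grid {grid_shape} cannot be split into {n_regions} regions of >= 27 voxels")
    blocks.sort(key=lambda b: tuple(lo for lo, _ in b))

    labels = np.zeros(grid_shape, dtype=np.int32)
    for i, box in enumerate(blocks, start=1):
        sl = tuple(slice(lo, hi) for lo, hi in box)
        labels[sl] = i
    if region_names is None:
        if n_regions == 90:
            region_names = [name for _, name in default_region_table()]
        else:
            region_names = [f"Region {i:02d}" for i in range(1, n_regions + 1)]
    table = list(zip(range(1, n_regions + 1), region_names))
    return Parcellation(labels=labels, region_table=table, voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# band-limited latent signals


def _latent(rng: np.random.Generator, n: int, tr: float, n_sin: int) -> np.ndarray:
    """Unit-variance sum of sinusoids with frequencies in the 0.01-0.08 Hz band."""
    freqs = rng.uniform(LOW_BAND[0], LOW_BAND[1], size=n_sin)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_sin)
    t = np.arange(n) * tr
    amp = math.sqrt(2.0 / n_sin)
    return amp * np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)


def _paired_latents(rng: np.random.Generator, rho: float, n: int, tr: float,
                    n_sin: int) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-variance latents with shared-variance fraction rho."""
    shared = _latent(rng, n, tr, n_sin)
    a = _latent(rng, n, tr, n_sin)
    b = _latent(rng, n, tr, n_sin)
    sq, sr = math.sqrt(rho), math.sqrt(1.0 - rho)
    return sq * shared + sr * a, sq * shared + sr * b


# ---------------------------------------------------------------------------
# effect-size calibration (Monte-Carlo proxy + bisection)


def _proxy_cluster_feature(kind: str, delta: float, w: float, g: float, noise_sd: float,
                           rho: float, n: int, tr: float, n_sin: int,
                           rng: np.random.Generator, n_draws: int) -> float:
    """Realized Cohen's d of the proxy region-mean feature at modulation delta."""
    in_low, in_full = _band_masks(n, tr, LOW_BAND, include_dc_bin=False)
    f_h = np.empty(n_draws)
    f_s = np.empty(n_draws)
    for m in range(n_draws):
        u_h, u_s = _paired_latents(rng, rho, n, tr, n_sin)
        h_h, h_s = _paired_latents(rng, rho, n, tr, n_sin)
        noise_h = rng.normal(0.0, noise_sd, size=(_CLUSTER, n))
        noise_s = rng.normal(0.0, noise_sd, size=(_CLUSTER, n))
        if kind in ("amplitude", "local_coherence"):
            series_h = w * (1.0 + delta) * u_h + g * h_h + noise_h
            series_s = w * u_s + g * h_s + noise_s
        elif kind == "global_coupling":
            series_h = w * u_h + g * (1.0 + delta) * h_h + noise_h
            series_s = w * u_s + g * h_s + noise_s
        else:
            raise ValueError(f"unknown effect_kind {kind!r}")
        if kind == "amplitude":
            for series, out in ((series_h, f_h), (series_s, f_s)):
                amp = np.abs(np.fft.rfft(series - series.mean(axis=1, keepdims=True), axis=1))
                den = amp[:, in_full].sum(axis=1)
                out[m] = float(np.mean(amp[:, in_low].sum(axis=1) / den))
        elif kind == "local_coherence":
            f_h[m] = _kendall_w_from_ranks(rankdata(series_h, axis=1))
            f_s[m] = _kendall_w_from_ranks(rankdata(series_s, axis=1))
        else:  # global_coupling: degree vs. a reference cluster in another region
            u_ref_h, u_ref_s = _paired_latents(rng, rho, n, tr, n_sin)
            ref_h = w * u_ref_h + g * h_h + rng.normal(0.0, noise_sd, size=(_CLUSTER, n))
            ref_s = w * u_ref_s + g * h_s + rng.normal(0.0, noise_sd, size=(_CLUSTER, n))
            for series, ref, out in ((series_h, ref_h, f_h), (series_s, ref_s, f_s)):
                both = np.vstack([series, ref])
                both = both - both.mean(axis=1, keepdims=True)
                norm = np.linalg.norm(both, axis=1)
                norm[norm == 0] = 1.0
                z = both / norm[:, None]
                corr = z[:_CLUSTER] @ z.T
                out[m] = float(np.mean((corr >= 0.25).sum(axis=1) - 1))
    diff = f_h.mean() - f_s.mean()
    pooled = math.sqrt((f_h.var(ddof=1) + f_s.var(ddof=1)) / 2.0)
    if pooled == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(np.inf, diff)
    return diff / pooled


@lru_cache(maxsize=64)
def _calibrate_delta(kind: str, effect_size: float, w: float, g: float, noise_sd: float,
                     rho: float, n: int, tr: float, n_sin: int,
                     n_draws: int = 256) -> tuple[float, float]:
    """Modulation factor delta such that the proxy feature realizes Cohen's d.

    Uses common random numbers (a fixed internal seed per evaluation) so the
    Monte-Carlo d(delta) curve is smooth and monotone, then bisects.  Returns
    (delta, realized d at delta).
    """
    if effect_size == 0.0:
        return 0.0, 0.0

    def realized(delta: float) -> float:
        rng = np.random.default_rng(_CALIBRATION_SEED)
        return _proxy_cluster_feature(kind, delta, w, g, noise_sd, rho, n, tr,
                                      n_sin, rng, n_draws)

    target = float(effect_size)
    if target > 0:
        lo, hi = 0.0, 1.0
        while realized(hi) < target and hi < 64.0:
            hi *= 2.0
    else:
        lo, hi = -0.999, 0.0
        if realized(lo) > target:
            return lo, realized(lo)
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target:
            lo = mid
        else:
            hi = mid
    delta = 0.5 * (lo + hi)
    return delta, realized(delta)


# ---------------------------------------------------------------------------
# BOLD cohort generator


def simulate_bold_cohort(parcellation: Parcellation, cohort: CohortSpec,
                         effects: EffectSpec, seed: int) -> tuple[list[BoldRun], GroundTruth]:
    """Simulate one 4D run per subject and condition, with known ground truth.

    Runs are returned subject-major, first condition (hunger) before second.
    Identical (parcellation, cohort, effects, seed) yield bit-identical data.
    """
    labels_present = set(parcellation.region_labels)
    missing = set(effects.informative_regions) - labels_present
    if missing:
        raise ValueError(f"informative regions {sorted(missing)} absent from parcellation")

    n = cohort.n_timepoints
    tr = cohort.tr
    grid = parcellation.labels.shape
    region_voxels = {label: parcellation.labels == label for label in parcellation.region_labels}
    mask = parcellation.mask

    realized: dict[int, float] = {}
    deltas: dict[int, float] = {}
    for label in sorted(effects.informative_regions):
        delta, real = _calibrate_delta(
            effects.effect_kind, float(effects.effect_size),
            effects.coupling_for(label), float(effects.global_weight),
            float(effects.noise_sd), float(effects.subject_rho), n, tr,
            int(effects.n_sinusoids))
        deltas[label] = delta
        realized[label] = real

    rng = np.random.default_rng(seed)
    cond_h, cond_s = cohort.conditions
    runs: list[BoldRun] = []
    for s in range(cohort.n_subjects):
        sid = f"S{s + 1:02d}"
        latents = {label: _paired_latents(rng, effects.subject_rho, n, tr, effects.n_sinusoids)
                   for label in parcellation.region_labels}
        shared = _paired_latents(rng, effects.subject_rho, n, tr, effects.n_sinusoids)
        for ci, cond in enumerate((cond_h, cond_s)):
            data = rng.normal(0.0, effects.noise_sd, size=grid + (n,))
            h = shared[ci]
            for label in parcellation.region_labels:
                u = latents[label][ci]
                w = effects.coupling_for(label)
                g = effects.global_weight
                if label in deltas and cond == cond_h:
                    if effects.effect_kind in ("amplitude", "local_coherence"):
                        w = w * (1.0 + deltas[label])
                    else:
                        g = g * (1.0 + deltas[label])
                vox = region_voxels[label]
                data[vox] += w * u + g * h
            runs.append(BoldRun(data=data, tr=tr, subject_id=sid, condition=cond))

    truth = GroundTruth(
        informative_regions=tuple(sorted(effects.informative_regions)),
        realized_effect_sizes=realized,
        seed=int(seed),
        parameters={
            "effect_kind": effects.effect_kind,
            "effect_size": effects.effect_size,
            "subject_rho": effects.subject_rho,
            "noise_sd": effects.noise_sd,
            "global_weight": effects.global_weight,
            "n_sinusoids": effects.n_sinusoids,
            "modulation_deltas": {str(k): v for k, v in deltas.items()},
            "n_subjects": cohort.n_subjects,
            "n_timepoints": n,
            "tr": tr,
        },
    )
    return runs, truth


# ---------------------------------------------------------------------------
# direct feature-table generator


def simulate_feature_table(n_subjects: int, n_regions: int,
                           informative_regions: Iterable[int], effect_size: float,
                           subject_rho: float = 0.5, seed: int = 0,
                           noise_sd: float = 1.0,
                           feature_kind: str = "synthetic") -> tuple[FeatureTable, GroundTruth]:
    """Directly generate a 2*n_subjects x n_regions region-vector table.

    Each subject's paired rows share a subject-level random effect with
    correlation ``subject_rho``; informative regions receive a between-
    condition mean shift of ``effect_size`` pooled standard deviations
    (hunger high); all other regions are pure noise.
    """
    informative = sorted(int(r) for r in informative_regions)
    if not np.isfinite(effect_size):
        raise ValueError("effect_size must be finite")
    if not (0.0 <= subject_rho < 1.0):
        raise ValueError("subject_rho must lie in [0, 1)")
    if any(r < 1 or r > n_regions for r in informative):
        raise ValueError("informative_regions must be a subset of 1..n_regions")

    rng = np.random.default_rng(seed)
    z_subject = rng.normal(size=(n_subjects, n_regions))
    z_h = rng.normal(size=(n_subjects, n_regions))
    z_s = rng.normal(size=(n_subjects, n_regions))
    sq, sr = math.sqrt(subject_rho), math.sqrt(1.0 - subject_rho)
    x_h = noise_sd * (sq * z_subject + sr * z_h)
    x_s = noise_sd * (sq * z_subject + sr * z_s)
    cols = [r - 1 for r in informative]
    x_h[:, cols] += 0.5 * effect_size * noise_sd
    x_s[:, cols] -= 0.5 * effect_size * noise_sd

    X = np.empty((2 * n_subjects, n_regions))
    X[0::2] = x_h
    X[1::2] = x_s
    subjects = np.repeat([f"S{s + 1:02d}" for s in range(n_subjects)], 2)
    from .datatypes import CONDITIONS
    y = np.tile(np.array(CONDITIONS, dtype=object), n_subjects)

    realized = {}
    for r in informative:
        j = r - 1
        pooled = math.sqrt((x_h[:, j].var(ddof=1) + x_s[:, j].var(ddof=1)) / 2.0)
        realized[r] = float((x_h[:, j].mean() - x_s[:, j].mean()) / pooled)

    table = FeatureTable(X=X, y=y, subject_id=subjects,
                         region_labels=list(range(1, n_regions + 1)),
                         feature_kind=feature_kind)
    truth = GroundTruth(
        informative_regions=tuple(informative),
        realized_effect_sizes=realized,
        seed=int(seed),
        parameters={"n_subjects": n_subjects, "n_regions": n_regions,
                    "effect_size": effect_size, "subject_rho": subject_rho,
                    "noise_sd": noise_sd},
    )
    return table, truth
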