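"""Feature-map tests: band-pass, smoothing, ReHo/KCC, DC, fALFF, ROI means."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import metastate as ms
from conftest import brute_force_kendall

N, TR = 170, 2.0
TT = np.arange(N) * TR


def onbin_sinusoid(k: int, n: int = N, tr: float = TR) -> np.ndarray:
    return np.sin(2 * np.pi * (k / (n * tr)) * np.arange(n) * tr)


def as_run(series: np.ndarray, shape=(2, 2, 2), tr: float = TR) -> ms.BoldRun:
    data = np.tile(series, shape + (1,))
    return ms.BoldRun(data, tr, "S01", "hunger")


class TestBandpass:
    def test_in_band_sinusoid_passes_untouched(self):
        run = as_run(onbin_sinusoid(17))  # 17/340 s = 0.05 Hz
        out = ms.bandpass(run)
        expected = run.data - run.data.mean(axis=-1, keepdims=True)
        assert np.abs(out.data - expected).max() <= 1e-10

    def test_out_of_band_sinusoid_removed(self):
        run = as_run(onbin_sinusoid(68))  # 0.20 Hz
        assert np.abs(ms.bandpass(run).data).max() <= 1e-10

    def test_white_noise_variance_ratio(self):
        # Parseval: the ideal filter keeps (bins in band)/(nonzero bins)
        # of the variance in expectation.  For n=170, tr=2: 24 of 85 bins.
        rng = np.random.default_rng(0)
        data = rng.normal(size=(10, 10, 10, N))
        run = ms.BoldRun(data, TR, "S", "hunger")
        out = ms.bandpass(run)
        ratio = out.data.var(axis=-1).mean() / data.var(axis=-1).mean()
        assert ratio == pytest.approx(24 / 85, rel=0.10)

    @pytest.mark.parametrize("band", [(-0.01, 0.08), (0.08, 0.01), (0.01, 0.30)])
    def test_invalid_band_rejected(self, band):
        run = as_run(onbin_sinusoid(17))
        with pytest.raises(ValueError):
            ms.bandpass(run, *band)

    def test_tr_and_length_preserved(self):
        run = as_run(onbin_sinusoid(5))
        out = ms.bandpass(run)
        assert out.tr == run.tr and out.n_timepoints == run.n_timepoints


class TestSmoothing:
    def test_fwhm_zero_is_identity(self):
        rng = np.random.default_rng(1)
        run = ms.BoldRun(rng.normal(size=(4, 4, 4, 20)), TR, "S", "hunger")
        assert np.array_equal(ms.smooth_run(run, 0.0).data, run.data)

    def test_constant_volume_unchanged(self):
        run = ms.BoldRun(np.full((5, 5, 5, 16), 3.7), TR, "S", "hunger")
        out = ms.smooth_run(run, 6.0, voxel_size=3.0)
        assert np.allclose(out.data, 3.7)

    def test_impulse_peak_equals_central_kernel_weight(self):
        # independent kernel computation: discrete Gaussian, truncated at
        # 4 sigma as scipy does, normalized; 3D central weight = w0^3
        sigma = 6.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0  # 0.8493 voxels
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        w = np.exp(-0.5 * (x / sigma) ** 2)
        w /= w.sum()
        expected_peak = w[radius] ** 3

        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        vmap = ms.VoxelMap(vol, np.ones((15, 15, 15), bool), "falff")
        out = ms.smooth_map(vmap, 6.0, voxel_size=3.0)
        assert out.values[7, 7, 7] == pytest.approx(expected_peak, rel=1e-10)

    def test_negative_fwhm_rejected(self):
        run = as_run(onbin_sinusoid(5))
        with pytest.raises(ValueError):
            ms.smooth_run(run, -1.0)

    def test_map_smoothing_respects_mask(self):
        rng = np.random.default_rng(2)
        mask = np.zeros((6, 6, 6), bool)
        mask[1:5, 1:5, 1:5] = True
        values = np.where(mask, rng.normal(size=(6, 6, 6)), np.nan)
        vmap = ms.VoxelMap(values, mask, "reho")
        out = ms.smooth_map(vmap, 6.0, voxel_size=3.0)
        assert np.isfinite(out.values[mask]).all()
        assert np.isnan(out.values[~mask]).all()
        # constant map stays constant despite the mask boundary
        const = ms.VoxelMap(np.where(mask, 2.5, np.nan), mask, "reho")
        sm = ms.smooth_map(const, 6.0, voxel_size=3.0)
        assert np.allclose(sm.values[mask], 2.5)


class TestKendallW:
    def test_identical_monotone_series_give_one(self):
        for K, n in [(2, 5), (4, 10), (27, 170)]:
            series = np.tile(np.linspace(0, 1, n) ** 2, (K, 1))
            assert ms.kendall_w(series) == pytest.approx(1.0, abs=1e-12)

    def test_two_exactly_reversed_rankings_give_zero(self):
        base = np.arange(9.0)
        assert ms.kendall_w(np.vstack([base, -base])) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            K = rng.integers(2, 6)
            n = rng.integers(3, 11)
            series = rng.normal(size=(K, n))
            assert ms.kendall_w(series) == pytest.approx(
                brute_force_kendall(series), abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_strictly_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        series = rng.normal(size=(rng.integers(2, 6), rng.integers(4, 12)))
        w0 = ms.kendall_w(series)
        assert 0.0 <= w0 <= 1.0
        transformed = series.copy()
        transformed[0] = np.exp(series[0])          # strictly increasing
        transformed[-1] = series[-1] ** 3 + 2.0     # strictly increasing
        assert ms.kendall_w(transformed) == pytest.approx(w0, abs=1e-12)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            ms.kendall_w(np.ones((1, 10)))
        with pytest.raises(ValueError):
            ms.kendall_w(np.ones((3, 1)))


class TestRehoMap:
    def test_shared_monotone_series_gives_one_everywhere(self):
        series = np.linspace(0.0, 1.0, 40)
        run = as_run(series, shape=(4, 4, 4))
        vmap = ms.reho_map(run, np.ones((4, 4, 4), bool))
        assert np.allclose(vmap.values, 1.0)

    def test_matches_per_voxel_brute_force(self):
        # independent per-voxel loop over truncated clusters, partial mask
        rng = np.random.default_rng(5)
        data = rng.normal(size=(5, 4, 4, 24))
        mask = rng.random((5, 4, 4)) < 0.8
        vmap = ms.reho_map(ms.BoldRun(data, TR, "S", "h"), mask)
        nx, ny, nz, _ = data.shape
        for x, y, z in np.argwhere(mask):
            rows = [data[a, b, c]
                    for a in range(max(0, x - 1), min(nx, x + 2))
                    for b in range(max(0, y - 1), min(ny, y + 2))
                    for c in range(max(0, z - 1), min(nz, z + 2))
                    if mask[a, b, c]]
            if len(rows) >= 2:
                expected = brute_force_kendall(np.array(rows))
                assert vmap.values[x, y, z] == pytest.approx(expected, abs=1e-12)

    def test_white_noise_interior_mean_matches_null_oracle(self):
        # simulate the null W distribution for K=27 independently and
        # compare the interior map mean against its Monte-Carlo expectation
        rng = np.random.default_rng(9)
        n = 170
        ws = [brute_force_kendall(rng.normal(size=(27, n))) for _ in range(200)]
        expected = np.mean(ws)
        data = rng.normal(size=(8, 8, 8, n))
        vmap = ms.reho_map(ms.BoldRun(data, TR, "S", "h"), np.ones((8, 8, 8), bool))
        interior = vmap.values[1:-1, 1:-1, 1:-1]
        assert interior.mean() == pytest.approx(expected, abs=0.002)

    def test_coherent_region_beats_incoherent(self, octant_parcellation):
        cohort = ms.CohortSpec(n_subjects=2, n_timepoints=64)
        eff = ms.EffectSpec(coupling={1: 2.0, 2: 0.0})
        for seed in range(5):
            runs, _ = ms.simulate_bold_cohort(octant_parcellation, cohort, eff, seed=seed)
            bp = ms.bandpass(runs[0])
            vmap = ms.reho_map(bp, octant_parcellation.mask)
            rv = ms.roi_means(vmap, octant_parcellation)
            assert rv.values[0] > rv.values[1]

    def test_empty_mask_rejected(self):
        run = as_run(onbin_sinusoid(5))
        with pytest.raises(ValueError, match="empty"):
            ms.reho_map(run, np.zeros((2, 2, 2), bool))


class TestDcMap:
    def test_identical_series_full_degree(self):
        rng = np.random.default_rng(3)
        run = as_run(rng.normal(size=40), shape=(3, 3, 3))
        vmap = ms.dc_map(run, np.ones((3, 3, 3), bool))
        assert np.all(vmap.values == 26)

    def test_anticorrelated_groups(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=50)
        data = np.empty((3, 3, 3, 50))
        flat = data.reshape(27, 50)
        flat[:10] = base
        flat[10:] = -base
        vmap = ms.dc_map(ms.BoldRun(data, TR, "S", "h"), np.ones((3, 3, 3), bool))
        vals = vmap.values.reshape(27)
        assert (vals[:10] == 9).all()   # a - 1
        assert (vals[10:] == 16).all()  # b - 1

    def test_null_mean_degree_matches_analytic_r_distribution(self):
        # exact null of Pearson r: t = r sqrt((n-2)/(1-r^2)) ~ t_{n-2}
        rng = np.random.default_rng(6)
        N_vox, n = 400, 170
        p_exceed = stats.t.sf(0.25 * np.sqrt((n - 2) / (1 - 0.25 ** 2)), df=n - 2)
        expected = (N_vox - 1) * p_exceed
        degrees = []
        for seed in range(8):
            data = np.random.default_rng(seed).normal(size=(N_vox, 1, 1, n))
            vmap = ms.dc_map(ms.BoldRun(data, TR, "S", "h"), np.ones((N_vox, 1, 1), bool))
            degrees.append(vmap.values[np.isfinite(vmap.values)].mean())
        # variance of the mean degree: pair indicators, roughly binomial
        mc_sd = np.sqrt(2 * p_exceed / N_vox / len(degrees))
        assert np.mean(degrees) == pytest.approx(expected, abs=max(3 * mc_sd * (N_vox - 1), 0.05))

    def test_zero_variance_voxel_excluded_with_warning(self, caplog):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(2, 2, 2, 30))
        data[0, 0, 0] = 5.0  # constant series
        import logging
        with caplog.at_level(logging.WARNING, logger="metastate.features"):
            vmap = ms.dc_map(ms.BoldRun(data, TR, "S", "h"), np.ones((2, 2, 2), bool))
        assert "zero-variance" in caplog.text
        assert not vmap.mask[0, 0, 0]
        assert vmap.mask.sum() == 7

    def test_invariance_under_positive_linear_rescale_and_even_degree_sum(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(3, 3, 2, 60))
        mask = np.ones((3, 3, 2), bool)
        v1 = ms.dc_map(ms.BoldRun(data, TR, "S", "h"), mask)
        scaled = data * rng.uniform(0.5, 4.0, size=(3, 3, 2, 1)) + \
            rng.normal(size=(3, 3, 2, 1))
        v2 = ms.dc_map(ms.BoldRun(scaled, TR, "S", "h"), mask)
        assert np.array_equal(v1.values, v2.values)
        assert int(v1.values[mask].sum()) % 2 == 0


class TestFalffMap:
    def test_on_bin_low_frequency_sinusoid_gives_one(self):
        vmap = ms.falff_map(as_run(onbin_sinusoid(17)), np.ones((2, 2, 2), bool))
        assert np.abs(vmap.values - 1.0).max() <= 1e-10

    def test_on_bin_high_frequency_sinusoid_gives_zero(self):
        vmap = ms.falff_map(as_run(onbin_sinusoid(68)), np.ones((2, 2, 2), bool))
        assert np.abs(vmap.values).max() <= 1e-10

    def test_white_noise_expectation_matches_bin_count(self):
        # independent bin count: centers k/340 s, k=4..27 in [0.01, 0.08],
        # k=1..85 in (0, 0.25] -> expectation ~ 24/85
        ks = np.arange(1, N // 2 + 1)
        in_band = ((ks / (N * TR)) >= 0.01) & ((ks / (N * TR)) <= 0.08)
        assert in_band.sum() == 24 and len(ks) == 85
        rng = np.random.default_rng(10)
        data = rng.normal(size=(25, 20, 20, N))
        vmap = ms.falff_map(ms.BoldRun(data, TR, "S", "h"), np.ones((25, 20, 20), bool))
        assert vmap.values.mean() == pytest.approx(24 / 85, abs=0.02)

    def test_scale_invariance(self):
        rng = np.random.default_rng(12)
        data = rng.normal(size=(2, 2, 2, N))
        m = np.ones((2, 2, 2), bool)
        v1 = ms.falff_map(ms.BoldRun(data, TR, "S", "h"), m)
        v2 = ms.falff_map(ms.BoldRun(data * 37.5, TR, "S", "h"), m)
        assert np.allclose(v1.values, v2.values, atol=1e-12)

    def test_all_zero_series_reports_zero_with_warning(self, caplog):
        import logging
        data = np.zeros((2, 2, 2, N))
        with caplog.at_level(logging.WARNING, logger="metastate.features"):
            vmap = ms.falff_map(ms.BoldRun(data, TR, "S", "h"), np.ones((2, 2, 2), bool))
        assert "all-zero" in caplog.text
        assert (vmap.values == 0).all()

    def test_dc_bin_dialect_lowers_ratio(self):
        # keeping the k=0 bin in the denominator can only lower fALFF
        rng = np.random.default_rng(13)
        data = rng.normal(size=(2, 2, 2, N)) + 50.0
        m = np.ones((2, 2, 2), bool)
        v_excl = ms.falff_map(ms.BoldRun(data, TR, "S", "h"), m)
        v_incl = ms.falff_map(ms.BoldRun(data, TR, "S", "h"), m, include_dc_bin=True)
        assert (v_incl.values <= v_excl.values + 1e-15).all()


class TestRoiMeans:
    def test_constant_map(self, octant_parcellation):
        vmap = ms.VoxelMap(np.full((6, 6, 6), 2.5), np.ones((6, 6, 6), bool), "falff")
        rv = ms.roi_means(vmap, octant_parcellation)
        assert np.allclose(rv.values, 2.5)

    def test_label_indicator_map(self, octant_parcellation):
        vmap = ms.VoxelMap(octant_parcellation.labels.astype(float),
                           octant_parcellation.mask, "dc")
        rv = ms.roi_means(vmap, octant_parcellation)
        assert np.array_equal(rv.values, np.arange(1, 9))

    def test_matches_brute_force_aggregation(self, octant_parcellation):
        rng = np.random.default_rng(14)
        values = rng.normal(size=(6, 6, 6))
        vmap = ms.VoxelMap(values, octant_parcellation.mask, "reho")
        rv = ms.roi_means(vmap, octant_parcellation)
        for i, label in enumerate(octant_parcellation.region_labels):
            acc, cnt = 0.0, 0
            for idx in np.ndindex(6, 6, 6):
                if octant_parcellation.labels[idx] == label:
                    acc += values[idx]
                    cnt += 1
            assert rv.values[i] == pytest.approx(acc / cnt, abs=1e-12)

    def test_region_without_masked_voxels_named_in_error(self, octant_parcellation):
        values = np.zeros((6, 6, 6))
        mask = octant_parcellation.mask & (octant_parcellation.labels != 5)
        vmap = ms.VoxelMap(np.where(mask, values, np.nan), mask, "reho")
        with pytest.raises(ValueError, match="region 5"):
            ms.roi_means(vmap, octant_parcellation)


class TestPipelineOrderContract:
    def test_reho_path_composition(self, octant_parcellation):
        runs, _ = ms.simulate_bold_cohort(
            octant_parcellation, ms.CohortSpec(n_subjects=2, n_timepoints=64),
            ms.EffectSpec(), seed=1)
        run = runs[0]
        via_pipeline = ms.compute_feature_map(run, octant_parcellation, "reho", fwhm=6.0)
        manual = ms.smooth_map(
            ms.reho_map(ms.bandpass(run), octant_parcellation.mask),
            6.0, octant_parcellation.voxel_size)
        assert np.allclose(via_pipeline.values[via_pipeline.mask],
                           manual.values[manual.mask], atol=1e-15)

    def test_dc_path_composition(self, octant_parcellation):
        runs, _ = ms.simulate_bold_cohort(
            octant_parcellation, ms.CohortSpec(n_subjects=2, n_timepoints=64),
            ms.EffectSpec(), seed=1)
        run = runs[1]
        via_pipeline = ms.compute_feature_map(run, octant_parcellation, "dc", fwhm=6.0)
        manual = ms.dc_map(ms.bandpass(ms.smooth_run(run, 6.0, 3.0)),
                           octant_parcellation.mask)
        assert np.array_equal(via_pipeline.values[via_pipeline.mask],
                              manual.values[manual.mask])

    def test_falff_path_skips_bandpass(self, octant_parcellation):
        runs, _ = ms.simulate_bold_cohort(
            octant_parcellation, ms.CohortSpec(n_subjects=2, n_timepoints=64),
            ms.EffectSpec(), seed=1)
        run = runs[2]
        via_pipeline = ms.compute_feature_map(run, octant_parcellation, "falff", fwhm=6.0)
        manual = ms.falff_map(ms.smooth_run(run, 6.0, 3.0), octant_parcellation.mask)
        assert np.array_equal(via_pipeline.values[via_pipeline.mask],
                              manual.values[manual.mask])
        # band-passing first would push the ratio to ~1 — assert the
        # pipeline's values stay clearly below that degenerate regime
        degenerate = ms.falff_map(ms.bandpass(ms.smooth_run(run, 6.0, 3.0)),
                                  octant_parcellation.mask)
        assert via_pipeline.values[via_pipeline.mask].mean() < \
            degenerate.values[degenerate.mask].mean()

    def test_unknown_kind_rejected(self, octant_parcellation):
        runs, _ = ms.simulate_bold_cohort(
            octant_parcellation, ms.CohortSpec(n_subjects=2, n_timepoints=32),
            ms.EffectSpec(), seed=0)
        with pytest.raises(ValueError, match="unknown feature kind"):
            ms.compute_feature_map(runs[0], octant_parcellation, "alff")
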