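"""Pre-processing chain: each step against independent oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seraman import (
    BaselineSpec,
    ChainOrderError,
    InstrumentSpec,
    ScanBlock,
    SerumModel,
    Spectrum,
    apply_calibration,
    average_measurements,
    average_scans,
    correct_baseline,
    cull_scans,
    detect_reference_peaks,
    fit_calibration,
    normalize,
    remove_cosmic_rays,
    subtract_background,
)
from seraman.simulate import lorentzian, simulate_cohort, water_template
from seraman.pipeline import DEFAULT_ANCHORS


def pixel_block(intensities):
    arr = np.asarray(intensities, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return ScanBlock(axis=np.arange(arr.shape[0], dtype=float), intensities=arr)


def bc_spectrum(values, grid=None):
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = np.arange(values.size, dtype=float)
    return Spectrum(grid, values, calibrated=True,
                    background_corrected=True, baseline_corrected=True)


class TestDetectReferencePeaks:
    def test_on_grid_apex(self):
        x = np.arange(1024, dtype=float)
        block = pixel_block(lorentzian(x, 312.0, 8.0, 1.0))
        (apex,) = detect_reference_peaks(block, 1)
        assert apex == pytest.approx(312.0, abs=0.05)

    def test_subpixel_apex_against_upsampled_oracle(self):
        x = np.arange(1024, dtype=float)
        true_center = 312.4
        block = pixel_block(lorentzian(x, true_center, 8.0, 1.0))
        (apex,) = detect_reference_peaks(block, 1)
        dense = np.linspace(300, 325, 25_000)  # 1000x upsampled oracle
        oracle = dense[np.argmax(lorentzian(dense, true_center, 8.0, 1.0))]
        assert apex == pytest.approx(oracle, abs=0.1)

    def test_flat_spectrum_rejected(self):
        with pytest.raises(ValueError, match="local maxima"):
            detect_reference_peaks(pixel_block(np.ones(100)), 1)

    def test_most_prominent_peaks_selected_in_order(self):
        x = np.arange(500, dtype=float)
        y = (lorentzian(x, 100, 8, 1.0) + lorentzian(x, 250, 8, 0.8)
             + lorentzian(x, 400, 8, 0.02))
        apexes = detect_reference_peaks(pixel_block(y), 2)
        assert apexes == pytest.approx([100.0, 250.0], abs=0.05)


class TestFitCalibration:
    def test_exact_linear_points(self):
        model = fit_calibration([100, 300, 500], [580, 840, 1100], degree=1)
        assert model.coefficients == pytest.approx([450.0, 1.3])
        assert np.max(np.abs(model.residuals)) < 1e-9

    def test_exact_quadratic_points(self):
        px = np.array([50.0, 200.0, 400.0, 700.0, 900.0])
        coeffs = np.array([400.0, 1.45, -5e-5])
        from numpy.polynomial import polynomial as npoly

        model = fit_calibration(px, npoly.polyval(px, coeffs), degree=2)
        assert np.max(np.abs(model.residuals)) < 1e-9
        assert model.coefficients == pytest.approx(coeffs)

    def test_jittered_apexes_recover_map_within_1_wavenumber(self):
        from numpy.polynomial import polynomial as npoly

        coeffs = np.array([400.0, 1.45, -5e-5])
        bands = np.array([521.7, 785.5, 1003.6, 1030.6, 1211.4, 1605.1])
        grid = np.linspace(0, 1023, 100_000)
        wmap = npoly.polyval(grid, coeffs)
        true_px = np.array([grid[np.argmin(np.abs(wmap - b))] for b in bands])
        rng = np.random.default_rng(0)
        px = np.sort(true_px + rng.normal(0, 0.3, bands.size))
        model = fit_calibration(px, bands, degree=2)
        span = np.linspace(true_px[0], true_px[-1], 2048)
        err = np.abs(model(span) - npoly.polyval(span, coeffs))
        assert err.max() < 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="reference bands"):
            fit_calibration([1, 2, 3], [10, 20], degree=1)

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_calibration([1, 2], [10, 20], degree=2)

    def test_non_monotone_fit_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            fit_calibration([10, 20, 30], [100, 300, 310], degree=2)


class TestApplyCalibration:
    def test_identity_map_preserves_intensities(self, rng):
        block = pixel_block(rng.normal(size=(50, 3)))
        model = fit_calibration([0, 25, 49], [0, 25, 49], degree=1)
        out = apply_calibration(block, model, 0, 49, 1.0)
        assert out.axis_kind == "wavenumber"
        assert np.allclose(out.intensities, block.intensities)

    def test_linear_interpolation_exact_on_affine_signal(self):
        x = np.arange(100, dtype=float)
        block = pixel_block(2.0 * x + 5.0)
        model = fit_calibration([0, 50, 99], [500, 600, 698], degree=1)
        out = apply_calibration(block, model, 510, 690, 2.0)
        expected = 2.0 * (out.axis - 500.0) / 2.0 + 5.0  # pixel = (w-500)/2
        assert np.allclose(out.intensities[:, 0], expected)

    def test_fine_to_coarse_interpolation_error_below_one_percent_of_apex(self):
        # densely sampled source (~0.3 cm^-1/px) onto the 1 cm^-1 target grid
        inst = InstrumentSpec(n_pixels=4096, true_calib_coeffs=(400.0, 0.34))
        w = inst.wavenumbers()
        block = ScanBlock(inst.pixel_grid(), lorentzian(w, 1005.0, 10.0, 1.0))
        model = fit_calibration(
            [0.0, 2000.0, 4095.0], w[[0, 2000, 4095]], degree=1
        )
        out = apply_calibration(block, model, 450, 1729, 1.0)
        analytic = lorentzian(out.axis, 1005.0, 10.0, 1.0)
        assert np.max(np.abs(out.intensities[:, 0] - analytic)) < 0.01

    def test_grid_outside_span_rejected(self):
        block = pixel_block(np.zeros(100) + 1.0)
        model = fit_calibration([0, 50, 99], [500, 600, 698], degree=1)
        with pytest.raises(ValueError, match="exceeds the"):
            apply_calibration(block, model, 400, 800, 1.0)


class TestRemoveCosmicRays:
    def test_injected_spike_flagged_and_repaired(self, rng):
        clean = np.tile(lorentzian(np.arange(200.0), 90, 10, 1.0)[:, None], (1, 14))
        data = clean + rng.normal(0, 0.01, clean.shape)
        data[50, 3] += 30.0
        out, flags = remove_cosmic_rays(pixel_block(data))
        assert flags[50, 3]
        assert abs(out.intensities[50, 3] - clean[50, 3]) < 0.05
        flags[50, 3] = False
        assert flags.mean() < 1e-3  # false positives < 0.1%

    def test_spike_free_block_nearly_untouched(self, rng):
        data = rng.normal(0, 0.01, (300, 14)) + 1.0
        out, flags = remove_cosmic_rays(pixel_block(data))
        assert flags.mean() < 1e-3
        assert np.array_equal(out.intensities[~flags], data[~flags])

    def test_spike_in_every_scan_not_flagged(self):
        data = np.ones((100, 10))
        data[40, :] += 30.0  # contaminates the median: documented limitation
        _, flags = remove_cosmic_rays(pixel_block(data))
        assert not flags[40].any()

    def test_fewer_than_three_scans_rejected(self):
        with pytest.raises(ValueError, match="single-scan"):
            remove_cosmic_rays(pixel_block(np.ones((50, 2))))


class TestCullScans:
    def test_noisy_scans_removed_exactly(self, rng):
        hits = 0
        for _ in range(100):
            data = rng.normal(0, 0.01, (200, 14))
            noisy = rng.choice(14, size=4, replace=False)
            data[:, noisy] += rng.normal(0, 0.1, (200, 4))
            kept = cull_scans(pixel_block(data), keep=10)
            kept_cols = {
                j for j in range(14)
                if any(np.array_equal(data[:, j], kept.intensities[:, i])
                       for i in range(10))
            }
            if kept_cols == set(range(14)) - set(noisy.tolist()):
                hits += 1
        assert hits >= 99

    def test_identical_scans_mean_unchanged(self):
        data = np.tile(np.arange(50.0)[:, None], (1, 14))
        kept = cull_scans(pixel_block(data), keep=10)
        assert kept.n_scans == 10
        assert np.array_equal(kept.intensities.mean(axis=1), data.mean(axis=1))

    def test_keep_all_is_identity(self, rng):
        data = rng.normal(size=(50, 5))
        kept = cull_scans(pixel_block(data), keep=5)
        assert np.array_equal(kept.intensities, data)

    def test_kept_scans_unmodified_and_in_order(self, rng):
        data = rng.normal(size=(80, 8))
        kept = cull_scans(pixel_block(data), keep=5)
        cols = [
            j for j in range(8)
            if any(np.array_equal(data[:, j], kept.intensities[:, i])
                   for i in range(5))
        ]
        assert len(cols) == 5 and cols == sorted(cols)

    def test_keep_more_than_available_rejected(self):
        with pytest.raises(ValueError, match="cannot keep"):
            cull_scans(pixel_block(np.ones((10, 3))), keep=4)


class TestAveraging:
    def test_scan_average_is_pointwise_mean(self):
        grid = np.arange(5.0)
        block = ScanBlock(grid, np.column_stack([np.zeros(5), np.full(5, 2.0)]),
                          axis_kind="wavenumber")
        spec = average_scans(block)
        assert np.array_equal(spec.intensities, np.ones(5))
        assert spec.calibrated

    def test_single_scan_average_is_itself(self, rng):
        y = rng.normal(size=30)
        block = ScanBlock(np.arange(30.0), y, axis_kind="wavenumber")
        assert np.array_equal(average_scans(block).intensities, y)

    def test_average_approaches_template_with_scans(self, rng):
        template = lorentzian(np.arange(300.0), 150, 12, 1.0)
        sd = 0.05
        data = template[:, None] + rng.normal(0, sd, (300, 10))
        spec = average_scans(ScanBlock(np.arange(300.0), data, axis_kind="wavenumber"))
        within = np.abs(spec.intensities - template) < 5 * sd / np.sqrt(10)
        assert within.mean() >= 0.99

    def test_measurement_average_requires_matching_grids(self):
        a = Spectrum(np.arange(5.0), np.ones(5), calibrated=True)
        b = Spectrum(np.arange(5.0) + 1.0, np.ones(5), calibrated=True)
        with pytest.raises(ValueError, match="grids"):
            average_measurements([a, b])

    def test_measurement_average_requires_matching_states(self):
        a = Spectrum(np.arange(5.0), np.ones(5), calibrated=True)
        b = Spectrum(np.arange(5.0), np.ones(5), calibrated=True,
                     background_corrected=True)
        with pytest.raises(ValueError, match="states"):
            average_measurements([a, b])

    def test_measurement_average_value(self):
        a = Spectrum(np.arange(5.0), np.zeros(5), calibrated=True)
        b = Spectrum(np.arange(5.0), np.full(5, 2.0), calibrated=True)
        assert np.array_equal(average_measurements([a, b]).intensities, np.ones(5))


class TestSubtractBackground:
    def test_serum_equal_to_water_gives_zero(self):
        w = np.arange(10.0)
        s = Spectrum(w, np.ones(10), calibrated=True)
        out = subtract_background(s, Spectrum(w, np.ones(10), calibrated=True))
        assert np.array_equal(out.intensities, np.zeros(10))
        assert out.background_corrected

    def test_template_plus_water_recovers_template(self):
        w = np.arange(100.0)
        template = lorentzian(w, 40, 8, 1.0)
        water = 0.3 + 0.01 * w
        serum = Spectrum(w, template + water, calibrated=True)
        out = subtract_background(serum, Spectrum(w, water, calibrated=True))
        assert np.allclose(out.intensities, template)

    def test_water_band_power_reduced_tenfold(self, serum_model):
        inst = InstrumentSpec(noise_sd=0.002, cosmic_ray_rate=0.0)
        w = inst.wavenumbers()
        water = water_template(inst)
        rng = np.random.default_rng(5)
        serum_raw = serum_model.bands(w) + water + rng.normal(0, 0.002, w.size)
        window = (w > 1600) & (w < 1680)
        # power of the broad water band relative to a flat local baseline
        def band_power(y):
            seg = y[window]
            return np.sum((seg - np.median(y[(w > 1560) & (w < 1600)])) ** 2)

        serum = Spectrum(w, serum_raw, calibrated=True)
        corrected = subtract_background(serum, Spectrum(w, water, calibrated=True))
        residual = band_power(corrected.intensities - serum_model.bands(w))
        assert band_power(serum_raw - serum_model.bands(w)) / residual >= 10

    def test_grid_mismatch_rejected(self):
        s = Spectrum(np.arange(5.0), np.ones(5), calibrated=True)
        wtr = Spectrum(np.arange(5.0) * 2 + 1, np.ones(5), calibrated=True)
        with pytest.raises(ValueError, match="grids"):
            subtract_background(s, wtr)


class TestCorrectBaseline:
    anchors = BaselineSpec(DEFAULT_ANCHORS)

    def grid(self):
        return np.arange(450.0, 1729.5, 1.0)

    def test_cubic_polynomial_removed_exactly(self):
        w = self.grid()
        cubic = 1e-9 * (w - 1000) ** 3 + 1e-5 * w**2 - 0.01 * w + 5
        spec = Spectrum(w, cubic, calibrated=True, background_corrected=True)
        corrected, baseline = correct_baseline(spec, self.anchors)
        assert np.max(np.abs(corrected.intensities)) < 1e-9
        assert np.allclose(baseline.intensities, cubic)

    def test_zero_spectrum_gives_zero_baseline(self):
        w = self.grid()
        spec = Spectrum(w, np.zeros(w.size), calibrated=True, background_corrected=True)
        corrected, baseline = correct_baseline(spec, self.anchors)
        assert np.all(corrected.intensities == 0)
        assert np.all(baseline.intensities == 0)

    def test_simulator_fluorescence_recovered_within_5pct_rms(self, serum_model):
        w = self.grid()
        true_baseline = serum_model.baseline(w, (450.0, 1729.0))
        spec = Spectrum(
            w, serum_model.bands(w) + true_baseline,
            calibrated=True, background_corrected=True,
        )
        _, estimated = correct_baseline(spec, self.anchors)
        err_rms = np.sqrt(np.mean((estimated.intensities - true_baseline) ** 2))
        true_rms = np.sqrt(np.mean(true_baseline**2))
        assert err_rms < 0.05 * true_rms

    def test_anchor_outside_span_rejected(self):
        w = np.arange(500.0, 1700.0)
        spec = Spectrum(w, np.zeros(w.size), calibrated=True, background_corrected=True)
        with pytest.raises(ValueError, match="inside the spectrum span"):
            correct_baseline(spec, self.anchors)

    def test_anchor_count_enforced(self):
        with pytest.raises(ValueError, match="12"):
            BaselineSpec((500, 600, 700))

    def test_duplicate_anchors_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            BaselineSpec((500,) * 12)


class TestNormalize:
    def test_three_four_becomes_unit_vector(self):
        out = normalize(bc_spectrum([3.0, 4.0]))
        assert out.intensities == pytest.approx([0.6, 0.8])
        assert out.normalized

    def test_idempotent(self, rng):
        spec = bc_spectrum(rng.normal(size=64))
        once = normalize(spec)
        twice = normalize(once)
        assert np.allclose(once.intensities, twice.intensities, atol=1e-15)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_unit_norm_for_random_vectors(self, seed):
        vec = np.random.default_rng(seed).normal(size=32)
        out = normalize(bc_spectrum(vec))
        assert abs(np.linalg.norm(out.intensities) - 1.0) < 1e-12

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero spectrum"):
            normalize(bc_spectrum(np.zeros(10)))


class TestChainOrder:
    def test_background_requires_calibrated(self):
        s = Spectrum(np.arange(5.0), np.ones(5))
        with pytest.raises(ChainOrderError):
            subtract_background(s, Spectrum(np.arange(5.0), np.ones(5)))

    def test_baseline_requires_background_corrected(self):
        s = Spectrum(np.arange(450.0, 1729.5), np.ones(1280), calibrated=True)
        with pytest.raises(ChainOrderError):
            correct_baseline(s, BaselineSpec(DEFAULT_ANCHORS))

    def test_normalize_requires_baseline_corrected(self):
        s = Spectrum(np.arange(5.0), np.ones(5), calibrated=True,
                     background_corrected=True)
        with pytest.raises(ChainOrderError):
            normalize(s)

    def test_double_background_subtraction_rejected(self):
        w = np.arange(5.0)
        s = Spectrum(w, np.ones(5), calibrated=True)
        wtr = Spectrum(w, np.zeros(5), calibrated=True)
        once = subtract_background(s, wtr)
        with pytest.raises(ChainOrderError):
            subtract_background(once, wtr)
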