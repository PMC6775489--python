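"""Spectral pre-processing chain: despiking, cropping, baselines,
normalization and smoothing."""
import numpy as np
import pytest

from tenswood import preprocess as pp
from tenswood.types import Spectrum


@pytest.fixture
def smooth_spectrum():
    nu = np.arange(510.0, 1801.0)
    y = (np.exp(-0.5 * ((nu - 1100) / 20) ** 2)
         + 0.6 * np.exp(-0.5 * ((nu - 1600) / 15) ** 2))
    return Spectrum(nu, y)


class TestDespike:
    def test_single_large_spike_is_flagged_and_repaired(self, smooth_spectrum):
        rng = np.random.default_rng(0)
        noise_sd = 0.002
        noisy = smooth_spectrum.intensities + rng.normal(0, noise_sd, len(smooth_spectrum))
        idx = 400
        spiked = noisy.copy()
        spiked[idx] += 40 * max(abs(noisy[idx]), 0.1)
        out, spikes = pp.despike(Spectrum(smooth_spectrum.wavenumbers, spiked))
        assert idx in spikes
        resid = out.intensities - smooth_spectrum.intensities
        assert np.max(np.abs(resid)) < 3 * noise_sd * 4  # within noise scale

    def test_spike_free_spectrum_untouched(self, smooth_spectrum):
        rng = np.random.default_rng(1)
        y = smooth_spectrum.intensities + rng.normal(0, 0.002, len(smooth_spectrum))
        out, spikes = pp.despike(Spectrum(smooth_spectrum.wavenumbers, y),
                                 z_threshold=8.0)
        assert spikes.size == 0
        np.testing.assert_array_equal(out.intensities, y)

    def test_two_adjacent_spikes_both_flagged_with_window_5(self, smooth_spectrum):
        rng = np.random.default_rng(2)
        y = smooth_spectrum.intensities + rng.normal(0, 0.002, len(smooth_spectrum))
        y[700] += 3.0
        y[701] += 2.5
        _, spikes = pp.despike(Spectrum(smooth_spectrum.wavenumbers, y),
                               window=5)
        assert {700, 701} <= set(spikes.tolist())

    def test_window_larger_than_spectrum_rejected(self):
        sp = Spectrum(np.arange(5.0), np.zeros(5))
        with pytest.raises(ValueError):
            pp.despike(sp, window=7)


class TestCrop:
    def test_default_range_keeps_510_to_1800(self):
        nu = np.arange(400.0, 2001.0)
        sp = pp.crop(Spectrum(nu, nu * 0.0))
        assert sp.wavenumbers[0] == 510.0
        assert sp.wavenumbers[-1] == 1800.0

    def test_full_range_crop_is_identity(self, smooth_spectrum):
        out = pp.crop(smooth_spectrum, 0, 1e6)
        np.testing.assert_array_equal(out.intensities,
                                      smooth_spectrum.intensities)

    def test_empty_crop_rejected(self, smooth_spectrum):
        with pytest.raises(ValueError):
            pp.crop(smooth_spectrum, 5000, 6000)


class TestAlsBaseline:
    def test_constant_spectrum_fully_captured(self):
        nu = np.arange(510.0, 1801.0)
        c = 3.7
        base, corr = pp.als_baseline(Spectrum(nu, np.full(nu.size, c)))
        assert np.max(np.abs(base - c)) < 1e-6 * c
        assert np.max(np.abs(corr.intensities)) < 1e-6 * c

    def test_straight_line_fully_captured(self):
        nu = np.arange(510.0, 1801.0)
        y = 0.002 * nu + 1.0
        _, corr = pp.als_baseline(Spectrum(nu, y))
        assert np.max(np.abs(corr.intensities)) < 1e-6 * np.max(y)

    def test_quadratic_drift_under_peaks_recovered(self):
        nu = np.arange(510.0, 1801.0)
        x = (nu - nu[0]) / (nu[-1] - nu[0])
        drift = 0.3 + 0.4 * x - 0.5 * x**2
        peaks = (np.exp(-0.5 * ((nu - 1096) / 10) ** 2)
                 + 0.8 * np.exp(-0.5 * ((nu - 1600) / 12) ** 2)
                 + 0.5 * np.exp(-0.5 * ((nu - 1376) / 9) ** 2))
        base, _ = pp.als_baseline(Spectrum(nu, peaks + drift),
                                  lam=5000.0, p=0.001)
        rmse = np.sqrt(np.mean((base - drift) ** 2))
        assert rmse < 0.02 * peaks.max()

    def test_non_finite_intensities_rejected(self):
        nu = np.arange(10.0)
        y = np.ones(10)
        y[3] = np.nan
        with pytest.raises(ValueError):
            pp.als_baseline(Spectrum(nu, y))


class TestAreaNormalize:
    def test_scale_invariance(self, smooth_spectrum):
        a = pp.area_normalize(smooth_spectrum)
        scaled = Spectrum(smooth_spectrum.wavenumbers,
                          7.0 * smooth_spectrum.intensities)
        b = pp.area_normalize(scaled)
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-12)

    def test_unit_rectangle_of_width_two(self):
        sp = Spectrum(np.array([0.0, 2.0]), np.array([1.0, 1.0]))
        out = pp.area_normalize(sp)
        np.testing.assert_allclose(out.intensities, [0.5, 0.5])

    def test_area_is_one_after_normalization(self):
        rng = np.random.default_rng(3)
        nu = np.sort(rng.uniform(500, 1800, 200))
        y = rng.uniform(0.1, 2.0, 200)
        out = pp.area_normalize(Spectrum(nu, y))
        assert np.trapezoid(out.intensities, nu) == pytest.approx(1.0,
                                                                  abs=1e-12)

    def test_non_positive_area_rejected(self):
        sp = Spectrum(np.arange(5.0), -np.ones(5))
        with pytest.raises(ValueError):
            pp.area_normalize(sp)


class TestSavgol:
    def test_order1_frame3_interior_is_three_point_mean(self):
        sp = Spectrum(np.arange(5.0), np.array([0.0, 3.0, 0.0, 3.0, 0.0]))
        out = pp.savgol(sp, order=1, frame=3)
        np.testing.assert_allclose(out.intensities[1:-1], [1.0, 2.0, 1.0])

    def test_linear_ramp_unchanged(self):
        sp = Spectrum(np.arange(20.0), 2.0 * np.arange(20.0) + 1)
        out = pp.savgol(sp)
        np.testing.assert_allclose(out.intensities, sp.intensities, atol=1e-10)

    def test_frame_too_large_rejected(self):
        sp = Spectrum(np.arange(5.0), np.zeros(5))
        with pytest.raises(ValueError):
            pp.savgol(sp, frame=5)


class TestLinearBaseline2pt:
    def test_straight_line_maps_to_zero(self):
        nu = np.arange(700.0, 1900.0)
        _ = y = 0.01 * nu - 2.0
        out = pp.linear_baseline_2pt(Spectrum(nu, y))
        np.testing.assert_allclose(out.intensities, 0.0, atol=1e-9)

    def test_equal_anchor_heights_subtract_constant(self):
        nu = np.arange(700.0, 1900.0)
        y = np.full(nu.size, 5.0)
        y[600] = 8.0  # peak far from anchors
        out = pp.linear_baseline_2pt(Spectrum(nu, y))
        assert out.intensities[0] == pytest.approx(0.0)
        assert out.intensities[600] == pytest.approx(3.0)

    def test_peak_height_preserved_on_tilted_base(self):
        nu = np.arange(700.0, 1900.0)
        tilt = 0.003 * nu + 1.0
        peak = 2.0 * np.exp(-0.5 * ((nu - 1300) / 25) ** 2)
        out = pp.linear_baseline_2pt(Spectrum(nu, tilt + peak), 812.0, 1809.0)
        np.testing.assert_allclose(out.intensities, peak, atol=1e-9)


class TestPreprocessMap:
    def test_noiseless_map_outputs_unit_area(self, noiseless_map):
        out, _ = pp.preprocess_map(noiseless_map)
        for i in range(out.n_voxels):
            area = np.trapezoid(out.intensities[i], out.wavenumbers)
            assert area == pytest.approx(1.0, abs=1e-3)

    def test_second_pass_changes_little(self, noiseless_map):
        # near-idempotence: a repeated pass may shave a few percent (ALS
        # baseline bulge under narrow bands plus renormalization) but must
        # not drift further
        once, _ = pp.preprocess_map(noiseless_map)
        twice, _ = pp.preprocess_map(once)
        scale = np.max(np.abs(once.intensities))
        delta = np.abs(twice.intensities - once.intensities)
        # interior channels; the unconstrained baseline ends drift more
        assert np.max(delta[:, 10:-10]) < 0.05 * scale
        assert np.max(delta) < 0.10 * scale

    def test_ftir_mode_skips_als_and_savgol(self, noiseless_map):
        cfg = pp.PreprocessConfig(crop_lo=812, crop_hi=1795)
        out, _ = pp.preprocess_map(noiseless_map, cfg, mode="ftir")
        # 2-pt baseline + normalization only: a linear-ramp spectrum would
        # be annihilated, and outputs stay area-1 on the cropped grid
        assert out.wavenumbers[0] >= 812
        for i in range(0, out.n_voxels, 17):
            area = np.trapezoid(out.intensities[i], out.wavenumbers)
            assert area == pytest.approx(1.0, abs=1e-9)
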