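import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from iccs import (
    CorrelationSurface,
    SyntheticSpec,
    compute_fluctuations,
    crop_correlation,
    fit_gaussian,
    generate_image,
    particle_number,
    spatial_correlation,
)
from helpers import direct_correlation, oracle_lag


def autocorr(pixels, max_lag=None):
    f = compute_fluctuations(pixels)
    s = spatial_correlation(f, f)
    return crop_correlation(s, max_lag) if max_lag else s


def model_surface(amplitude, beam_radius, u, v, offset, max_lag, pair="aa"):
    lags = np.arange(-max_lag, max_lag + 1)
    xi, eta = np.meshgrid(lags, lags, indexing="ij")
    values = amplitude * np.exp(-((xi - u) ** 2 + (eta - v) ** 2) / beam_radius**2) + offset
    return CorrelationSurface(values=values, pair=pair, max_lag=max_lag)


class TestFluctuations:
    def test_constant_grid(self):
        f = compute_fluctuations(np.full((4, 4), 7.0))
        assert f.mean_intensity == 7.0
        assert np.all(f.delta == 0)

    def test_two_by_two_arithmetic(self):
        f = compute_fluctuations(np.array([[1.0, 3.0], [1.0, 3.0]]))
        assert f.mean_intensity == 2.0
        np.testing.assert_array_equal(f.delta, [[-1.0, 1.0], [-1.0, 1.0]])

    @given(arrays(np.float64, (6, 6), elements=st.floats(0.1, 100.0)))
    @settings(max_examples=25, deadline=None)
    def test_fluctuations_sum_to_zero(self, pixels):
        f = compute_fluctuations(pixels)
        assert abs(f.delta.sum()) < 1e-9 * f.mean_intensity * pixels.size

    def test_dark_roi_rejected(self):
        with pytest.raises(ValueError, match="dark"):
            compute_fluctuations(np.zeros((8, 8)))


class TestSpatialCorrelation:
    def test_zero_lag_of_worked_example(self):
        # <dI^2>/<I>^2 = 1/4 for the 2x2 grid [[1,3],[1,3]]
        s = autocorr(np.array([[1.0, 3.0], [1.0, 3.0]]))
        assert s.zero_lag_sample == pytest.approx(0.25, abs=1e-12)

    def test_global_intensity_scale_cancels(self):
        rng = np.random.default_rng(1)
        pix = rng.uniform(1, 10, (16, 16))
        f_a = compute_fluctuations(pix)
        f_b = compute_fluctuations(2.0 * pix)
        r_ab = spatial_correlation(f_a, f_b)
        r_aa = spatial_correlation(f_a, f_a)
        np.testing.assert_allclose(r_ab.values, r_aa.values, rtol=1e-12)

    def test_fft_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            pix_a = rng.uniform(1, 10, (12, 12))
            pix_b = rng.uniform(1, 10, (12, 12))
            s = spatial_correlation(compute_fluctuations(pix_a), compute_fluctuations(pix_b))
            oracle = direct_correlation(pix_a, pix_b)
            for i in range(-s.max_lag, s.max_lag + 1):
                for j in range(-s.max_lag, s.max_lag + 1):
                    assert s.values[s.max_lag + i, s.max_lag + j] == pytest.approx(
                        oracle_lag(oracle, i, j), rel=1e-10, abs=1e-12
                    )

    def test_autocorrelation_point_symmetry(self):
        rng = np.random.default_rng(3)
        s = autocorr(rng.uniform(1, 5, (15, 15)))
        np.testing.assert_allclose(s.values, s.values[::-1, ::-1], atol=1e-13)

    def test_cross_correlation_transpose_symmetry(self):
        rng = np.random.default_rng(4)
        f_a = compute_fluctuations(rng.uniform(1, 5, (14, 14)))
        f_b = compute_fluctuations(rng.uniform(1, 5, (14, 14)))
        r_ab = spatial_correlation(f_a, f_b)
        r_ba = spatial_correlation(f_b, f_a)
        np.testing.assert_allclose(r_ab.values, r_ba.values[::-1, ::-1], atol=1e-13)

    def test_independent_noise_fields_uncorrelated(self):
        bound = 5.0 / math.sqrt(64 * 64)
        rng = np.random.default_rng(10)
        for _ in range(100):
            f_a = compute_fluctuations(rng.normal(100, 10, (64, 64)))
            f_b = compute_fluctuations(rng.normal(100, 10, (64, 64)))
            s = spatial_correlation(f_a, f_b)
            assert abs(s.zero_lag_sample) < bound

    def test_zero_lag_is_peak_for_noiseless_emitters(self, noiseless_spec):
        img, _ = generate_image(noiseless_spec)
        s = autocorr(img.pixels_a, max_lag=16)
        assert s.zero_lag_sample == pytest.approx(s.values.max())

    def test_shape_mismatch(self):
        f_a = compute_fluctuations(np.ones((8, 8)) + np.eye(8))
        f_b = compute_fluctuations(np.ones((8, 9)))
        with pytest.raises(ValueError, match="differ"):
            spatial_correlation(f_a, f_b)


class TestCrop:
    def test_shape_contract(self, noiseless_spec):
        img, _ = generate_image(noiseless_spec)
        s = autocorr(img.pixels_a)
        cropped = crop_correlation(s, 16)
        assert cropped.values.shape == (33, 33)
        assert cropped.max_lag == 16

    def test_crop_composition_and_center_identity(self, noiseless_spec):
        img, _ = generate_image(noiseless_spec)
        s = autocorr(img.pixels_a)
        twice = crop_correlation(crop_correlation(s, 16), 8)
        once = crop_correlation(s, 8)
        np.testing.assert_array_equal(twice.values, once.values)
        assert once.zero_lag_sample == s.zero_lag_sample

    def test_crop_too_large(self):
        s = autocorr(np.arange(64.0).reshape(8, 8) + 1)
        with pytest.raises(ValueError, match="exceeds"):
            crop_correlation(s, 20)


class TestGaussianFit:
    def test_recovers_model_exactly(self):
        s = model_surface(0.2, 3.0, 0.0, 0.0, 0.01, max_lag=16)
        fit = fit_gaussian(s)
        assert fit.amplitude == pytest.approx(0.2, abs=1e-6)
        assert fit.beam_radius == pytest.approx(3.0, abs=1e-6)
        assert fit.offset == pytest.approx(0.01, abs=1e-6)
        assert abs(fit.peak_u) < 1e-6 and abs(fit.peak_v) < 1e-6

    def test_zero_lag_spike_excluded_from_residuals(self):
        s = model_surface(0.2, 3.0, 0.0, 0.0, 0.01, max_lag=16)
        s.values[s.max_lag, s.max_lag] += 1.0  # white-noise spike
        fit = fit_gaussian(s, exclude_zero_lag=True)
        assert fit.zero_lag_excluded
        assert fit.amplitude == pytest.approx(0.2, abs=1e-6)

    def test_closed_form_particle_number(self, noiseless_spec):
        # mean emitters per beam area N = d*pi*w0^2; fitted 1/r(0,0) ~ N
        from dataclasses import replace

        estimates = []
        for seed in range(5):
            img, truth = generate_image(replace(noiseless_spec, n_a=41, n_b=41, seed=seed))
            fit = fit_gaussian(autocorr(img.pixels_a, 16), exclude_zero_lag=True)
            estimates.append(particle_number(fit))
        true_n = 41 / 4096 * math.pi * 9
        assert np.mean(estimates) == pytest.approx(true_n, rel=0.10)

    def test_recovers_psf_radius(self, noiseless_spec):
        img, _ = generate_image(noiseless_spec)
        fit = fit_gaussian(autocorr(img.pixels_a, 16), exclude_zero_lag=True)
        assert fit.beam_radius == pytest.approx(3.0, rel=0.10)

    def test_degenerate_surface(self):
        s = CorrelationSurface(values=np.zeros((9, 9)), pair="aa", max_lag=4)
        with pytest.raises(ValueError, match="degenerate"):
            fit_gaussian(s)

    def test_surface_too_small(self):
        s = model_surface(0.2, 3.0, 0, 0, 0.0, max_lag=2)
        with pytest.raises(ValueError, match="max_lag >= 3"):
            fit_gaussian(s)

    def test_fix_peak_pins_position(self):
        s = model_surface(0.2, 3.0, 0.8, -0.5, 0.0, max_lag=10)
        fit = fit_gaussian(s, fix_peak=True)
        assert abs(fit.peak_u) < 1e-6 and abs(fit.peak_v) < 1e-6


class TestParticleNumber:
    @pytest.mark.parametrize("amplitude,expected", [(0.25, 4.0), (0.05, 20.0)])
    def test_inverse_amplitude(self, amplitude, expected):
        s = model_surface(amplitude, 3.0, 0, 0, 0.0, max_lag=8)
        assert particle_number(fit_gaussian(s)) == pytest.approx(expected, rel=1e-6)

    def test_non_positive_amplitude_rejected(self):
        fit = fit_gaussian(model_surface(0.1, 3.0, 0, 0, 0.0, max_lag=8))
        fit.amplitude = -0.1
        with pytest.raises(ValueError, match="non-positive"):
            particle_number(fit)
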