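"""Photoreceptor filter: analytic gains, DFT/convolution equivalence,
linearity, and the temporal recursion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from retinasign.retina import (
    PhotoreceptorFilter,
    PhotoreceptorParams,
    apply_photoreceptor_filter,
    opl_frequency_response,
    temporal_filter_step,
)


def circular_convolution(image, kernel):
    """Brute-force spatial-domain oracle: sum of rolled copies."""
    out = np.zeros_like(image, dtype=float)
    h, w = image.shape
    for di in range(h):
        for dj in range(w):
            out += kernel[di, dj] * np.roll(np.roll(image, di, axis=0), dj, axis=1)
    return out


class TestFrequencyResponse:
    @pytest.mark.parametrize("beta, expected", [(0.0, 1.0), (1.0, 0.5)])
    def test_dc_gain_is_reciprocal_of_one_plus_beta(self, beta, expected):
        F = opl_frequency_response((8, 8), PhotoreceptorParams(beta_ph=beta))
        assert F[0, 0] == pytest.approx(expected)

    def test_nyquist_gain_along_one_axis(self):
        # fx = 0.5, fy = 0: denominator 1 + 2*1*(2 - cos(pi) - cos(0)) = 5
        F = opl_frequency_response((8, 8), PhotoreceptorParams(0.0, 1.0, 1.0))
        assert F[0, 4] == pytest.approx(0.2)

    def test_low_pass_shape(self):
        """Gain magnitude peaks at DC and decreases monotonically along
        both frequency axes."""
        F = np.abs(opl_frequency_response((16, 16), PhotoreceptorParams()))
        assert np.all(F <= F[0, 0] + 1e-12)
        half_x = F[0, : 16 // 2 + 1]
        half_y = F[: 16 // 2 + 1, 0]
        assert np.all(np.diff(half_x) <= 1e-12)
        assert np.all(np.diff(half_y) <= 1e-12)

    def test_hermitian_symmetry_at_zero_temporal_frequency(self):
        F = opl_frequency_response((12, 10), PhotoreceptorParams())
        flipped = np.conj(F[(-np.arange(12)) % 12][:, (-np.arange(10)) % 10])
        np.testing.assert_allclose(F, flipped, atol=1e-14)

    def test_temporal_frequency_adds_imaginary_part(self):
        F = opl_frequency_response((4, 4), PhotoreceptorParams(0, 1, 2.0), ft=0.1)
        assert F[0, 0] == pytest.approx(1.0 / (1.0 + 1j * 2 * np.pi * 2.0 * 0.1))

    @pytest.mark.parametrize("bad", [{"beta_ph": -1.0}, {"alpha_ph": np.nan},
                                     {"tau_ph": -0.5}, {"alpha_ph": np.inf}])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            PhotoreceptorParams(**bad)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError):
            opl_frequency_response((0, 4), PhotoreceptorParams())


class TestApplyFilter:
    def test_uniform_image_is_fixed_point_when_beta_zero(self):
        img = np.full((9, 13), 42.0)
        out = apply_photoreceptor_filter(img, PhotoreceptorParams(beta_ph=0.0))
        np.testing.assert_allclose(out, img, atol=1e-10)

    @pytest.mark.parametrize("beta", [0.0, 1.0, 2.5])
    def test_impulse_response_sums_to_dc_gain(self, beta):
        img = np.zeros((16, 16))
        img[8, 8] = 1.0
        out = apply_photoreceptor_filter(img, PhotoreceptorParams(beta_ph=beta))
        assert out.sum() == pytest.approx(1.0 / (1.0 + beta), abs=1e-10)

    def test_matches_circular_convolution_oracle(self, rng):
        params = PhotoreceptorParams(0.3, 1.7, 1.0)
        kernel = np.real(np.fft.ifft2(opl_frequency_response((16, 16), params)))
        img = rng.random((16, 16)) * 255
        out = apply_photoreceptor_filter(img, params)
        np.testing.assert_allclose(out, circular_convolution(img, kernel),
                                   atol=1e-8)

    def test_linearity(self, rng):
        a, b = 2.5, -0.7
        i1, i2 = rng.random((12, 12)), rng.random((12, 12))
        params = PhotoreceptorParams()
        lhs = apply_photoreceptor_filter(a * i1 + b * i2, params)
        rhs = (a * apply_photoreceptor_filter(i1, params)
               + b * apply_photoreceptor_filter(i2, params))
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    @given(beta=st.floats(0, 3), mean=st.floats(0, 255))
    def test_output_mean_is_input_mean_times_dc_gain(self, beta, mean):
        img = np.full((8, 8), mean) + np.linspace(-1, 1, 64).reshape(8, 8)
        out = apply_photoreceptor_filter(img, PhotoreceptorParams(beta_ph=beta))
        assert out.mean() == pytest.approx(img.mean() / (1.0 + beta), abs=1e-8)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            apply_photoreceptor_filter(np.zeros((0, 4)))

    def test_non_finite_image_rejected(self):
        img = np.ones((4, 4))
        img[0, 0] = np.nan
        with pytest.raises(ValueError):
            apply_photoreceptor_filter(img)


class TestTemporalFilter:
    def test_tau_zero_passes_input_through(self):
        x = np.arange(12.0).reshape(3, 4)
        out = temporal_filter_step(x, np.zeros((3, 4)),
                                   PhotoreceptorParams(tau_ph=0.0))
        np.testing.assert_array_equal(out, x)

    def test_initialization_returns_current_frame(self):
        x = np.ones((3, 3)) * 7
        np.testing.assert_array_equal(temporal_filter_step(x, None), x)

    def test_step_value(self):
        out = temporal_filter_step(np.full((2, 2), 100.0), np.zeros((2, 2)),
                                   PhotoreceptorParams(tau_ph=1.0))
        np.testing.assert_allclose(out, 50.0)

    def test_constant_sequence_is_fixed_point(self):
        c = np.full((4, 4), 13.0)
        y = temporal_filter_step(c, None)
        y = temporal_filter_step(c, y, PhotoreceptorParams(tau_ph=1.0))
        np.testing.assert_allclose(y, c)

    def test_converges_to_constant_input(self):
        c = np.full((4, 4), 200.0)
        y = np.zeros((4, 4))
        for _ in range(60):
            y = temporal_filter_step(c, y, PhotoreceptorParams(tau_ph=1.0))
        np.testing.assert_allclose(y, c, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            temporal_filter_step(np.zeros((3, 3)), np.zeros((4, 4)))


class TestTransformer:
    def test_transform_stack_matches_per_image_calls(self, rng):
        X = rng.random((3, 10, 10))
        tf = PhotoreceptorFilter(beta_ph=0.5).fit(X)
        out = tf.transform(X)
        assert out.shape == X.shape
        np.testing.assert_allclose(
            out[1],
            apply_photoreceptor_filter(X[1], PhotoreceptorParams(beta_ph=0.5)),
        )

    def test_sklearn_clone_roundtrip(self):
        from sklearn.base import clone

        tf = PhotoreceptorFilter(beta_ph=0.2, alpha_ph=2.0, tau_ph=0.5)
        assert clone(tf).get_params() == tf.get_params()
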