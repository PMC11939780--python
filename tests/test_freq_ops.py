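"""Frequency/filtering primitives against hand calculations and a
brute-force convolution oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dfdrnet import freq_ops


def brute_convolve(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Nested-loop true convolution with mirror (no edge repeat) padding."""
    r = kernel.shape[0] // 2
    pad = np.pad(img, r, mode="reflect")
    kf = kernel[::-1, ::-1]  # convolution flips the kernel
    out = np.zeros_like(img, dtype=np.float64)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            acc = 0.0
            for u in range(kernel.shape[0]):
                for v in range(kernel.shape[1]):
                    acc += pad[i + u, j + v] * kf[u, v]
            out[i, j] = acc
    return out


class TestFFT:
    def test_constant_map_energy_in_dc_bin(self):
        h, w, c_val = 6, 4, 2.5
        x = np.full((h, w, 1), c_val)
        X = freq_ops.forward_fft(x)
        assert X[0, 0, 0] == pytest.approx(c_val * np.sqrt(h * w))
        X[0, 0, 0] = 0
        assert np.abs(X).max() < 1e-12

    def test_roundtrip_identity(self, rng):
        for shape in [(4, 4, 2), (8, 6, 3), (5, 7, 1), (64, 64, 8)]:
            x = rng.standard_normal(shape)
            back = freq_ops.inverse_fft(freq_ops.forward_fft(x))
            np.testing.assert_allclose(back, x, atol=1e-10)

    def test_parseval_energy_conservation(self, rng):
        x = rng.standard_normal((4, 4, 2))
        X = freq_ops.forward_fft(x)
        assert np.sum(np.abs(X) ** 2) == pytest.approx(np.sum(x**2), rel=1e-10)

    def test_roundtrip_imag_residue_zero_for_real_input(self, rng):
        x = rng.standard_normal((6, 6, 2))
        back, frac = freq_ops.inverse_fft(freq_ops.forward_fft(x), return_imag_fraction=True)
        np.testing.assert_allclose(back, x, atol=1e-10)
        assert frac < 1e-12

    def test_dc_only_spectrum_gives_constant_map(self):
        h, w = 4, 6
        X = np.zeros((h, w, 1), dtype=complex)
        X[0, 0, 0] = 3.0 * np.sqrt(h * w)
        out = freq_ops.inverse_fft(X)
        np.testing.assert_allclose(out, 3.0, atol=1e-12)

    def test_inverse_linearity(self, rng):
        X = rng.standard_normal((5, 5, 2)) + 1j * rng.standard_normal((5, 5, 2))
        Y = rng.standard_normal((5, 5, 2)) + 1j * rng.standard_normal((5, 5, 2))
        a, b = 2.5, -1.25
        lhs = freq_ops.inverse_fft(a * X + b * Y)
        rhs = a * freq_ops.inverse_fft(X) + b * freq_ops.inverse_fft(Y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_nonfinite_input_rejected(self):
        x = np.ones((4, 4, 1))
        x[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            freq_ops.forward_fft(x)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        h=st.integers(2, 12),
        w=st.integers(2, 12),
        c=st.integers(1, 4),
        seed=st.integers(0, 1000),
    )
    def test_roundtrip_and_parseval_property(self, h, w, c, seed):
        x = np.random.default_rng(seed).standard_normal((h, w, c))
        X = freq_ops.forward_fft(x)
        np.testing.assert_allclose(freq_ops.inverse_fft(X), x, atol=1e-8)
        assert np.sum(np.abs(X) ** 2) == pytest.approx(np.sum(x**2), rel=1e-9)


class TestAmplitudePhase:
    def test_hand_computed_modulus_argument(self):
        X = np.array([[[3.0 + 4.0j]]])
        amp, pha = freq_ops.split_amplitude_phase(X)
        assert amp[0, 0, 0] == pytest.approx(5.0)
        assert pha[0, 0, 0] == pytest.approx(np.arctan2(4.0, 3.0))

    def test_real_positive_spectrum_has_zero_phase(self):
        X = np.abs(np.random.default_rng(0).standard_normal((3, 3, 2))) + 0j
        _, pha = freq_ops.split_amplitude_phase(X)
        np.testing.assert_array_equal(pha, 0.0)

    def test_pure_imaginary_gives_half_pi(self):
        X = np.array([[[2.0j]]])
        _, pha = freq_ops.split_amplitude_phase(X)
        assert pha[0, 0, 0] == pytest.approx(np.pi / 2)

    def test_zero_entry_phase_defined_as_zero(self):
        X = np.zeros((2, 2, 1), dtype=complex)
        amp, pha = freq_ops.split_amplitude_phase(X)
        np.testing.assert_array_equal(amp, 0.0)
        np.testing.assert_array_equal(pha, 0.0)

    def test_reconstruction(self, rng):
        X = rng.standard_normal((6, 5, 3)) + 1j * rng.standard_normal((6, 5, 3))
        amp, pha = freq_ops.split_amplitude_phase(X)
        np.testing.assert_allclose(amp * np.exp(1j * pha), X, atol=1e-12)
        assert (amp >= 0).all()
        assert (pha > -np.pi).all() and (pha <= np.pi).all()


class TestSobel:
    def test_constant_channel_zero_response(self):
        x = np.full((5, 5, 2), 3.7)
        assert np.abs(freq_ops.sobel_edge_map(x)).max() < 1e-12

    def test_unit_ramp_interior_response_is_eight(self):
        # f(i, j) = j: Gx correlation = (1+2+1) * (j+1 - (j-1)) = 8, Gy = 0
        x = np.tile(np.arange(8.0), (8, 1))[:, :, None]
        out = freq_ops.sobel_edge_map(x)
        np.testing.assert_allclose(out[2:-2, 2:-2, 0], 8.0)

    def test_transpose_swaps_gradients(self, rng):
        x = rng.standard_normal((7, 7, 1))
        out_t = freq_ops.sobel_edge_map(np.transpose(x, (1, 0, 2)))
        np.testing.assert_allclose(out_t, np.transpose(freq_ops.sobel_edge_map(x), (1, 0, 2)),
                                   atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        x = rng.standard_normal((8, 8, 2))
        out = freq_ops.sobel_edge_map(x)
        for c in range(2):
            gx = brute_convolve(x[:, :, c], freq_ops.SOBEL_GX)
            gy = brute_convolve(x[:, :, c], freq_ops.SOBEL_GY)
            np.testing.assert_allclose(out[:, :, c], np.hypot(gx, gy), atol=1e-6)

    def test_small_input_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            freq_ops.sobel_edge_map(np.ones((2, 5, 1)))


class TestMinMaxNorm:
    def test_two_point_channel(self):
        x = np.array([[[1.0], [3.0]]])
        np.testing.assert_allclose(freq_ops.min_max_norm(x), [[[0.0], [1.0]]])

    def test_constant_channel_maps_to_zero(self):
        np.testing.assert_array_equal(freq_ops.min_max_norm(np.full((4, 4, 2), 9.0)), 0.0)

    def test_positive_affine_invariance(self, rng):
        x = rng.standard_normal((5, 6, 3))
        np.testing.assert_allclose(
            freq_ops.min_max_norm(2.5 * x + 7.0), freq_ops.min_max_norm(x), atol=1e-12
        )

    def test_range(self, rng):
        out = freq_ops.min_max_norm(rng.standard_normal((6, 6, 4)))
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestGaussian:
    def test_kernel_normalized(self):
        for sigma, k in [(0.5, 3), (1.0, 5), (2.0, 7)]:
            assert freq_ops.gaussian_kernel(sigma, k).sum() == pytest.approx(1.0)

    def test_constant_map_unchanged(self):
        x = np.full((6, 6, 2), 1.3)
        np.testing.assert_allclose(freq_ops.gaussian_smooth(x, 1.0, 3), x, atol=1e-12)

    def test_impulse_reproduces_kernel(self):
        x = np.zeros((9, 9, 1))
        x[4, 4, 0] = 1.0
        out = freq_ops.gaussian_smooth(x, 1.0, 3)
        np.testing.assert_allclose(out[3:6, 3:6, 0], freq_ops.gaussian_kernel(1.0, 3), atol=1e-12)

    def test_matches_brute_force_and_reduces_variance(self, rng):
        x = rng.standard_normal((8, 8, 2))
        out = freq_ops.gaussian_smooth(x, 1.0, 3)
        k = freq_ops.gaussian_kernel(1.0, 3)
        for c in range(2):
            np.testing.assert_allclose(out[:, :, c], brute_convolve(x[:, :, c], k), atol=1e-6)
        assert out.var() <= x.var()

    def test_even_ksize_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            freq_ops.gaussian_smooth(np.ones((4, 4, 1)), 1.0, 4)
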