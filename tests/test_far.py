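"""Frequency Adaptive Refinement and the assembled DFDR block."""

import numpy as np
import pytest

from dfdrnet import freq_ops
from dfdrnet.autodiff import Tensor, fft_call_count, reset_fft_call_count
from dfdrnet.fad import FadParams, decouple, frequency_branch, fuse_gate, spatial_branch
from dfdrnet.far import DFDRBlock, DfdrConfig, dfdr_forward, refine_high, refine_low


@pytest.fixture
def spectrum(rng):
    return rng.standard_normal((8, 8, 4)) + 1j * rng.standard_normal((8, 8, 4))


class TestRefineHigh:
    def test_zero_spectrum_gives_zero(self):
        out = refine_high(np.zeros((4, 4, 2), dtype=complex))
        np.testing.assert_array_equal(out, 0.0)

    def test_constant_magnitude_spectrum_gives_zero(self, rng):
        # constant modulus -> zero Sobel response -> degenerate norm -> A = 0
        # (phases restricted to the exact axes so |z| is bitwise constant)
        phases = rng.choice([1.0 + 0j, -1.0 + 0j, 1j, -1j], size=(4, 4, 2))
        out = refine_high(2.0 * phases)
        np.testing.assert_allclose(np.abs(out), 0.0, atol=1e-12)

    def test_positive_homogeneity(self, spectrum):
        # min-max norm is scale invariant, so refine_high(k z) = k refine_high(z)
        for k in [0.5, 3.0]:
            np.testing.assert_allclose(
                refine_high(k * spectrum), k * refine_high(spectrum), atol=1e-10
            )

    def test_attention_bounded_by_one(self, spectrum):
        out = refine_high(spectrum)
        assert (np.abs(out) <= np.abs(spectrum) + 1e-12).all()

    def test_small_spatial_dims_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            refine_high(np.ones((2, 4, 1), dtype=complex))


class TestRefineLow:
    def test_single_channel_is_identity(self, rng):
        low = rng.standard_normal((6, 6, 1)) + 1j * rng.standard_normal((6, 6, 1))
        np.testing.assert_allclose(refine_low(low), low, atol=1e-14)

    def test_identical_channels_share_weight_half(self, rng):
        one = rng.standard_normal((6, 6, 1)) + 1j * rng.standard_normal((6, 6, 1))
        low = np.concatenate([one, one], axis=2)
        out = refine_low(low)
        np.testing.assert_allclose(out, 0.5 * low, atol=1e-12)

    def test_weights_sum_to_one_and_scale_energy(self, rng):
        low = rng.standard_normal((8, 8, 4)) + 1j * rng.standard_normal((8, 8, 4))
        out = refine_low(low)
        # recompute the channel attention independently
        sm = freq_ops.gaussian_smooth(np.abs(low), 1.0, 3)
        gap = sm.mean(axis=(0, 1))
        a = np.exp(gap - gap.max())
        a /= a.sum()
        assert a.sum() == pytest.approx(1.0)
        for c in range(4):
            assert np.sum(np.abs(out[:, :, c]) ** 2) == pytest.approx(
                a[c] ** 2 * np.sum(np.abs(low[:, :, c]) ** 2), rel=1e-9
            )


class TestDfdrForward:
    def test_output_shape_preserved(self, rng):
        x = rng.standard_normal((32, 32, 16))
        p = FadParams.init(16, rng)
        ow = rng.standard_normal((16, 32, 1, 1)) * 0.1
        out = dfdr_forward(x, p, DfdrConfig(), ow)
        assert out.shape == x.shape

    def test_fused_equals_step_by_step_composition(self, rng):
        x = rng.standard_normal((8, 8, 4))
        p = FadParams.init(4, rng)
        ow = rng.standard_normal((4, 8, 1, 1)) * 0.2
        ob = rng.standard_normal(4) * 0.1

        cfg = DfdrConfig(residual=False)  # compare the pure replacement form
        p_spa = spatial_branch(x, p)
        gate = fuse_gate(p_spa, frequency_branch(x, p), p)
        high, low = decouple(freq_ops.forward_fft(x), gate)
        refined = refine_high(high) + refine_low(low, cfg)
        spat = freq_ops.inverse_fft(refined)
        cat = np.concatenate([p_spa, spat], axis=2)
        expect = np.einsum("hwk,ck->hwc", cat, ow[:, :, 0, 0]) + ob

        fused = dfdr_forward(x, p, cfg, ow, ob)
        np.testing.assert_allclose(fused, expect, atol=1e-6)

    def test_no_frequency_with_identity_conv_returns_input(self, rng):
        c = 3
        x = rng.standard_normal((8, 8, c))
        p = FadParams.init(c, rng)
        # 1x1 conv selecting the second (F_in) half of the concatenation
        ow = np.zeros((c, 2 * c, 1, 1))
        for i in range(c):
            ow[i, c + i, 0, 0] = 1.0
        out = dfdr_forward(x, p, DfdrConfig(use_frequency=False, residual=False), ow)
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_refined_spectrum_magnitude_never_exceeds_input(self, rng):
        # |A_h g z| + |a_c (1-g) z| <= |z| per bin, since both attentions <= 1
        x = rng.standard_normal((8, 8, 4))
        p = FadParams.init(4, rng)
        gate = fuse_gate(spatial_branch(x, p), frequency_branch(x, p), p)
        F = freq_ops.forward_fft(x)
        high, low = decouple(F, gate)
        rh, rl = refine_high(high), refine_low(low)
        assert (np.abs(rh) + np.abs(rl) <= np.abs(F) + 1e-10).all()


class TestKnockouts:
    def test_no_frequency_variant_never_invokes_fft(self, rng):
        blk = DFDRBlock(4, cfg=DfdrConfig(use_frequency=False), rng=rng, dtype=np.float64)
        x = Tensor(rng.standard_normal((1, 4, 8, 8)))
        reset_fft_call_count()
        out = blk(x)
        assert fft_call_count() == 0
        assert out.shape == x.shape

    def test_full_variant_invokes_fft(self, rng):
        blk = DFDRBlock(4, cfg=DfdrConfig(), rng=rng, dtype=np.float64)
        reset_fft_call_count()
        blk(Tensor(rng.standard_normal((1, 4, 8, 8))))
        assert fft_call_count() > 0

    def test_no_high_drops_gated_component(self, rng):
        x = rng.standard_normal((8, 8, 2))
        p = FadParams.init(2, rng)
        ow = np.zeros((2, 4, 1, 1))
        for i in range(2):
            ow[i, 2 + i, 0, 0] = 1.0  # pick out the inverse-FFT half
        p_spa = spatial_branch(x, p)
        gate = fuse_gate(p_spa, frequency_branch(x, p), p)
        high, low = decouple(freq_ops.forward_fft(x), gate)
        expect_no_hf = freq_ops.inverse_fft(refine_low(low, DfdrConfig()))
        out = dfdr_forward(x, p, DfdrConfig(use_high=False, residual=False), ow)
        np.testing.assert_allclose(out, expect_no_hf, atol=1e-8)
        expect_no_lf = freq_ops.inverse_fft(refine_high(high))
        out2 = dfdr_forward(x, p, DfdrConfig(use_low=False, residual=False), ow)
        np.testing.assert_allclose(out2, expect_no_lf, atol=1e-8)

    def test_imag_energy_fraction_diagnostic_bounded(self, rng):
        blk = DFDRBlock(3, cfg=DfdrConfig(), rng=rng, dtype=np.float64)
        fractions = []
        for s in range(5):
            x = Tensor(np.random.default_rng(s).standard_normal((1, 3, 8, 8)))
            blk(x)
            fractions.append(blk.last_imag_fraction)
        assert all(0.0 <= f < 0.5 for f in fractions)


def test_config_validation():
    with pytest.raises(ValueError, match="odd"):
        DfdrConfig(gaussian_ksize=4).validate()
    with pytest.raises(ValueError, match="sigma"):
        DfdrConfig(gaussian_sigma=-1.0).validate()
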