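"""Frequency Adaptive Refinement (FAR) and the assembled DFDR block.

The gated "high-frequency" spectrum is refined by an edge-attention map:
the Sobel gradient magnitude of the per-bin modulus, min–max normalized
per channel, scales the complex entries.  The residual "low-frequency"
spectrum is refined by channel attention: its modulus is Gaussian
smoothed, globally average pooled and passed through a channel softmax,
and the resulting per-channel weights (summing to one) scale the
spectrum.  Both attentions are real-valued and bounded by one, so the
refined spectrum never exceeds the input per bin in magnitude.

Filters defined for real images are applied to the *magnitude* of the
complex spectra, and the resulting real weights scale the complex
entries; this keeps the refinement well defined on spectral tensors.

The refined components are summed, returned to the spatial domain by an
inverse FFT (real part; the discarded imaginary energy fraction is kept
as a diagnostic), concatenated with the spatial context and reduced by a
1x1 convolution.  Ablation flags remove the high or low component from
the recombination entirely, or bypass frequency processing altogether
(in which case no FFT is ever invoked).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import freq_ops
from .autodiff import Tensor, concat, conv2d, ifft2_ri, pad2d
from .fad import FadParams, FrequencyAdaptiveDecoupling, _check_hwc, _from_nchw, _to_nchw
from .layers import Conv2d, Module, softmax_t

__all__ = ["DfdrConfig", "DFDRBlock", "refine_high", "refine_low", "dfdr_forward"]


@dataclass
class DfdrConfig:
    """Configuration of one DFDR block.

    ``use_high`` / ``use_low`` / ``use_frequency`` implement the ablation
    variants: a disabled component is dropped from the spectral
    recombination, and ``use_frequency=False`` reduces the block to its
    spatial branch (no FFT is performed).  ``attention_downsample=0``
    selects the automatic token-grid policy.

    ``residual`` adds the block input back onto the output.  It is on by
    default: without the residual path a randomly initialized block
    replaces its stage's features with a near-random mix, which starves
    the encoder of gradient signal and stalls from-scratch training;
    with it the block starts near the identity and learns a refinement.
    Set it off to study the pure replacement form.
    """

    use_high: bool = True
    use_low: bool = True
    use_frequency: bool = True
    gaussian_sigma: float = 1.0
    gaussian_ksize: int = 3
    attention_downsample: int = 0
    residual: bool = True

    def validate(self):
        if self.gaussian_sigma <= 0:
            raise ValueError(f"gaussian_sigma must be positive, got {self.gaussian_sigma}")
        if self.gaussian_ksize % 2 == 0 or self.gaussian_ksize < 1:
            raise ValueError(f"gaussian_ksize must be odd, got {self.gaussian_ksize}")
        if self.attention_downsample < 0:
            raise ValueError("attention_downsample must be >= 0 (0 = automatic)")
        return self


def _depthwise_fixed(x: Tensor, kernel: np.ndarray) -> Tensor:
    """Per-channel correlation with a fixed 2-D kernel, reflect padding."""
    b, c, h, w = x.shape
    k = kernel.shape[0]
    r = k // 2
    w_t = Tensor(np.asarray(kernel, dtype=x.dtype)[None, None])
    flat = x.reshape(b * c, 1, h, w)
    out = conv2d(pad2d(flat, r, r, mode="reflect"), w_t)
    return out.reshape(b, c, h, w)


def _minmax_spatial(x: Tensor) -> Tensor:
    """Per-sample, per-channel min–max normalization over the spatial axes.

    A spatially constant channel yields zeros (degenerate rule shared
    with :func:`dfdrnet.freq_ops.min_max_norm`).
    """
    lo = x.reduce_min(axis=(2, 3), keepdims=True)
    hi = x.reduce_max(axis=(2, 3), keepdims=True)
    span = hi - lo
    # the floor must survive squaring in the division backward pass
    eps = 1e-12 if x.dtype == np.float64 else np.float32(1e-6)
    return (x - lo) / span.clamp_min(eps)


def _magnitude(re: Tensor, im: Tensor) -> Tensor:
    return (re * re + im * im).sqrt()


def refine_high_t(re: Tensor, im: Tensor) -> tuple[Tensor, Tensor]:
    """Edge attention on the gated spectrum: A = MinMax(Sobel(|z|)), out = A*z."""
    mag = _magnitude(re, im)
    gx = _depthwise_fixed(mag, freq_ops.SOBEL_GX)
    gy = _depthwise_fixed(mag, freq_ops.SOBEL_GY)
    edge = (gx * gx + gy * gy).sqrt()
    att = _minmax_spatial(edge)
    return att * re, att * im


def refine_low_t(re: Tensor, im: Tensor, sigma: float, ksize: int) -> tuple[Tensor, Tensor]:
    """Channel attention on the residual spectrum: softmax(GAP(Gauss(|z|)))."""
    mag = _magnitude(re, im)
    sm = _depthwise_fixed(mag, freq_ops.gaussian_kernel(sigma, ksize))
    gap = sm.mean(axis=(2, 3), keepdims=False)  # (B, C)
    att = softmax_t(gap, axis=1)
    b, c = att.shape
    scale = att.reshape(b, c, 1, 1)
    return scale * re, scale * im


class DFDRBlock(Module):
    """Dynamic Frequency-Decoupled Refinement block (FAD + FAR).

    Shape-preserving on NCHW tensors.  After each forward pass with
    frequency processing enabled, ``last_imag_fraction`` holds the
    fraction of post-inverse-FFT energy discarded as imaginary.
    """

    def __init__(self, channels: int, cfg: DfdrConfig | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = (cfg or DfdrConfig()).validate()
        self.channels = channels
        self.fad = FrequencyAdaptiveDecoupling(
            channels, attn_downsample=self.cfg.attention_downsample, rng=rng, dtype=dtype
        )
        self.out_conv = Conv2d(2 * channels, channels, 1, rng=rng, dtype=dtype)
        self.last_imag_fraction: float | None = None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        cfg = self.cfg
        if not cfg.use_frequency:
            p_spa = self.fad.spatial_branch_t(x)
            out = self.out_conv(concat([p_spa, x], axis=1))
            return out + x if cfg.residual else out

        p_spa, gate, (fr, fi) = self.fad(x)
        hr, hi_ = gate * fr, gate * fi
        lr, li = fr - hr, fi - hi_

        parts = []
        if cfg.use_high:
            parts.append(refine_high_t(hr, hi_))
        if cfg.use_low:
            parts.append(refine_low_t(lr, li, cfg.gaussian_sigma, cfg.gaussian_ksize))
        if parts:
            sr = parts[0][0]
            si = parts[0][1]
            for pr, pi in parts[1:]:
                sr, si = sr + pr, si + pi
        else:
            sr = Tensor(np.zeros_like(fr.data))
            si = Tensor(np.zeros_like(fi.data))

        spat_re, spat_im = ifft2_ri(sr, si)
        tot = float(np.sum(spat_re.data**2) + np.sum(spat_im.data**2))
        self.last_imag_fraction = float(np.sum(spat_im.data**2) / tot) if tot > 0 else 0.0

        out = self.out_conv(concat([p_spa, spat_re], axis=1))
        return out + x if cfg.residual else out

    def count_macs(self, h: int, w: int):
        c = self.channels
        if not self.cfg.use_frequency:
            # spatial branch (attention + conv3) and the output 1x1 only
            d = self.fad._attn_stride(h, w)
            n = (h // d) * (w // d) if d > 1 else h * w
            attn = 4.0 * c * c * n + 2.0 * n * n * c
            conv = 9.0 * c * c * h * w + 2.0 * c * c * h * w
            return {"conv": conv, "attention": attn}, h, w
        macs, _, _ = self.fad.count_macs(h, w)
        macs = dict(macs)
        macs["fft"] = macs.get("fft", 0.0) + 5.0 * h * w * np.log2(h * w) * c  # inverse FFT
        filt = 0.0
        if self.cfg.use_high:
            filt += 2.0 * 9.0 * c * h * w  # two Sobel taps, depthwise
        if self.cfg.use_low:
            filt += float(self.cfg.gaussian_ksize**2) * c * h * w
        macs["conv"] = macs.get("conv", 0.0) + filt + 2.0 * c * c * h * w  # + out 1x1
        return macs, h, w


# ---------------------------------------------------------------------------
# functional surface (single H x W x C complex spectra)
# ---------------------------------------------------------------------------

def refine_high(high: np.ndarray) -> np.ndarray:
    """Edge-attention refinement of a gated spectrum (``H x W x C`` complex)."""
    high = np.asarray(high)
    _check_hwc(high.real, "high spectrum")
    if high.shape[0] < 3 or high.shape[1] < 3:
        raise ValueError(f"refine_high needs spatial dims >= 3, got {high.shape[:2]}")
    att = freq_ops.min_max_norm(freq_ops.sobel_edge_map(np.abs(high)))
    return att * high


def refine_low(low: np.ndarray, cfg: DfdrConfig | None = None) -> np.ndarray:
    """Channel-attention refinement of a residual spectrum (``H x W x C`` complex)."""
    cfg = (cfg or DfdrConfig()).validate()
    low = np.asarray(low)
    _check_hwc(low.real, "low spectrum")
    sm = freq_ops.gaussian_smooth(np.abs(low), cfg.gaussian_sigma, cfg.gaussian_ksize)
    gap = sm.mean(axis=(0, 1))
    z = np.exp(gap - gap.max())
    att = z / z.sum()
    return att[None, None, :] * low


def dfdr_forward(
    f_in: np.ndarray,
    fad: FadParams,
    cfg: DfdrConfig | None = None,
    out_conv_w: np.ndarray | None = None,
    out_conv_b: np.ndarray | None = None,
) -> np.ndarray:
    """Run one full DFDR block on a single ``H x W x C`` sample.

    ``out_conv_w`` has shape ``(C, 2C, 1, 1)`` (with optional bias); if
    omitted, a zero-bias identity-like reduction cannot be assumed, so
    the weights are required.
    """
    cfg = (cfg or DfdrConfig()).validate()
    f_in = _check_hwc(f_in, "f_in")
    c = f_in.shape[2]
    if c != fad.channels:
        raise ValueError(f"channel mismatch: input {c}, params {fad.channels}")
    if out_conv_w is None:
        raise ValueError("out_conv_w (shape (C, 2C, 1, 1)) is required")
    out_conv_w = np.asarray(out_conv_w, dtype=np.float64)
    if out_conv_w.shape != (c, 2 * c, 1, 1):
        raise ValueError(f"out_conv_w has shape {out_conv_w.shape}, expected {(c, 2 * c, 1, 1)}")

    block = DFDRBlock(c, cfg=cfg, dtype=np.float64)
    block.fad = FrequencyAdaptiveDecoupling.from_params(
        fad, attn_downsample=cfg.attention_downsample
    )
    block.out_conv.weight.data = out_conv_w
    block.out_conv.bias.data = (
        np.zeros(c) if out_conv_b is None else np.asarray(out_conv_b, dtype=np.float64)
    )
    return _from_nchw(block(_to_nchw(f_in)))
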