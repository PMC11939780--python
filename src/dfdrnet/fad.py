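"""Frequency Adaptive Decoupling (FAD).

Splits a feature map's spectrum into a "high-frequency" (gated) and
"low-frequency" (residual) pair using a learned, per-bin sigmoid gate.
The gate is fused from two context branches:

* a spatial branch — single-head self-attention over the spatial tokens
  followed by a 3x3 convolution;
* a frequency branch — per-position channel MLPs applied to the
  amplitude and phase of the orthonormal 2-D FFT, summed.

The two contexts are concatenated, reduced by a 1x1 convolution and
squashed by a sigmoid, so every gate entry lies strictly in (0, 1).
``high = gate * spectrum`` and ``low = spectrum - high``; the split is
conservative by construction.  Nothing enforces that the gated part is
literally high-frequency — the assignment of names follows the model's
convention and the split is purely learned.

Two surfaces are provided: :class:`FrequencyAdaptiveDecoupling`, the
trainable module used inside the network, and pure-NumPy functional ops
(:func:`spatial_branch`, :func:`frequency_branch`, :func:`fuse_gate`,
:func:`decouple`) that operate on single ``H x W x C`` samples and a
:class:`FadParams` bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .autodiff import Tensor, concat, fft2_ri, matmul
from .layers import Conv2d, Linear, Module, softmax_t, xavier_uniform

__all__ = [
    "FadParams",
    "FrequencyAdaptiveDecoupling",
    "spatial_branch",
    "frequency_branch",
    "fuse_gate",
    "decouple",
]

#: token count above which self-attention runs on a stride-2 grid
ATTN_AUTO_TOKEN_LIMIT = 1024


@dataclass
class FadParams:
    """Flat parameter bundle for one FAD block of channel width C.

    Attention projections are ``C x C`` with bias; the two MLPs are
    two affine layers (hidden width C) with a GELU in between, applied
    along the channel axis at each position; ``fuse_w`` is the 1x1
    convolution reducing the concatenated 2C context to a C-channel gate
    pre-activation.
    """

    wq: np.ndarray
    bq: np.ndarray
    wk: np.ndarray
    bk: np.ndarray
    wv: np.ndarray
    bv: np.ndarray
    wo: np.ndarray
    bo: np.ndarray
    conv3_w: np.ndarray
    conv3_b: np.ndarray
    mlp_pha_w1: np.ndarray
    mlp_pha_b1: np.ndarray
    mlp_pha_w2: np.ndarray
    mlp_pha_b2: np.ndarray
    mlp_amp_w1: np.ndarray
    mlp_amp_b1: np.ndarray
    mlp_amp_w2: np.ndarray
    mlp_amp_b2: np.ndarray
    fuse_w: np.ndarray
    fuse_b: np.ndarray

    @property
    def channels(self) -> int:
        return self.wq.shape[0]

    def validate(self):
        c = self.channels
        for f in fields(self):
            arr = getattr(self, f.name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"FadParams.{f.name} contains non-finite values")
        expect = {
            "wq": (c, c), "wk": (c, c), "wv": (c, c), "wo": (c, c),
            "conv3_w": (c, c, 3, 3),
            "mlp_pha_w1": (c, c), "mlp_pha_w2": (c, c),
            "mlp_amp_w1": (c, c), "mlp_amp_w2": (c, c),
            "fuse_w": (c, 2 * c, 1, 1),
        }
        for name, shp in expect.items():
            if getattr(self, name).shape != shp:
                raise ValueError(
                    f"FadParams.{name} has shape {getattr(self, name).shape}, expected {shp}"
                )
        return self

    @classmethod
    def init(cls, channels: int, rng: np.random.Generator | None = None, dtype=np.float64):
        rng = rng or np.random.default_rng()
        c = channels

        def lin():
            return xavier_uniform(rng, (c, c), c, c, dtype)

        def vec():
            return np.zeros(c, dtype=dtype)

        conv3 = (rng.standard_normal((c, c, 3, 3)) * np.sqrt(2.0 / (9 * c))).astype(dtype)
        fuse = (rng.standard_normal((c, 2 * c, 1, 1)) * np.sqrt(2.0 / (2 * c))).astype(dtype)
        return cls(
            wq=lin(), bq=vec(), wk=lin(), bk=vec(), wv=lin(), bv=vec(), wo=lin(), bo=vec(),
            conv3_w=conv3, conv3_b=vec(),
            mlp_pha_w1=lin(), mlp_pha_b1=vec(), mlp_pha_w2=lin(), mlp_pha_b2=vec(),
            mlp_amp_w1=lin(), mlp_amp_b1=vec(), mlp_amp_w2=lin(), mlp_amp_b2=vec(),
            fuse_w=fuse, fuse_b=vec(),
        )


class FrequencyAdaptiveDecoupling(Module):
    """Trainable FAD block operating on NCHW tensors.

    ``attn_downsample=0`` selects the automatic policy: attention runs on
    the full token grid when ``H*W <= 1024`` and on a stride-2 grid
    (nearest-upsampled back) otherwise, bounding the quadratic token cost.
    """

    def __init__(self, channels: int, attn_downsample: int = 0,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        c = channels
        self.channels = c
        self.attn_downsample = attn_downsample
        self.q = Linear(c, c, rng=rng, dtype=dtype)
        self.k = Linear(c, c, rng=rng, dtype=dtype)
        self.v = Linear(c, c, rng=rng, dtype=dtype)
        self.o = Linear(c, c, rng=rng, dtype=dtype)
        self.conv3 = Conv2d(c, c, 3, padding=1, rng=rng, dtype=dtype)
        self.pha1 = Linear(c, c, rng=rng, dtype=dtype)
        self.pha2 = Linear(c, c, rng=rng, dtype=dtype)
        self.amp1 = Linear(c, c, rng=rng, dtype=dtype)
        self.amp2 = Linear(c, c, rng=rng, dtype=dtype)
        self.fuse = Conv2d(2 * c, c, 1, rng=rng, dtype=dtype)

    # -- parameter bridge ---------------------------------------------
    def export_params(self) -> FadParams:
        return FadParams(
            wq=self.q.weight.data, bq=self.q.bias.data,
            wk=self.k.weight.data, bk=self.k.bias.data,
            wv=self.v.weight.data, bv=self.v.bias.data,
            wo=self.o.weight.data, bo=self.o.bias.data,
            conv3_w=self.conv3.weight.data, conv3_b=self.conv3.bias.data,
            mlp_pha_w1=self.pha1.weight.data, mlp_pha_b1=self.pha1.bias.data,
            mlp_pha_w2=self.pha2.weight.data, mlp_pha_b2=self.pha2.bias.data,
            mlp_amp_w1=self.amp1.weight.data, mlp_amp_b1=self.amp1.bias.data,
            mlp_amp_w2=self.amp2.weight.data, mlp_amp_b2=self.amp2.bias.data,
            fuse_w=self.fuse.weight.data, fuse_b=self.fuse.bias.data,
        )

    @classmethod
    def from_params(cls, p: FadParams, attn_downsample: int = 0, dtype=np.float64):
        p.validate()
        m = cls(p.channels, attn_downsample=attn_downsample, dtype=dtype)
        pairs = [
            (m.q, p.wq, p.bq), (m.k, p.wk, p.bk), (m.v, p.wv, p.bv), (m.o, p.wo, p.bo),
            (m.pha1, p.mlp_pha_w1, p.mlp_pha_b1), (m.pha2, p.mlp_pha_w2, p.mlp_pha_b2),
            (m.amp1, p.mlp_amp_w1, p.mlp_amp_b1), (m.amp2, p.mlp_amp_w2, p.mlp_amp_b2),
        ]
        for lin, w, b in pairs:
            lin.weight.data = np.asarray(w, dtype=dtype)
            lin.bias.data = np.asarray(b, dtype=dtype)
        m.conv3.weight.data = np.asarray(p.conv3_w, dtype=dtype)
        m.conv3.bias.data = np.asarray(p.conv3_b, dtype=dtype)
        m.fuse.weight.data = np.asarray(p.fuse_w, dtype=dtype)
        m.fuse.bias.data = np.asarray(p.fuse_b, dtype=dtype)
        return m

    # -- sub-computations ----------------------------------------------
    def _attn_stride(self, h: int, w: int) -> int:
        if self.attn_downsample >= 1:
            return self.attn_downsample
        return 1 if h * w <= ATTN_AUTO_TOKEN_LIMIT else 2

    def attention(self, x: Tensor) -> Tensor:
        """Single-head scaled dot-product self-attention over spatial tokens."""
        b, c, h, w = x.shape
        d = self._attn_stride(h, w)
        xs = x[:, :, ::d, ::d] if d > 1 else x
        hs, ws = xs.shape[2], xs.shape[3]
        tokens = xs.reshape(b, c, hs * ws).transpose(0, 2, 1)  # (B, N, C)
        q, k, v = self.q(tokens), self.k(tokens), self.v(tokens)
        scores = matmul(q, k.transpose(0, 2, 1)) * (1.0 / np.sqrt(c))
        att = softmax_t(scores, axis=-1)
        out = self.o(matmul(att, v))
        out = out.transpose(0, 2, 1).reshape(b, c, hs, ws)
        if d > 1:
            out = out.upsample_nearest(d)[:, :, :h, :w]
        return out

    def spatial_branch_t(self, x: Tensor) -> Tensor:
        return self.conv3(self.attention(x))

    def _freq_context(self, fr: Tensor, fi: Tensor) -> Tensor:
        amp = (fr * fr + fi * fi).sqrt()
        pha = fi.atan2(fr)
        # channel MLPs act along the last axis
        amp_t = amp.transpose(0, 2, 3, 1)
        pha_t = pha.transpose(0, 2, 3, 1)
        p_amp = self.amp2(self.amp1(amp_t).gelu())
        p_pha = self.pha2(self.pha1(pha_t).gelu())
        return (p_amp + p_pha).transpose(0, 3, 1, 2)

    def frequency_branch_t(self, x: Tensor) -> Tensor:
        fr, fi = fft2_ri(x)
        return self._freq_context(fr, fi)

    def fuse_gate_t(self, p_spa: Tensor, p_freq: Tensor) -> Tensor:
        return self.fuse(concat([p_spa, p_freq], axis=1)).sigmoid()

    def forward(self, x: Tensor):
        """Return ``(p_spa, gate, (freq_re, freq_im))`` for an NCHW input.

        The spectrum is computed once and shared between the frequency
        context branch and the downstream gated decoupling.
        """
        p_spa = self.spatial_branch_t(x)
        fr, fi = fft2_ri(x)
        p_freq = self._freq_context(fr, fi)
        gate = self.fuse_gate_t(p_spa, p_freq)
        return p_spa, gate, (fr, fi)

    def count_macs(self, h: int, w: int):
        c = self.channels
        d = self._attn_stride(h, w)
        n = (h // d) * (w // d) if d > 1 else h * w
        attn = 4.0 * c * c * n + 2.0 * n * n * c  # projections + the two token products
        conv = 9.0 * c * c * h * w + 2.0 * c * c * h * w  # conv3 + fuse 1x1
        mlp = 4.0 * c * c * h * w  # two 2-layer channel MLPs
        fft = 5.0 * h * w * np.log2(h * w) * c  # one forward FFT, shared
        return {"conv": conv + mlp, "attention": attn, "fft": fft}, h, w


# ---------------------------------------------------------------------------
# functional surface (single H x W x C samples, float64)
# ---------------------------------------------------------------------------

def _check_hwc(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError(f"{name} must be H x W x C, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def _to_nchw(x: np.ndarray) -> Tensor:
    return Tensor(np.ascontiguousarray(x.astype(np.float64).transpose(2, 0, 1)[None]))


def _from_nchw(t: Tensor) -> np.ndarray:
    return np.ascontiguousarray(t.data[0].transpose(1, 2, 0))


def spatial_branch(f_in: np.ndarray, p: FadParams, attn_downsample: int = 0) -> np.ndarray:
    """Self-attention over spatial tokens followed by a 3x3 convolution."""
    f_in = _check_hwc(f_in, "f_in")
    if f_in.shape[2] != p.channels:
        raise ValueError(f"channel mismatch: input {f_in.shape[2]}, params {p.channels}")
    m = FrequencyAdaptiveDecoupling.from_params(p, attn_downsample=attn_downsample)
    return _from_nchw(m.spatial_branch_t(_to_nchw(f_in)))


def frequency_branch(f_in: np.ndarray, p: FadParams) -> np.ndarray:
    """Channel-MLP embeddings of FFT phase and amplitude, summed."""
    f_in = _check_hwc(f_in, "f_in")
    if f_in.shape[2] != p.channels:
        raise ValueError(f"channel mismatch: input {f_in.shape[2]}, params {p.channels}")
    m = FrequencyAdaptiveDecoupling.from_params(p)
    return _from_nchw(m.frequency_branch_t(_to_nchw(f_in)))


def fuse_gate(p_spa: np.ndarray, p_freq: np.ndarray, p: FadParams) -> np.ndarray:
    """1x1 fusion of the two contexts into a sigmoid gate, entries in (0, 1)."""
    p_spa = _check_hwc(p_spa, "p_spa")
    p_freq = _check_hwc(p_freq, "p_freq")
    if p_spa.shape != p_freq.shape:
        raise ValueError(f"shape mismatch: {p_spa.shape} vs {p_freq.shape}")
    m = FrequencyAdaptiveDecoupling.from_params(p)
    return _from_nchw(m.fuse_gate_t(_to_nchw(p_spa), _to_nchw(p_freq)))


def decouple(f_freq: np.ndarray, gate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a spectrum into ``high = gate * f_freq`` and ``low = f_freq - high``.

    The real gate scales real and imaginary parts alike; the two parts
    sum back to the input spectrum exactly (a single subtraction).
    """
    f_freq = np.asarray(f_freq)
    gate = np.asarray(gate)
    if f_freq.shape != gate.shape:
        raise ValueError(f"shape mismatch: spectrum {f_freq.shape} vs gate {gate.shape}")
    if gate.min() < 0.0 or gate.max() > 1.0:
        raise ValueError("gate entries must lie in [0, 1]")
    high = gate * f_freq
    low = f_freq - high
    return high, low
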