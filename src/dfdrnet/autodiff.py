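"""Compact reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied
to it on a tape; :meth:`Tensor.backward` runs the tape in reverse
topological order and accumulates gradients.  The primitive set is
deliberately small — exactly what an encoder–decoder segmentation network
with FFT-based feature processing needs: elementwise arithmetic,
matmul, 2-D convolution, pooling/upsampling, reductions, and a pair of
orthonormal FFT primitives operating on (real, imaginary) tensor pairs.

Dtype follows the operands (float32 for training speed, float64 where
tests need tight tolerances); gradients are allocated in the same dtype.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf as _erf

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "matmul",
    "conv2d",
    "pad2d",
    "fft2_ri",
    "ifft2_ri",
    "fft_call_count",
    "reset_fft_call_count",
]

_EPS = 1e-12

_FFT_CALLS = 0


def fft_call_count() -> int:
    """Number of forward/inverse FFT primitive invocations since the last reset."""
    return _FFT_CALLS


def reset_fft_call_count():
    global _FFT_CALLS
    _FFT_CALLS = 0


def as_tensor(x, dtype=None) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype), requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- infrastructure ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order over the tape
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers -------------------------------------------------------
    @staticmethod
    def _make(data, parents, backward_fn):
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward_fn
        return out

    # -- elementwise arithmetic ----------------------------------------
    def __add__(self, other):
        other = as_tensor(other, dtype=self.dtype)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other, dtype=self.dtype))

    def __rsub__(self, other):
        return as_tensor(other, dtype=self.dtype) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, dtype=self.dtype)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, dtype=self.dtype)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.shape)
                )

        return Tensor._make(out_data, (self, other), bwd)

    def __rtruediv__(self, other):
        return as_tensor(other, dtype=self.dtype) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), bwd)

    # -- elementwise nonlinearities ------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        out_data = np.log(self.data)

        def bwd(g):
            self._accum(g / self.data)

        return Tensor._make(out_data, (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)
        guard = _EPS if self.dtype == np.float64 else 1e-6

        def bwd(g):
            self._accum(g * 0.5 / np.maximum(out_data, guard))

        return Tensor._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), bwd)

    def sigmoid(self):
        x = self.data
        out_data = np.empty_like(x)
        pos = x >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out_data[~pos] = ex / (1.0 + ex)

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def gelu(self):
        x = self.data
        cdf = 0.5 * (1.0 + _erf(x / np.sqrt(2.0)))
        out_data = x * cdf

        def bwd(g):
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            self._accum(g * (cdf + x * pdf))

        return Tensor._make(out_data, (self,), bwd)

    def clamp_min(self, lo: float):
        mask = self.data > lo
        out_data = np.where(mask, self.data, lo)

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), bwd)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reduce_max(self, axis, keepdims: bool = False):
        """Max over `axis` (int or tuple); gradient flows to the first argmax."""
        axes = tuple(np.atleast_1d(axis))
        # move reduced axes to the back and flatten them
        keep = tuple(i for i in range(self.ndim) if i not in axes)
        perm = keep + axes
        moved = self.data.transpose(perm)
        lead = moved.shape[: len(keep)]
        flat = moved.reshape(lead + (-1,))
        idx = flat.argmax(axis=-1)
        out_flat = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        out_data = out_flat
        if keepdims:
            shp = list(self.shape)
            for a in axes:
                shp[a] = 1
            out_data = out_flat.reshape(shp)

        def bwd(g):
            gg = np.asarray(g).reshape(lead)
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, idx[..., None], gg[..., None], axis=-1)
            gmoved = gflat.reshape(moved.shape)
            inv = np.argsort(perm)
            self._accum(gmoved.transpose(inv))

        return Tensor._make(out_data, (self,), bwd)

    def reduce_min(self, axis, keepdims: bool = False):
        return -((-self).reduce_max(axis, keepdims=keepdims))

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        src_shape = self.shape

        def bwd(g):
            self._accum(g.reshape(src_shape))

        return Tensor._make(out_data, (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        src_shape = self.shape

        def bwd(g):
            full = np.zeros(src_shape, dtype=g.dtype)
            full[idx] = g  # basic (non-repeating) indexing only
            self._accum(full)

        return Tensor._make(out_data, (self,), bwd)

    # -- pooling / resampling (NCHW) -----------------------------------
    def maxpool2x2(self):
        b, c, h, w = self.shape
        if h % 2 or w % 2:
            raise ValueError(f"maxpool2x2 needs even spatial dims, got {(h, w)}")
        patches = self.data.reshape(b, c, h // 2, 2, w // 2, 2)
        flat = patches.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

        def bwd(g):
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            gp = gflat.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            self._accum(gp.reshape(b, c, h, w))

        return Tensor._make(out_data, (self,), bwd)

    def upsample_nearest(self, factor: int = 2):
        b, c, h, w = self.shape
        out_data = np.repeat(np.repeat(self.data, factor, axis=2), factor, axis=3)

        def bwd(g):
            gp = g.reshape(b, c, h, factor, w, factor)
            self._accum(gp.sum(axis=(3, 5)))

        return Tensor._make(out_data, (self,), bwd)

    # -- transcendental pair op ----------------------------------------
    def atan2(self, other: "Tensor"):
        """Elementwise atan2(self, other) == atan2(y, x)."""
        other = as_tensor(other, dtype=self.dtype)
        y, x = self.data, other.data
        out_data = np.arctan2(y, x)
        denom = np.maximum(x * x + y * y, _EPS if self.dtype == np.float64 else 1e-8)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * x / denom)
            if other.requires_grad:
                other._accum(g * (-y) / denom)

        return Tensor._make(out_data, (self, other), bwd)

    def __matmul__(self, other):
        return matmul(self, other)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum `g` down to `shape` (reverse of NumPy broadcasting)."""
    if g.shape == tuple(shape):
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product via ``numpy.matmul`` semantics (2-D or 3-D)."""
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.shape))

    return Tensor._make(out_data, (a, b), bwd)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bwd)


def pad2d(x: Tensor, ph: int, pw: int, mode: str = "zero") -> Tensor:
    """Pad the two trailing spatial axes of an NCHW tensor.

    ``mode='zero'`` or ``'reflect'`` (mirror without edge repetition).
    """
    if ph == 0 and pw == 0:
        return x
    x = as_tensor(x)
    np_mode = "constant" if mode == "zero" else "reflect"
    out_data = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)), mode=np_mode)
    h, w = x.shape[2], x.shape[3]

    def bwd_full(g):
        # fold width first on the full padded grad, then height
        gw = g[:, :, :, pw : pw + w].copy()
        if mode == "reflect" and pw:
            gw[:, :, :, 1 : pw + 1] += g[:, :, :, pw - 1 :: -1]
            gw[:, :, :, w - pw - 1 : w - 1] += g[:, :, :, : pw + w - 1 : -1]
        core = gw[:, :, ph : ph + h].copy()
        if mode == "reflect" and ph:
            core[:, :, 1 : ph + 1] += gw[:, :, ph - 1 :: -1]
            core[:, :, h - ph - 1 : h - 1] += gw[:, :, : ph + h - 1 : -1]
        x._accum(core)

    return Tensor._make(out_data, (x,), bwd_full)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 1) -> Tensor:
    """Valid (unpadded) 2-D cross-correlation on NCHW input.

    ``weight`` has shape ``(C_out, C_in, kh, kw)``.  Padding is applied
    beforehand with :func:`pad2d`.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    b_, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    windows = sliding_window_view(x.data, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # (B, Cin, Ho, Wo, kh, kw) -> (B, Ho, Wo, Cin*kh*kw)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(b_, ho, wo, cin * kh * kw)
    wmat = weight.data.reshape(cout, cin * kh * kw)
    out_data = (cols @ wmat.T).transpose(0, 3, 1, 2)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, cout)  # (B*Ho*Wo, Cout)
        if weight.requires_grad:
            gw = gmat.T @ cols.reshape(-1, cin * kh * kw)
            weight._accum(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=0))
        if x.requires_grad:
            gcols = (gmat @ wmat).reshape(b_, ho, wo, cin, kh, kw)
            gx = np.zeros_like(x.data)
            for u in range(kh):
                for v in range(kw):
                    gx[:, :, u : u + stride * ho : stride, v : v + stride * wo : stride] += (
                        gcols[:, :, :, :, u, v].transpose(0, 3, 1, 2)
                    )
            x._accum(gx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out_data, parents, bwd)


def fft2_ri(re: Tensor, im: Tensor | None = None) -> tuple[Tensor, Tensor]:
    """Orthonormal 2-D FFT over the two trailing axes of NCHW tensors.

    Input and output are (real, imaginary) pairs of real tensors, which
    keeps the whole tape real-valued.  Because the orthonormal DFT is a
    unitary linear map, the adjoint used in backprop is the inverse
    transform.
    """
    global _FFT_CALLS
    _FFT_CALLS += 1
    re = as_tensor(re)
    z = re.data.astype(np.complex128) if im is None else re.data + 1j * im.data
    Z = np.fft.fft2(z, axes=(-2, -1), norm="ortho")
    out_re_data = np.ascontiguousarray(Z.real).astype(re.dtype)
    out_im_data = np.ascontiguousarray(Z.imag).astype(re.dtype)

    parents = (re,) if im is None else (re, im)
    state = {"gr": None, "gi": None}

    def flush():
        if state["gr"] is None or state["gi"] is None:
            return
        G = np.fft.ifft2(state["gr"] + 1j * state["gi"], axes=(-2, -1), norm="ortho")
        if re.requires_grad:
            re._accum(G.real.astype(re.dtype))
        if im is not None and im.requires_grad:
            im._accum(G.imag.astype(im.dtype))
        state["gr"] = state["gi"] = None

    def bwd_re(g):
        state["gr"] = np.asarray(g, dtype=np.float64)
        if state["gi"] is None:
            state["gi"] = np.zeros_like(state["gr"])
        flush()

    def bwd_im(g):
        state["gi"] = np.asarray(g, dtype=np.float64)
        if state["gr"] is None:
            state["gr"] = np.zeros_like(state["gi"])
        flush()

    out_re = Tensor._make(out_re_data, parents, bwd_re)
    out_im = Tensor._make(out_im_data, parents, bwd_im)
    return out_re, out_im


def ifft2_ri(re: Tensor, im: Tensor) -> tuple[Tensor, Tensor]:
    """Orthonormal inverse 2-D FFT on a (real, imaginary) pair; adjoint is the forward FFT."""
    global _FFT_CALLS
    _FFT_CALLS += 1
    re, im = as_tensor(re), as_tensor(im)
    Z = np.fft.ifft2(re.data + 1j * im.data, axes=(-2, -1), norm="ortho")
    out_re_data = np.ascontiguousarray(Z.real).astype(re.dtype)
    out_im_data = np.ascontiguousarray(Z.imag).astype(re.dtype)

    state = {"gr": None, "gi": None}

    def flush():
        if state["gr"] is None or state["gi"] is None:
            return
        G = np.fft.fft2(state["gr"] + 1j * state["gi"], axes=(-2, -1), norm="ortho")
        if re.requires_grad:
            re._accum(G.real.astype(re.dtype))
        if im.requires_grad:
            im._accum(G.imag.astype(im.dtype))
        state["gr"] = state["gi"] = None

    def bwd_re(g):
        state["gr"] = np.asarray(g, dtype=np.float64)
        if state["gi"] is None:
            state["gi"] = np.zeros_like(state["gr"])
        flush()

    def bwd_im(g):
        state["gi"] = np.asarray(g, dtype=np.float64)
        if state["gr"] is None:
            state["gr"] = np.zeros_like(state["gi"])
        flush()

    out_re = Tensor._make(out_re_data, (re, im), bwd_re)
    out_im = Tensor._make(out_im_data, (re, im), bwd_im)
    return out_re, out_im
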