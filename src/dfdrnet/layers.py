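"""Neural-network layers built on the :mod:`dfdrnet.autodiff` engine.

Layers follow the NCHW convention. Each parametric layer knows how to
count its own multiply–accumulate operations (``count_macs``) so the
whole network's cost can be tallied under one declared convention:
a convolution contributes ``k^2 * C_in * C_out * H_out * W_out`` MACs, a
linear map ``in * out`` per position, and normalization/activations are
not counted.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, pad2d

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "Sequential",
    "softmax_t",
]


class Module:
    """Minimal module container: parameter discovery, train/eval mode,
    and flat ``state_dict`` serialization."""

    def __init__(self):
        self.training = True

    # -- traversal -----------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    # -- mode / grads --------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- serialization -------------------------------------------------
    def _named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child._named_buffers(prefix + cname + ".")

    def state_dict(self) -> dict:
        out = {k: v.data.copy() for k, v in self.named_parameters()}
        out.update({k: v.copy() for k, v in self._named_buffers()})
        return out

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        missing = []
        for k, v in params.items():
            if k in state:
                v.data = np.asarray(state[k], dtype=v.data.dtype).reshape(v.shape)
            else:
                missing.append(k)
        buf_owners = self._buffer_owners()
        for k, (owner, attr) in buf_owners.items():
            if k in state:
                cur = getattr(owner, attr)
                setattr(owner, attr, np.asarray(state[k], dtype=cur.dtype).reshape(cur.shape))
        if missing:
            raise KeyError(f"state dict is missing parameters: {missing[:5]}...")

    def _buffer_owners(self, prefix: str = ""):
        out = {}
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                out[prefix + name] = (self, name)
        for cname, child in self._children():
            out.update(child._buffer_owners(prefix + cname + "."))
        return out

    # -- cost accounting -----------------------------------------------
    def count_macs(self, h: int, w: int):
        """Return ``(macs_by_kind: dict, h_out, w_out)`` for one forward pass."""
        total: dict[str, float] = {}
        for _, child in self._children():
            macs, h, w = child.count_macs(h, w)
            _merge(total, macs)
        return total, h, w

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _merge(acc: dict, add: dict):
    for k, v in add.items():
        acc[k] = acc.get(k, 0.0) + v


def he_normal(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


def xavier_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype=np.float32):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(dtype)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        pad_mode: str = "zero",
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel_size
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size, self.stride, self.padding = k, stride, padding
        self.pad_mode = pad_mode
        fan_in = in_channels * k * k
        self.weight = Tensor(
            he_normal(rng, (out_channels, in_channels, k, k), fan_in, dtype),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        if self.padding:
            x = pad2d(x, self.padding, self.padding, mode=self.pad_mode)
        return conv2d(x, self.weight, self.bias, stride=self.stride)

    def count_macs(self, h: int, w: int):
        k, s, p = self.kernel_size, self.stride, self.padding
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        macs = float(k * k * self.in_channels * self.out_channels * ho * wo)
        return {"conv": macs}, ho, wo


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel, with running statistics."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        super().__init__()
        self.num_features = num_features
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(num_features, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float64)
        self.running_var = np.ones(num_features, dtype=np.float64)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = batchnorm_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
            return out
        g = self.gamma.reshape(1, self.num_features, 1, 1)
        b = self.beta.reshape(1, self.num_features, 1, 1)
        mu = self.running_mean.reshape(1, -1, 1, 1).astype(x.dtype)
        inv = (1.0 / np.sqrt(self.running_var + self.eps)).reshape(1, -1, 1, 1).astype(x.dtype)
        return (x - mu) * inv * g + b

    def count_macs(self, h: int, w: int):
        return {}, h, w  # normalization is not counted


class Linear(Module):
    """Affine map applied along the last axis."""

    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_features, self.out_features = in_features, out_features
        self.weight = Tensor(
            xavier_uniform(rng, (in_features, out_features), in_features, out_features, dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y

    def count_macs(self, h: int, w: int):
        # interpreted per spatial position when used inside a conv net
        macs = float(self.in_features * self.out_features * h * w)
        return {"conv": macs}, h, w


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()

    def count_macs(self, h, w):
        return {}, h, w


class MaxPool2x2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.maxpool2x2()

    def count_macs(self, h, w):
        return {}, h // 2, w // 2


def softmax_t(x: Tensor, axis: int) -> Tensor:
    """Numerically stable softmax along ``axis`` (fused forward/backward)."""
    z = x.data - np.max(x.data, axis=axis, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=axis, keepdims=True)
    out_data = z

    def bwd(g):
        dot = np.sum(g * out_data, axis=axis, keepdims=True)
        x._accum(out_data * (g - dot))

    return Tensor._make(out_data, (x,), bwd)


def batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float):
    """Fused training-mode batch normalization over (N, H, W) per channel.

    Returns ``(out, batch_mean, batch_var)``; the statistics are plain
    arrays for the running-average update.
    """
    axes = (0, 2, 3)
    n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    gshape = (1, -1, 1, 1)
    out_data = xhat * gamma.data.reshape(gshape) + beta.data.reshape(gshape)

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum(np.sum(g * xhat, axis=axes))
        if beta.requires_grad:
            beta._accum(np.sum(g, axis=axes))
        if x.requires_grad:
            gsum = np.sum(g, axis=axes, keepdims=True)
            gxhat = np.sum(g * xhat, axis=axes, keepdims=True)
            scale = gamma.data.reshape(gshape) * inv / n
            x._accum(scale * (n * g - gsum - xhat * gxhat))

    out = Tensor._make(out_data, (x, gamma, beta), bwd)
    return out, mu.reshape(-1), var.reshape(-1)
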