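"""U-shaped encoder–decoder segmentation network with DFDR blocks.

The encoder is a ResNet50-style backbone (bottleneck residual blocks in
a 3-4-6-3 layout, expansion 4) producing skip features at 1/2, 1/4, 1/8
and 1/16 resolution and a bottleneck at 1/32.  Each skip is reduced by a
1x1 lateral convolution to the decoder width of its stage and refined by
a DFDR block; each decoder stage upsamples by two, concatenates the
refined skip, applies two 3x3 conv+BN+ReLU layers and a second DFDR
block.  A 1x1 head produces per-class logits at 1/2 resolution, which
are nearest-upsampled to the input size; softmax gives per-pixel class
posteriors.

Decoder widths are not architectural free parameters at run time: the
defaults are calibrated so the reference configuration matches the
published complexity budget (28.5 M parameters; 22.8 GMac at 256x256
under the MAC convention declared in :mod:`dfdrnet.layers` — convolution
and attention matrix products counted exactly, an H x W FFT counted as
``5 * H*W * log2(H*W)`` real MACs per channel, normalizations and
activations free).

``width_multiplier`` shrinks every channel count proportionally for
desk-scale experiments on synthetic data.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .far import DfdrConfig, DFDRBlock
from .layers import BatchNorm2d, Conv2d, Module, Sequential, softmax_t

__all__ = [
    "NetworkConfig",
    "SegmentationOutput",
    "DFDRNet",
    "build_model",
    "forward",
    "count_parameters",
    "count_macs",
    "MacReport",
    "save_checkpoint",
    "load_checkpoint",
]

#: ResNet50 stage layout: (blocks, mid channels) per stage, expansion 4.
_RESNET50_STAGES = ((3, 64), (4, 128), (6, 256), (3, 512))
_EXPANSION = 4


@dataclass
class NetworkConfig:
    """Architecture hyper-parameters.

    ``decoder_channels`` defaults are the calibrated widths (deepest
    stage first).  ``dfdr_on_skips`` / ``dfdr_in_decoder`` place one DFDR
    block per skip connection and one per decoder stage (eight total by
    default).  ``input_size`` must be divisible by 32.
    """

    input_size: int = 256
    num_classes: int = 2
    width_multiplier: float = 1.0
    decoder_channels: tuple[int, int, int, int] = (176, 128, 96, 76)
    dfdr_on_skips: bool = True
    dfdr_in_decoder: bool = True
    dfdr: DfdrConfig = field(default_factory=DfdrConfig)
    seed: int = 0

    def validate(self):
        if self.input_size % 32 != 0:
            raise ValueError(f"input_size must be divisible by 32, got {self.input_size}")
        if self.num_classes < 2:
            raise ValueError(f"num_classes must be >= 2, got {self.num_classes}")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        if len(self.decoder_channels) != 4:
            raise ValueError("decoder_channels must list four stage widths")
        self.dfdr.validate()
        return self

    def _scale(self, c: int) -> int:
        return max(1, int(round(c * self.width_multiplier)))

    @property
    def stem_channels(self) -> int:
        return self._scale(64)

    @property
    def encoder_stage_channels(self) -> list[int]:
        """Output channels of stem and the four residual stages."""
        return [self.stem_channels] + [self._scale(m) * _EXPANSION for _, m in _RESNET50_STAGES]

    @property
    def scaled_decoder_channels(self) -> list[int]:
        return [self._scale(c) for c in self.decoder_channels]


@dataclass
class SegmentationOutput:
    """Per-pixel class posteriors and the argmax mask (foreground = class 1)."""

    probabilities: np.ndarray  # (B, H, W, num_classes), rows sum to 1
    predicted_mask: np.ndarray  # (B, H, W) in {0, 1} for binary; argmax id otherwise

    @property
    def foreground_probability(self) -> np.ndarray:
        return self.probabilities[..., 1]


class _Bottleneck(Module):
    """ResNet bottleneck: 1x1 reduce, 3x3 (stride), 1x1 expand, residual add."""

    def __init__(self, cin, mid, stride, rng, dtype=np.float32):
        super().__init__()
        cout = mid * _EXPANSION
        self.conv1 = Conv2d(cin, mid, 1, bias=False, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(mid, dtype=dtype)
        self.conv2 = Conv2d(mid, mid, 3, stride=stride, padding=1, bias=False, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(mid, dtype=dtype)
        self.conv3 = Conv2d(mid, cout, 1, bias=False, rng=rng, dtype=dtype)
        self.bn3 = BatchNorm2d(cout, dtype=dtype)
        # zero-init the last BN scale so each residual block starts as the
        # identity; essential for from-scratch SGD training of a 50-layer
        # encoder at small batch sizes
        self.bn3.gamma.data[:] = 0.0
        self.down = None
        if stride != 1 or cin != cout:
            self.down = Sequential(
                Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng, dtype=dtype),
                BatchNorm2d(cout, dtype=dtype),
            )

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y)).relu()
        y = self.bn3(self.conv3(y))
        s = self.down(x) if self.down is not None else x
        return (y + s).relu()

    def count_macs(self, h, w):
        cin = self.conv1.in_channels
        mid = self.conv1.out_channels
        cout = self.conv3.out_channels
        s = self.conv2.stride
        ho, wo = h // s, w // s
        macs = float(cin * mid * h * w)  # 1x1 reduce
        macs += 9.0 * mid * mid * ho * wo  # 3x3 (stride)
        macs += float(mid * cout * ho * wo)  # 1x1 expand
        if self.down is not None:
            macs += float(cin * cout * ho * wo)  # projection shortcut
        return {"conv": macs}, ho, wo


class _Encoder(Module):
    def __init__(self, cfg: NetworkConfig, rng, dtype=np.float32):
        super().__init__()
        stem_c = cfg.stem_channels
        self.stem_conv = Conv2d(3, stem_c, 7, stride=2, padding=3, bias=False, rng=rng, dtype=dtype)
        self.stem_bn = BatchNorm2d(stem_c, dtype=dtype)
        self.stages = []
        cin = stem_c
        for si, (blocks, mid) in enumerate(_RESNET50_STAGES):
            mid_s = cfg._scale(mid)
            stride = 1 if si == 0 else 2
            mods = [_Bottleneck(cin, mid_s, stride, rng, dtype)]
            cin = mid_s * _EXPANSION
            mods += [_Bottleneck(cin, mid_s, 1, rng, dtype) for _ in range(blocks - 1)]
            self.stages.append(Sequential(*mods))

    def forward(self, x: Tensor):
        stem = self.stem_bn(self.stem_conv(x)).relu()  # 1/2
        f = stem.maxpool2x2()  # 1/4
        feats = [stem]
        for stage in self.stages:
            f = stage(f)
            feats.append(f)
        # [stem 1/2, s1 1/4, s2 1/8, s3 1/16, s4 1/32]
        return feats

    def count_macs(self, h, w):
        total, h, w = {}, h, w
        m, h, w = self.stem_conv.count_macs(h, w)
        for k, v in m.items():
            total[k] = total.get(k, 0) + v
        h, w = h // 2, w // 2  # maxpool
        for stage in self.stages:
            m, h, w = stage.count_macs(h, w)
            for k, v in m.items():
                total[k] = total.get(k, 0) + v
        return total, h, w


class _DecoderStage(Module):
    """Upsample x2, fuse the (optionally DFDR-refined) lateral skip, refine."""

    def __init__(self, cin_prev, cin_skip, cout, cfg: NetworkConfig, rng, dtype=np.float32):
        super().__init__()
        self.lateral = Conv2d(cin_skip, cout, 1, bias=False, rng=rng, dtype=dtype)
        self.lateral_bn = BatchNorm2d(cout, dtype=dtype)
        self.skip_dfdr = (
            DFDRBlock(cout, cfg=cfg.dfdr, rng=rng, dtype=dtype) if cfg.dfdr_on_skips else None
        )
        self.conv1 = Conv2d(cin_prev + cout, cout, 3, padding=1, bias=False, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(cout, dtype=dtype)
        self.conv2 = Conv2d(cout, cout, 3, padding=1, bias=False, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(cout, dtype=dtype)
        self.dec_dfdr = (
            DFDRBlock(cout, cfg=cfg.dfdr, rng=rng, dtype=dtype) if cfg.dfdr_in_decoder else None
        )

    def forward(self, below: Tensor, skip: Tensor) -> Tensor:
        up = below.upsample_nearest(2)
        lat = self.lateral_bn(self.lateral(skip)).relu()
        if self.skip_dfdr is not None:
            lat = self.skip_dfdr(lat)
        y = concat([up, lat], axis=1)
        y = self.bn1(self.conv1(y)).relu()
        y = self.bn2(self.conv2(y)).relu()
        if self.dec_dfdr is not None:
            y = self.dec_dfdr(y)
        return y

    def count_macs(self, h, w):
        # operates at the skip's resolution: h, w are the upsampled size
        total = {}
        for mod in [self.lateral, self.skip_dfdr, self.conv1, self.conv2, self.dec_dfdr]:
            if mod is None:
                continue
            m, _, _ = mod.count_macs(h, w)
            for k, v in m.items():
                total[k] = total.get(k, 0) + v
        return total, h, w


class DFDRNet(Module):
    """Full segmentation network; forward maps NCHW images in [0, 1] to logits."""

    def __init__(self, cfg: NetworkConfig, dtype=np.float32):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder = _Encoder(cfg, rng, dtype)
        enc = cfg.encoder_stage_channels  # [stem, s1, s2, s3, s4]
        dec = cfg.scaled_decoder_channels  # deepest first
        self.bottleneck = Conv2d(enc[4], dec[0], 1, bias=False, rng=rng, dtype=dtype)
        self.bottleneck_bn = BatchNorm2d(dec[0], dtype=dtype)
        skips = [enc[3], enc[2], enc[1], enc[0]]
        prev = [dec[0]] + dec[:-1]
        self.decoder = [
            _DecoderStage(prev[i], skips[i], dec[i], cfg, rng, dtype) for i in range(4)
        ]
        self.head = Conv2d(dec[3], cfg.num_classes, 1, rng=rng, dtype=dtype)

    def num_dfdr_blocks(self) -> int:
        return sum(1 for m in self.modules() if isinstance(m, DFDRBlock))

    def forward(self, x: Tensor) -> Tensor:
        """Return per-class logits at input resolution (B, num_classes, H, W)."""
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected NCHW input with 3 channels, got shape {x.shape}")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(f"spatial dims must be divisible by 32, got {x.shape[2:]}")
        stem, s1, s2, s3, s4 = self.encoder(x)
        y = self.bottleneck_bn(self.bottleneck(s4)).relu()
        for stage, skip in zip(self.decoder, [s3, s2, s1, stem]):
            y = stage(y, skip)
        logits = self.head(y)  # at 1/2 resolution
        return logits.upsample_nearest(2)

    def predict(self, images: np.ndarray) -> SegmentationOutput:
        """Run inference on a batch of H x W x 3 images in [0, 1]."""
        x = _images_to_nchw(images)
        was_training = self.training
        self.eval()
        logits = self.forward(Tensor(x))
        if was_training:
            self.train()
        probs_t = softmax_t(logits, axis=1)
        probs = np.ascontiguousarray(probs_t.data.transpose(0, 2, 3, 1))
        mask = probs.argmax(axis=-1).astype(np.uint8)
        return SegmentationOutput(probabilities=probs, predicted_mask=mask)

    def count_macs_report(self, input_size: int | None = None) -> "MacReport":
        size = input_size or self.cfg.input_size
        if size % 32:
            raise ValueError("input size must be divisible by 32")
        total, h, w = self.encoder.count_macs(size, size)
        m, h, w = self.bottleneck.count_macs(h, w)
        for k, v in m.items():
            total[k] = total.get(k, 0) + v
        for stage in self.decoder:
            h, w = h * 2, w * 2
            m, _, _ = stage.count_macs(h, w)
            for k, v in m.items():
                total[k] = total.get(k, 0) + v
        m, _, _ = self.head.count_macs(h, w)
        for k, v in m.items():
            total[k] = total.get(k, 0) + v
        return MacReport(
            conv_gmac=total.get("conv", 0.0) / 1e9,
            attention_gmac=total.get("attention", 0.0) / 1e9,
            fft_gmac=total.get("fft", 0.0) / 1e9,
        )


@dataclass
class MacReport:
    """Multiply–accumulate tally of one forward pass, by operation kind (GMac)."""

    conv_gmac: float
    attention_gmac: float
    fft_gmac: float

    @property
    def total_gmac(self) -> float:
        return self.conv_gmac + self.attention_gmac + self.fft_gmac

    @property
    def conv_only_gmac(self) -> float:
        return self.conv_gmac

    def __float__(self):
        return self.total_gmac


def build_model(cfg: NetworkConfig | None = None) -> DFDRNet:
    """Instantiate the network from a configuration (validated)."""
    return DFDRNet((cfg or NetworkConfig()))


def forward(model: DFDRNet, images: np.ndarray) -> SegmentationOutput:
    """Evaluate the model on a batch of H x W x 3 images in [0, 1]."""
    return model.predict(images)


def count_parameters(model: Module) -> float:
    """Trainable parameter count in millions."""
    return sum(p.data.size for p in model.parameters()) / 1e6


def count_macs(model: Module, input_size: int) -> MacReport | float:
    """MAC count of one forward pass at ``input_size`` square input.

    For the full network a :class:`MacReport` is returned (its float value
    is the total in GMac); for a bare layer the raw MAC count is returned.
    """
    if isinstance(model, DFDRNet):
        return model.count_macs_report(input_size)
    total, _, _ = model.count_macs(input_size, input_size)
    return float(sum(total.values()))


def _images_to_nchw(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[None]
    if images.ndim != 4 or images.shape[-1] != 3:
        raise ValueError(f"expected (B, H, W, 3) images, got shape {images.shape}")
    return np.ascontiguousarray(images.transpose(0, 3, 1, 2))


def save_checkpoint(path, model: DFDRNet, extra: dict | None = None):
    """Serialize weights plus the architecture config to a single file."""
    payload = {
        "config": model.cfg,
        "state": model.state_dict(),
        "extra": extra or {},
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path) -> tuple[DFDRNet, dict]:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    model = DFDRNet(payload["config"])
    model.load_state_dict(payload["state"])
    return model, payload.get("extra", {})
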