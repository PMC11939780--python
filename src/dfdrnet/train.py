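"""Training protocol: poly LR decay, softmax cross-entropy, SGD with
momentum, min-validation-loss checkpointing, and the frequency-ablation
suite.

The published protocol trains 256x256 patches with batch size 64 for up
to 500 epochs at initial learning rate 0.02 (poly decay), SGD momentum
0.9, selecting the epoch with the lowest validation loss.  The desk
defaults keep every rule but shrink the problem (64x64 patches, batch
8, tens of epochs) so the full pipeline runs on one CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .data_synth import SamplePair, augment
from .far import DfdrConfig
from .metrics import MetricsReport, evaluate_dataset
from .network import DFDRNet, NetworkConfig, SegmentationOutput, build_model

__all__ = [
    "TrainConfig",
    "TrainLog",
    "poly_lr",
    "softmax_ce_loss",
    "train",
    "select_epoch",
    "desk_benchmark",
    "desk_network_config",
    "run_knockout_suite",
    "KNOCKOUT_VARIANTS",
]


@dataclass
class TrainConfig:
    """Optimization settings (published values: batch 64, 500 epochs,
    patch 256; desk defaults shown)."""

    base_lr: float = 0.02
    momentum: float = 0.9
    lr_power: float = 0.9
    batch_size: int = 8
    epochs: int = 30
    patch_size: int = 64
    seed: int = 0
    checkpoint_rule: str = "min_val_loss"

    def validate(self):
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if not (0.0 < self.momentum < 1.0):
            raise ValueError("momentum must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        return self


@dataclass
class TrainLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    selected_epoch: int = -1


def select_epoch(val_losses) -> int:
    """Index of the checkpointed epoch: the first minimum of validation loss."""
    val_losses = list(val_losses)
    if not val_losses:
        raise ValueError("empty validation-loss sequence")
    return int(np.argmin(val_losses))


def desk_benchmark(seed: int = 0, n_train: int = 200, n_val: int = 50, n_test: int = 50,
                   image_size: int = 64):
    """The standard desk-scale synthetic benchmark: disjoint 200/50/50 splits.

    Samples are generated from the default :class:`SynthConfig` with
    consecutive indices, so the three sets are disjoint by construction
    and reproducible from the seed alone.
    """
    from .data_synth import SynthConfig, generate_dataset

    cfg = SynthConfig(image_size=image_size, seed=seed)
    tr = generate_dataset(cfg, n_train, start_index=0)
    va = generate_dataset(cfg, n_val, start_index=n_train)
    te = generate_dataset(cfg, n_test, start_index=n_train + n_val)
    return tr, va, te


def desk_network_config(seed: int = 0) -> NetworkConfig:
    """Reference desk-scale architecture: quarter width, 64x64 input,
    attention on a stride-2 token grid (the token cost dominates CPU
    runtime at full granularity and the gate quality does not need it)."""
    return NetworkConfig(
        input_size=64,
        width_multiplier=0.25,
        dfdr=DfdrConfig(attention_downsample=2),
        seed=seed,
    )


def run_desk_benchmark(seed: int = 0, epochs: int = 20, n_train: int = 200,
                       n_val: int = 50, n_test: int = 50):
    """Train the desk-scale model on the standard synthetic benchmark.

    Generates the 200/50/50 split, trains the quarter-width network for
    ``epochs`` epochs under the standard protocol, and evaluates the
    min-validation-loss checkpoint on the held-out test set.

    Returns ``(model, mean_metrics, TrainLog)``.
    """
    tr, va, te = desk_benchmark(seed=seed, n_train=n_train, n_val=n_val, n_test=n_test)
    model = build_model(desk_network_config(seed=seed))
    cfg = TrainConfig(epochs=epochs, seed=seed)
    _, log = train(model, tr, va, cfg)
    mean, _ = evaluate_dataset(model, te, batch_size=cfg.batch_size)
    return model, mean, log


def poly_lr(epoch: int, total_epochs: int, base_lr: float = 0.02, power: float = 0.9) -> float:
    """Polynomial decay ``base_lr * (1 - epoch/total)^power``."""
    if epoch < 0 or epoch > total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs}]")
    return base_lr * (1.0 - epoch / total_epochs) ** power


def softmax_ce_loss(probabilities, gt: np.ndarray) -> float:
    """Mean per-pixel cross-entropy ``-log p(class = gt)``.

    ``probabilities`` is a :class:`SegmentationOutput` or an array whose
    last axis holds per-pixel class posteriors; probabilities are
    clamped at 1e-7 before the log.
    """
    if isinstance(probabilities, SegmentationOutput):
        probs = probabilities.probabilities
    else:
        probs = np.asarray(probabilities)
    gt = np.asarray(gt).astype(np.int64)
    if probs.shape[:-1] != gt.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs gt {gt.shape}")
    p_correct = np.take_along_axis(probs, gt[..., None], axis=-1)[..., 0]
    return float(-np.mean(np.log(np.clip(p_correct, 1e-7, 1.0))))


def _ce_from_logits(logits: Tensor, gt: np.ndarray) -> Tensor:
    """Numerically stable softmax cross-entropy on NCHW logits (for training)."""
    b, c, h, w = logits.shape
    m = np.max(logits.data, axis=1, keepdims=True)
    zm = logits - Tensor(m)
    lse = zm.exp().sum(axis=1, keepdims=True).log() + Tensor(m)
    onehot = np.zeros(logits.shape, dtype=logits.dtype)
    np.put_along_axis(onehot, gt[:, None].astype(np.int64), 1.0, axis=1)
    z_correct = (logits * Tensor(onehot)).sum(axis=1, keepdims=True)
    return (lse - z_correct).mean()


def _stack_batch(samples: list[SamplePair]):
    imgs = np.stack([s.image for s in samples]).astype(np.float32)
    x = np.ascontiguousarray(imgs.transpose(0, 3, 1, 2))
    gt = np.stack([s.mask for s in samples]).astype(np.int64)
    return x, gt


class _SGDMomentum:
    def __init__(self, params, momentum: float):
        self.params = params
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= (lr * v).astype(p.data.dtype)


def _mean_loss(model: DFDRNet, samples: list[SamplePair], batch_size: int) -> float:
    """Validation loss: evaluation mode, no augmentation, no gradient tape."""
    model.eval()
    total, npx = 0.0, 0
    for i in range(0, len(samples), batch_size):
        x, gt = _stack_batch(samples[i : i + batch_size])
        logits = model(Tensor(x))
        loss = _ce_from_logits(logits, gt)
        total += float(loss.data) * gt.size
        npx += gt.size
    return total / npx


def train(model: DFDRNet, train_set, val_set, cfg: TrainConfig):
    """SGD-with-momentum training with per-epoch poly LR decay.

    Augmentation (flips, crop to ``patch_size``, intensity jitter) is
    applied to training samples only; validation loss is computed on the
    raw samples after every epoch, and the returned checkpoint holds the
    weights of the epoch with the lowest validation loss.

    Returns ``(checkpoint_state_dict, TrainLog)``.
    """
    cfg.validate()
    train_set, val_set = list(train_set), list(val_set)
    if not train_set or not val_set:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = _SGDMomentum(model.parameters(), cfg.momentum)
    log = TrainLog()
    best_state, best_val = None, np.inf

    for epoch in range(cfg.epochs):
        lr = poly_lr(epoch, cfg.epochs, cfg.base_lr, cfg.lr_power)
        model.train()
        order = rng.permutation(len(train_set))
        epoch_loss, seen = 0.0, 0
        for bstart in range(0, len(order), cfg.batch_size):
            idxs = order[bstart : bstart + cfg.batch_size]
            crop = min(cfg.patch_size, min(train_set[0].mask.shape))
            batch = [
                augment(train_set[i], seed=int(rng.integers(2**31)), crop_size=crop)
                for i in idxs
            ]
            x, gt = _stack_batch(batch)
            model.zero_grad()
            logits = model(Tensor(x))
            loss = _ce_from_logits(logits, gt)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={float(loss.data)}"
                )
            loss.backward()
            opt.step(lr)
            epoch_loss += float(loss.data) * len(idxs)
            seen += len(idxs)

        val_loss = _mean_loss(model, val_set, cfg.batch_size)
        log.train_loss.append(epoch_loss / seen)
        log.val_loss.append(val_loss)
        log.learning_rate.append(lr)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()

    log.selected_epoch = select_epoch(log.val_loss)
    model.load_state_dict(best_state)
    return best_state, log


#: ablation variants: name -> DfdrConfig flags
KNOCKOUT_VARIANTS = {
    "full": DfdrConfig(),
    "no_hf": DfdrConfig(use_high=False),
    "no_lf": DfdrConfig(use_low=False),
    "no_frequency": DfdrConfig(use_frequency=False),
}


def run_knockout_suite(
    train_set,
    val_set,
    test_set,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    variants: dict[str, DfdrConfig] | None = None,
):
    """Train and evaluate the frequency-ablation variants on one split.

    Every variant shares the data split, the seed and the protocol;
    only the DFDR flags differ.  Returns an ordered mapping
    ``variant name -> MetricsReport`` (mean over test images).
    """
    from dataclasses import replace

    variants = variants or KNOCKOUT_VARIANTS
    results: dict[str, MetricsReport] = {}
    for name, dfdr_cfg in variants.items():
        cfg_v = replace(net_cfg, dfdr=dfdr_cfg)
        model = build_model(cfg_v)
        train(model, train_set, val_set, train_cfg)
        mean, _ = evaluate_dataset(model, test_set, batch_size=train_cfg.batch_size)
        results[name] = mean
    return results


def knockout_table(results: dict[str, MetricsReport]) -> str:
    """Format ablation results as a fixed-width four-metric table."""
    lines = [f"{'variant':<14}{'Dice':>8}{'IoU':>8}{'Sens':>8}{'Spec':>8}"]
    for name, r in results.items():
        lines.append(
            f"{name:<14}{r.dice:>8.4f}{r.iou:>8.4f}{r.sensitivity:>8.4f}{r.specificity:>8.4f}"
        )
    return "\n".join(lines)
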