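"""Dataset handling and the synthetic colonoscopy-style sample generator.

The generator emulates the imaging conditions that make colonoscopic
polyp segmentation hard: low lesion/background contrast, specular
reflections from the wet mucosa, and partial occlusion by the dark
endoscope border.  A sample is a pink-tissue textured background with
one or more rotated, radially perturbed elliptical lesions whose
intensity offset from the background is controlled by ``contrast``;
small saturated highlight spots are added to the image but never to the
mask (they are imaging artifacts, not lesions).

Every sample is a deterministic function of ``(config, index)``:
regeneration with the same config and index is bitwise identical.

Real datasets in the same directory layout (``images/`` + ``masks/``
with same-stem single-channel PNG masks, foreground 255) load through
:func:`load_dataset`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "SamplePair",
    "SynthConfig",
    "load_dataset",
    "split_dataset",
    "augment",
    "generate_synthetic_sample",
    "generate_dataset",
    "write_dataset",
]

#: base mucosal tissue color (RGB, [0,1])
_TISSUE_RGB = np.array([0.76, 0.47, 0.42])
#: lesion tint: slightly redder/darker than surrounding tissue
_LESION_RGB = np.array([0.66, 0.34, 0.32])


@dataclass(frozen=True)
class SamplePair:
    """An image/mask pair: image ``H x W x 3`` in [0,1], mask ``H x W`` in {0,1}."""

    image: np.ndarray
    mask: np.ndarray
    id: str

    def validate(self) -> "SamplePair":
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"image must be H x W x 3, got {self.image.shape}")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match image {self.image.shape[:2]}"
            )
        if not np.all(np.isin(np.unique(self.mask), (0, 1))):
            raise ValueError("mask must be binary {0,1}")
        return self


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    ``contrast`` in (0,1] scales the lesion/background intensity
    separation (low values emulate the low-contrast regime);
    ``specular_density`` is the expected number of highlight spots per
    image; ``texture_scale`` is the correlation length (pixels) of the
    background texture; ``occlusion_prob`` is the chance of a dark
    border wedge partially covering the frame.
    """

    image_size: int = 64
    n_lesions: tuple[int, int] = (1, 3)
    lesion_axes: tuple[float, float] = (6.0, 18.0)
    contrast: float = 0.35
    specular_density: float = 8.0
    texture_scale: float = 6.0
    occlusion_prob: float = 0.3
    seed: int = 0

    def validate(self) -> "SynthConfig":
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError(f"contrast must be in (0, 1], got {self.contrast}")
        if self.n_lesions[0] > self.n_lesions[1] or self.n_lesions[0] < 0:
            raise ValueError(f"invalid n_lesions range {self.n_lesions}")
        if self.lesion_axes[0] >= self.lesion_axes[1] or self.lesion_axes[0] <= 0:
            raise ValueError(f"invalid lesion_axes range {self.lesion_axes}")
        if self.image_size < 8:
            raise ValueError("image_size must be at least 8")
        return self


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_IMAGE_EXTS = (".png", ".jpg", ".jpeg")


def load_dataset(image_dir, mask_dir) -> list[SamplePair]:
    """Load image/mask pairs; every image must have a same-stem mask.

    Images are read as RGB and scaled to [0,1]; masks are read
    single-channel and binarized at 128/255.  Pairs are sorted by id.
    """
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    for d in (image_dir, mask_dir):
        if not d.is_dir():
            raise FileNotFoundError(f"directory does not exist: {d}")
    masks = {p.stem: p for p in mask_dir.iterdir() if p.suffix.lower() in _IMAGE_EXTS}
    pairs = []
    for img_path in sorted(image_dir.iterdir()):
        if img_path.suffix.lower() not in _IMAGE_EXTS:
            continue
        if img_path.stem not in masks:
            raise FileNotFoundError(f"no mask found for image stem '{img_path.stem}'")
        image = np.asarray(Image.open(img_path).convert("RGB"), dtype=np.float64) / 255.0
        mask_raw = np.asarray(Image.open(masks[img_path.stem]).convert("L"))
        mask = (mask_raw >= 128).astype(np.uint8)
        pairs.append(SamplePair(image=image, mask=mask, id=img_path.stem).validate())
    return pairs


def write_dataset(samples, out_dir):
    """Write samples as ``images/<id>.png`` and ``masks/<id>.png`` ({0,255})."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    for s in samples:
        img = Image.fromarray((np.clip(s.image, 0, 1) * 255).round().astype(np.uint8))
        img.save(out_dir / "images" / f"{s.id}.png")
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(out_dir / "masks" / f"{s.id}.png")


# ---------------------------------------------------------------------------
# splitting and augmentation
# ---------------------------------------------------------------------------

def split_dataset(samples, fractions=(0.6, 0.2, 0.2), seed: int = 0):
    """Seeded shuffle then contiguous 60/20/20-style slicing.

    Validation and test sizes are floored; the remainder goes to the
    training split, so 1000 samples yield 600/200/200.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    samples = list(samples)
    n = len(samples)
    if n < 3:
        raise ValueError(f"need at least 3 samples to split, got {n}")
    order = np.random.default_rng(seed).permutation(n)
    n_val = int(np.floor(n * fractions[1]))
    n_test = int(np.floor(n * fractions[2]))
    n_train = n - n_val - n_test
    shuffled = [samples[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )


def augment(pair: SamplePair, seed: int, crop_size: int | None = None) -> SamplePair:
    """Random flips, random crop, and photometric jitter.

    Horizontal and vertical flips (p=0.5 each) are applied jointly to
    image and mask; the crop (if requested) is taken identically from
    both; intensity jitter (gain U(0.8, 1.2), offset U(-0.1, 0.1),
    clipped to [0,1]) touches the image only, so the mask stays binary.
    """
    rng = np.random.default_rng(seed)
    img, mask = pair.image, pair.mask
    if rng.random() < 0.5:
        img, mask = img[:, ::-1], mask[:, ::-1]
    if rng.random() < 0.5:
        img, mask = img[::-1], mask[::-1]
    if crop_size is not None:
        h, w = mask.shape
        if crop_size > h or crop_size > w:
            raise ValueError(f"crop_size {crop_size} exceeds image size {(h, w)}")
        top = rng.integers(0, h - crop_size + 1)
        left = rng.integers(0, w - crop_size + 1)
        img = img[top : top + crop_size, left : left + crop_size]
        mask = mask[top : top + crop_size, left : left + crop_size]
    gain = rng.uniform(0.8, 1.2)
    offset = rng.uniform(-0.1, 0.1)
    img = np.clip(img * gain + offset, 0.0, 1.0)
    return SamplePair(image=np.ascontiguousarray(img), mask=np.ascontiguousarray(mask), id=pair.id)


# ---------------------------------------------------------------------------
# synthesis
# ---------------------------------------------------------------------------

def _lesion_support(size: int, rng: np.random.Generator, axes_range) -> np.ndarray:
    """Boolean support of one rotated ellipse with a radially perturbed boundary."""
    a = rng.uniform(*axes_range)
    b = rng.uniform(*axes_range)
    theta = rng.uniform(0.0, np.pi)
    margin = 0.15 * size
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    phi = np.arctan2(v / b, u / a)
    # low-order radial harmonics give an irregular, polyp-like outline
    wobble = np.zeros_like(phi)
    for k in range(2, 5):
        wobble += rng.uniform(0.0, 0.08) * np.cos(k * phi + rng.uniform(0, 2 * np.pi))
    return r <= 1.0 + wobble


def generate_synthetic_sample(cfg: SynthConfig, index: int) -> SamplePair:
    """Generate one image/mask pair as a pure function of ``(cfg, index)``."""
    cfg.validate()
    rng = np.random.default_rng((cfg.seed, 7919, index))
    size = cfg.image_size

    # correlated background texture in a tissue palette
    noise = gaussian_filter(rng.standard_normal((size, size)), cfg.texture_scale)
    noise = noise / (np.abs(noise).max() + 1e-9)
    illum = gaussian_filter(rng.standard_normal((size, size)), size / 3.0)
    illum = illum / (np.abs(illum).max() + 1e-9)
    shade = 1.0 + 0.18 * noise + 0.15 * illum
    image = _TISSUE_RGB[None, None, :] * shade[:, :, None]

    # lesions: radially perturbed ellipses, blended with a soft edge
    n = int(rng.integers(cfg.n_lesions[0], cfg.n_lesions[1] + 1))
    mask = np.zeros((size, size), dtype=np.uint8)
    for _ in range(n):
        support = _lesion_support(size, rng, cfg.lesion_axes)
        mask |= support.astype(np.uint8)
        soft = gaussian_filter(support.astype(np.float64), 1.5)[:, :, None]
        lesion_color = _LESION_RGB[None, None, :] * (
            shade[:, :, None] * (1.0 + 0.1 * rng.standard_normal())
        )
        blend = cfg.contrast * soft
        image = image * (1.0 - blend) + lesion_color * blend

    # specular reflections: small saturated spots, image only
    n_spec = int(rng.poisson(cfg.specular_density))
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_spec):
        cy, cx = rng.uniform(0, size, 2)
        ry, rx = rng.uniform(0.6, 2.2, 2)
        spot = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        glow = gaussian_filter(spot.astype(np.float64), 0.8)[:, :, None]
        image = image * (1.0 - glow) + np.array([0.99, 0.97, 0.95])[None, None, :] * glow

    # partial occlusion by the dark endoscope border
    if rng.random() < cfg.occlusion_prob:
        cy = rng.uniform(-0.3, 1.3) * size
        cx = rng.uniform(-0.3, 1.3) * size
        radius = rng.uniform(0.9, 1.3) * size
        outside = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) > radius
        dark = gaussian_filter(outside.astype(np.float64), 2.0)[:, :, None]
        image = image * (1.0 - 0.85 * dark)

    image = np.clip(image, 0.0, 1.0)
    return SamplePair(image=image, mask=mask, id=f"synth_{index:05d}").validate()


def generate_dataset(cfg: SynthConfig, n: int, start_index: int = 0) -> list[SamplePair]:
    """Generate ``n`` samples with indices ``start_index .. start_index+n-1``."""
    return [generate_synthetic_sample(cfg, i) for i in range(start_index, start_index + n)]
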