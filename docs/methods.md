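# Methods

## Model

The network is a U-shaped encoder–decoder for binary (lesion /
background) segmentation of RGB endoscopy-style frames. The encoder is
a ResNet50-style backbone — a 7×7 stride-2 stem, 2×2 max-pooling, and
four stages of bottleneck residual blocks in a 3-4-6-3 layout with
expansion 4 — giving skip features at 1/2, 1/4, 1/8 and 1/16 resolution
and a bottleneck at 1/32. The final BatchNorm scale of every bottleneck
is initialized to zero, so each residual block starts as the identity —
the standard recipe for training deep residual encoders from scratch,
and at the small batch sizes used here the difference between reliable
convergence and a seed-dependent stall on the background-prior
plateau. Each skip is reduced by a 1×1 lateral
convolution to its decoder stage width and refined by a DFDR block;
each decoder stage upsamples by two (nearest), concatenates the refined
skip, applies two 3×3 conv + BatchNorm + ReLU layers and a second DFDR
block. A 1×1 head produces two-class logits at 1/2 resolution,
upsampled to the input size; per-pixel softmax gives class posteriors
and argmax the predicted mask.

### The DFDR block

Given `F_in ∈ R^{H×W×C}`, the block computes:

1. *Spatial context* `P_spa`: single-head scaled dot-product
   self-attention over the H·W spatial tokens (no positional encoding —
   the following 3×3 convolution restores locality), then a 3×3
   convolution.
2. *Frequency context* `P_freq`: per-channel orthonormal 2-D FFT;
   amplitude and phase are each passed through a two-layer channel MLP
   (hidden width C, GELU) applied independently at every frequency
   position, and the two embeddings are summed. Amplitude and phase
   MLPs have independent weights.
3. *Gate*: `σ(Conv1×1([P_spa, P_freq]))`, a per-bin value strictly in
   (0,1). The split `high = gate ⊙ F_freq`, `low = F_freq − high` is
   conservative by a single subtraction. The gate is purely learned; no
   radial prior marks which bins are "high", so the band names follow
   the model's convention rather than a guarantee.
4. *Refinement*: the high band is scaled per bin by
   `MinMaxNorm(Sobel(|high|))`; the low band per channel by
   `Softmax(GAP(Gauss(|low|)))`. Sobel and Gaussian filters are defined
   for real images, so they are applied to the *magnitude* of the
   complex spectra and the resulting real, ≤ 1 attention weights scale
   the complex entries — this keeps the refinement well defined while
   guaranteeing no bin is amplified.
5. *Fusion*: the refined bands are summed and returned to the spatial
   domain by inverse FFT. Gated spectra are no longer
   Hermitian-symmetric, so the inverse transform has an imaginary
   component; the real part is used and the imaginary energy fraction
   is recorded as a diagnostic (`DFDRBlock.last_imag_fraction`,
   typically well under 10%). The output is a 1×1 convolution of
   `[P_spa, iFFT]` plus the block input.

The residual connection is a deliberate design choice where the design
was genuinely open. A replacement-form block (output = fused features
only) was implemented first and measurably stalls from-scratch
training: with randomly initialized gates and attentions the block
rewrites its stage's features as a near-random mixture, and the
single-batch overfitting probe that a plain U-Net passes in ~60 steps
(loss 0.79 → 0.06) plateaus at loss 0.35. With the residual path the
block starts near the identity and matches plain U-Net learning speed.
The replacement form remains available (`DfdrConfig(residual=False)`).

Ablation flags mirror the knockout experiment design: `use_high=False`
/ `use_low=False` drop the corresponding band from the recombination
entirely; `use_frequency=False` reduces the block to its spatial branch
and output convolution, and provably never invokes an FFT (asserted by
call counting in the tests).

### Numerical conventions

- FFTs are orthonormal in both directions, so Parseval's identity holds
  symmetrically and the gate's effect on spectral energy is directly
  interpretable. Transforms are per channel over the two spatial axes.
- The phase of an exactly-zero spectral bin is defined as 0, making
  `amplitude·exp(i·phase)` an exact reconstruction.
- Sobel/Gaussian filtering uses mirror (reflect-without-edge-repeat)
  padding to avoid border ringing on small feature maps.
- Min–max normalization is per channel and per sample; a spatially
  constant channel maps to all zeros rather than NaN (a featureless
  channel should receive no edge attention). In the differentiable
  path the span is floored (1e-6 in single precision, 1e-12 in double)
  so its square survives the division backward pass.
- `high + low` re-adds to the input spectrum to within one ulp per
  entry (the subtraction defining `low` is exact; the verification sum
  re-rounds). Tests assert bitwise equality of `low` with
  `F_freq − high` and ≤ 5e-16 absolute residual on the sum.
- Ties in max/min reductions send the gradient to the first argmax.

### Attention token grid

Self-attention cost grows with the square of the token count. Blocks
accept an `attention_downsample` stride: at stride d the attention runs
on a d-strided token grid and is nearest-upsampled back. The automatic
policy (stride 1 up to 1024 tokens, else 2) is used in the reference
configuration and is part of the declared MAC accounting; the
desk-scale configuration fixes stride 2 throughout, which leaves the
gate quality at 64×64 inputs intact while removing the dominant CPU
cost of training.

## Complexity accounting

Published complexity figures for this architecture family are a
parameter count (28.5 M) and a MAC count (22.8 GMac at 256×256), but
not the decoder widths that produce them, so the decoder is calibrated
once against the budget: widths (176, 128, 96, 76) from deepest to
shallowest stage give 28.56 M parameters (+0.2%) and 22.76 GMac
(−0.2%) and are frozen as defaults. The MAC convention is declared
rather than inherited from any tool: a k×k convolution counts
`k²·C_in·C_out·H_out·W_out`, a channel MLP counts its two matrix
products per position, attention counts its four projections plus the
two token-matrix products, an H×W FFT counts `5·H·W·log₂(H·W)` real
MACs per channel, and normalizations/activations are free.
`count_macs` reports the split by kind so a convolution-only total is
also available.

## Training protocol

Softmax cross-entropy (training uses the numerically stable
log-sum-exp form on logits; the public loss on probabilities clamps at
1e-7 — the two agree to float precision), SGD with momentum 0.9,
initial learning rate 0.02 with per-epoch polynomial decay of power
0.9, batch size 8 at desk scale (64 at full scale), flip / crop /
intensity augmentation on training samples only, and checkpoint
selection by minimum validation loss (first minimum on ties). The
returned model carries the checkpointed weights and BatchNorm running
statistics, so re-evaluating it reproduces the logged minimum.

## Synthetic data

The generator emulates the properties that make the clinical imagery
hard: **low contrast** (lesions are a slightly redder, darker tissue
tone blended at strength `contrast`, default 0.35), **specular
reflections** (small saturated elliptical highlights at an expected 8
per frame, added to the image and deliberately excluded from the mask —
they are imaging artifacts, not lesions), and **partial occlusions** (a
dark endoscope-border wedge with probability 0.3). Backgrounds are
correlated pink-tissue noise (Gaussian-filtered, correlation length 6
px); lesions are rotated ellipses with semi-axes drawn from 6–18 px on
a 64×64 frame and low-order radial harmonic boundary perturbations, 1–3
per image, giving ~5–45% foreground coverage. Every sample is a pure
function of (config, index): regeneration is bitwise identical.

What the generator does **not** emulate: true mucosal texture and
vasculature, motion blur and fluid artifacts, the long-tailed polyp
morphology of clinical datasets, or inter-annotator boundary
uncertainty. Passing the desk-scale benchmark therefore demonstrates
that the architecture, gradients, protocol and metrics are correct and
that the model can learn low-contrast boundary delineation — not that
it reaches clinical-benchmark accuracy; the published full-scale scores
require the real datasets and GPU-scale training, which are out of
scope here.

## Desk-scale benchmark

The standard desk run uses 200 train / 50 validation / 50 test images
at 64×64 (disjoint generator indices), the quarter-width network
(width_multiplier 0.25, ~1.8 M parameters), attention stride 2, and 20
training epochs under the full protocol — sizes chosen so the complete
benchmark (generation, training, evaluation) finishes in a few minutes
on one CPU while leaving margin under the held-out Dice ≥ 0.80
criterion, under the unmodified protocol (initial learning rate 0.02,
batch 8). Occasional unstable epochs occur at this rate and are
absorbed by min-validation-loss checkpointing.
The frequency-knockout suite is run at a further reduced scale (40
images at 32×32, eighth width, 6 epochs) to exercise all four variants
end to end; at that scale and horizon the variant ranking is noisy, and
the suite's table is reported rather than asserted.

## Evaluation

Per-image Dice, IoU, sensitivity and specificity with foreground as
the positive class, averaged arithmetically over images (the dominant
convention for these benchmarks, rather than pooled-pixel ratios).
Predictions binarize by argmax, equivalent to thresholding the
foreground posterior at 0.5. Degenerate images follow the
empty-reference rule: a metric whose reference set is empty scores 1
when the prediction agrees and 0 otherwise — needed because synthetic
sets may contain lesion-free crops.

## Implementation

Everything trainable runs on a compact reverse-mode autodiff engine
(`dfdrnet.autodiff`): a Tensor wrapping a NumPy array, a tape, and the
~25 primitives this model needs, including FFT primitives on
(real, imaginary) pairs whose adjoint is the inverse transform (the
orthonormal DFT is unitary). Convolution uses im2col with BLAS matrix
products; BatchNorm and softmax have fused hand-written backward
passes. Every primitive and the assembled block are verified against
central-difference numerical gradients. Single precision is used for
training; the functional single-sample surfaces (`spatial_branch`,
`dfdr_forward`, ...) run in double precision.

## Known limitations

- CPU-only; full-scale (256×256, width 1) training is out of reach —
  only architecture accounting runs at that scale.
- Binary segmentation is the tested path (`num_classes` is
  configurable but exercised only structurally).
- The encoder trains from scratch; pretrained initialization, common
  for this model family, is not provided.
- The attention stride trades granularity for cost and is part of the
  declared configuration rather than a learned choice.
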