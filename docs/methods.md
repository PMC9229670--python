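# Methods

## Problem and model

The package segments blood vessels in grayscale slice stacks — the setting is
time-of-flight MR angiography (TOF-MRA) of the brain, where flowing blood is
bright, vessels are thin tortuous tubes, and vessel pixels are a tiny
fraction of each slice.  Segmentation is cast as conditional image-to-image
translation: a generator `G` maps a slice `x` (with noise `z`) to a
segmentation map, and a patch discriminator `D` judges `(x, map)` pairs as
real (ground truth) or generated.  The minimax objective is the conditional
GAN value function augmented with a strongly weighted L1 term,

```
g* = arg min_G max_D  L_cGAN(D, G) + λ · E‖y − G(x, z)‖₁ ,    λ = 75
```

The large λ matters because of class imbalance: with ~1–3% vessel pixels the
adversarial signal alone is weak, while the L1 term directly penalizes missed
vessels; the adversarial term then sharpens boundaries and suppresses the
isolated-blob noise a plain regression objective tends to leave.

### Generator

Two U-Net-shaped subnetworks in sequence ("dual U-Net"):

* **Subnet 1 (plain U-Net).** Four encoder levels: a stride-2 3×3
  convolution (halving the side, doubling the width) then a refining 3×3
  convolution, each followed by instance normalization and LeakyReLU
  (slope 0.2).  The decoder mirrors this with stride-2 3×3 transposed
  convolutions, concatenation skips from the matching encoder scale, and a
  refining convolution per level.  A single-channel 3×3 convolution with
  tanh closes the subnet.
* **Subnet 2 (residual U-Net).** Identical topology with each refining
  convolution replaced by a residual block
  `y = LeakyReLU(IN(conv(LReLU(IN(conv(x))))) + x)`.  A residual block must
  preserve channel count, so in the decoder it is applied to the
  transposed-convolution output *before* the skip concatenation; the next
  transposed convolution absorbs the doubled width.  Subnet 2 consumes
  subnet 1's one-channel output; there are no cross-subnet skips.

Dropout (p = 0.1) at both bottlenecks is the noise source `z` (off at
inference by default; a flag keeps it on).  Instance normalization is used
everywhere a normalization appears — it is the stable choice for
image-generation models at small batch sizes.

Channel widths follow the classic doubling ladder from a base width.  The
bases (125 for subnet 1, 112 for subnet 2) were fixed once so the default
model carries 64,995,587 trainable parameters (~65 M), with subnet 1 alone at
~30 M — the full generator is roughly twice a conventional U-Net.  Variants:
`single_unet` (subnet 1 alone) and `concat_unets` (same topology as the full
model, intended for non-adversarial training baselines).

### Discriminator

A PatchGAN: four stride-2 4×4 convolutions (instance norm + LeakyReLU,
widths doubling from base 101), dropout 0.1, then a single-filter 4×4
same-padding convolution and a sigmoid.  For a 256×256 input the output is a
16×16 map of per-patch real/fake probabilities; default parameter count
6,875,778 (~6.9 M).  The discriminator is conditional: its input is the
slice concatenated channel-wise with the (real or generated) mask.

### Training

Each step updates D then G:

* **D step** on real pairs `(x, y)` labeled 1 and generated pairs
  `(x, G(x))` labeled 0 (the generated map is detached, so G is frozen):
  `pace · ½[BCE(D(x,y), 1) + BCE(D(x,G(x)), 0)]` with pace = 0.5 — the
  discriminator objective is halved so it does not outrun the generator.
* **G step** through a frozen D: `BCE(D(x, G(x)), 1) + λ·L1`.  D's gradient
  buffers are discarded; its weights are verifiably untouched.

G uses Adam (lr 2·10⁻⁴, β₁ = 0.9, β₂ = 0.999); D uses RMSProp (same lr,
squared-gradient decay 0.9, momentum 0.9).  An optional per-epoch exponential
learning-rate schedule multiplies both rates by 0.96.  BCE probabilities are
clamped at 10⁻⁷.  Labels are plain ones/zeros 16×16 maps (no smoothing).
Epoch count defaults to 100 with patience-10 early stopping on validation
Dice; the best-Dice weights are restored at the end.  Only the generator is
kept for inference; predictions binarize the tanh output at 0.

## Network engine

No GPU framework is assumed: the package ships its own reverse-mode
autodiff on numpy arrays (`vesselgan.nn`), float32, NCHW.  Convolutions are
computed by sliding-window views + einsum; the transposed convolution is the
exact adjoint of the strided convolution (verified by an inner-product
identity and finite differences in the test suite).  Instance norm uses the
standard fused backward.  This keeps the full pipeline reproducible from a
single integer seed, at the cost of speed — which is why the shipped
experiments are desk-scale.

## Synthetic phantoms

The private 4-volume TOF-MRA dataset behind the original protocol is not
distributable, so all end-to-end runs use synthetic phantoms that reproduce
its testable structure: bright tubular structures of varying radius
(centerlines are smoothed 3-D random walks threaded through the stack, so
adjacent slices share structure), exact analytic masks (distance-to-
centerline thresholding), Gaussian background noise clipped to [0,1], and
severe class imbalance (~1–3% vessel pixels at defaults).  Default size is
32 slices of 64×64 — scaled for CPU training — with 3 vessels of radius 1–3
px, vessel intensity 0.75–1.0 over background 0.15 ± 0.05; the config
requires vessel intensity to exceed background mean + 2σ so contrast is
learnable.  What the phantoms do *not* emulate: anatomy (no Circle of
Willis), MR flow physics, bias fields, partial-volume effects, or annotation
noise — so passing tests demonstrate the machinery learns tube-vs-background
segmentation end to end, not clinical-grade performance on real MRA.

## Preprocessing and augmentation

ROI masking thresholds at τ (default 10 on 0–255; pixels exactly at τ are
kept), closes with a k×k square structuring element (default 9; disk
optional), and multiplies the mask into the slice.  Closure border
convention: dilation sees zeros outside the image (MRA borders are dark),
erosion sees ones — the standard convention under which a solid image stays
solid.  The mask is computed at native resolution, then slices are resized
(bilinear; nearest-neighbor for masks, top-left index mapping
`src_i = ⌊i·src/dst⌋`) and affinely normalized to [−1, 1].  CLAHE (clip
0.01, 8×8 tiles) is available for low-contrast modalities.

Augmentation doubles as the small-data remedy: left-right mirror flips and
random patch-zoom (zoom ~ U(1, 2], window resized back to full size, same
window for image and mask).  Two augmented copies per slice per epoch are
drawn on the fly; validation volumes are split off *before* expansion and
never augmented.

## Evaluation

Metrics derive from pixel confusion counts pooled over a whole validation
volume: Dice 2TP/(2TP+FP+FN), precision TP/(TP+FP), sensitivity TP/(TP+FN),
specificity TN/(TN+FP).  Undefined ratios (empty denominators) are reported
as missing, never as 0, and are skipped in averages.  An independent
set-based Dice (2|A∩B|/(|A|+|B|)) must agree exactly with the count formula
and is tested on 500 random mask pairs.  Error maps are |truth − pred|; their
positive count equals FP+FN by construction.  Cross-validation uses k = 4
with the deterministic cycling assignment (volume i → fold i), trains one
model per fold on the other volumes, and reports per-fold rows plus their
unweighted average.  Metrics are computed at model resolution.

## Numerical choices and degenerate inputs

* Weight init N(0, 0.02); instance-norm scale 1 / shift 0; eps 10⁻⁵.
* Tanh output binarized at exactly 0; ties cannot occur in float32 practice.
* Generator input sides must be divisible by 2^levels (16 at defaults);
  violations raise at forward time.
* Patch-zoom windows smaller than 2 px and degenerate intensity ranges
  (lo == hi) are rejected; thresholds outside a slice's declared range warn
  but still compute.
* All randomness (phantoms, weight init, dropout, augmentation, shuffling)
  descends from explicit integer seeds via seed sequences; repeated runs are
  bit-identical.

## Scale of the shipped experiments

The desk-scale study configuration used throughout the tests is 4 phantom
volumes of 32×64×64, generator/discriminator base width 8, batch 10, and at
most 10 epochs — a single CPU trains it in about two minutes, reaching pooled
validation Dice ≈ 0.8 from an untrained baseline of ≈ 0.01.  The full-size
architecture (65 M / 6.9 M parameters, 256×256 slices) is built and verified
structurally (parameter counts, output geometry) but not trained in the test
suite.

## Known limitations

Phantom realism as above; single-channel 2-D slices only (no 3-D
convolutions, no multi-modal input); no attention gates or deep supervision;
no mixed precision or multi-device support; training the full 65 M-parameter
model on real 256×256 data with this numpy engine is possible but slow —
the engine exists for correctness and reproducibility, not throughput.
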