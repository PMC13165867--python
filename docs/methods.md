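# Methods

This note documents the models, conventions and numerical choices the
package implements, the design decisions that were genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## Problem and model family

The task is binary semantic segmentation of the liver in laparoscopic RGB
frames: map an image `X ∈ [0,1]^{H×W×3}` to a probability map
`Ŷ ∈ (0,1)^{H×W}` whose 0.5-threshold is the predicted liver mask.
Laparoscopic frames are hard for classical encoders — low contrast,
specular highlights, instrument occlusion, and organ boundaries that are
both irregular and scale-variable.

Four encoder–decoder variants are implemented behind one declarative
`ArchitectureSpec`:

1. **InceptionV3 U-Net (baseline)** — an InceptionV3-style encoder with
   intermediate endpoints (`mixed0/3/6/10`) tapped as skip connections
   into a U-Net decoder.
2. **MCP U-Net** — a plain two-conv-per-stage encoder whose bottleneck is
   the *Multi-Core Pooling* block: three parallel max-pooling branches
   with kernels 2×2, 3×3 and 5×5, all stride 1 with `same` padding (so the
   grid is preserved), each followed by a learnable 1×1 convolution with
   `branch_filters` outputs (batch-norm + ReLU), channel-concatenated.
   At default width that is 3 × 256 = **768 channels**.  Max-pooling is
   used in all branches to preserve edge responses; the small kernels see
   sharp boundary detail, the 5×5 kernel structural continuity.
3. **Improved-ASPP U-Net** — the same plain encoder with an atrous
   spatial pyramid pooling bottleneck: four parallel 3×3 convolutions at
   dilation rates 2, 4, 6, 8 (256 filters each), plus a global-average-
   pooling branch through a 1×1 convolution that is broadcast back to the
   grid.  The five branches concatenate to **1280 channels** and a 1×1
   convolution reduces them to **512**.  Dilated kernels expand the
   receptive field (extent `2r+1` per 3×3 kernel at rate `r`) without
   losing resolution.
4. **Hybrid fused-bottleneck model (IMAU-Net)** — InceptionV3 taps with
   *both* blocks applied to the deepest tap `c4` and fused by channel
   concatenation: `Bottleneck = [MCP(c4) ‖ ASPP(c4)]`, 768 + 512 = 1280
   channels at default width.  MCP supplies high-frequency boundary
   evidence, ASPP global scene context; the decoder receives both.

Every decoder stage is: 3×3 transposed convolution (stride 2, ReLU) →
bilinear-resize the corresponding skip tap to the current grid → channel
concatenation → two 3×3 convolutions (ReLU).  Resize-based skip fusion
makes the decoder agnostic to the exact tap grids.  The head is two more
stride-2 transposed convolutions (backbone variants), a bilinear resize
to the input resolution, and a 1×1 convolution with sigmoid.

### Encoder tap shapes

The canonical InceptionV3 was designed for 299×299 inputs and `valid`
stem padding, which yields odd grids (35/17/8).  This package's encoder
keeps the canonical block structure and channel widths (mixed0 = 256,
mixed3 = mixed6 = 768, mixed10 = 2048) but uses `same` padding
throughout, so a 256×256 input produces clean grids: mixed0 at 32×32,
mixed3/6 at 16×16, mixed10 at 8×8.  Tap shapes are *recorded from a
forward pass*, never assumed; the resize-based skip fusion absorbs any
grid mismatch.  ImageNet weights are an optional download the package
does not perform — all experiments run from seeded He-normal
initialization, and requesting pretrained weights raises an explicit
offline-mode error.

### Width multiplier and parameter count

`width_multiplier ∈ (0,1]` scales every filter count (rounded, minimum
1).  Width 1.0 reproduces the published layer widths; widths 1/8–1/16
give desk-scale models that train on one CPU core.  At width 1.0 the
hybrid model has **62.2 M parameters** as measured from the built
network: ~21.8 M in the backbone, ~20.1 M in the ASPP block (four 3×3
convolutions on a 2048-channel input dominate), ~1.6 M in MCP, ~18.7 M
in the decoder and head.  Smaller totals sometimes quoted for this
architecture class are not reachable from the layer table as stated —
the backbone plus the ASPP branches alone exceed them — so the package
reports the honest measured count.

## The neural-network core

No deep-learning framework is used: the models run on a small NumPy
reverse-mode autodiff core inside the package (`imau_seg.nn`) with
exactly the operations the family needs — conv2d (strided, dilated,
rectangular kernels), transposed conv, max/average pooling, batch norm,
bilinear resize, concatenation, global average pooling, sigmoid/ReLU,
and the soft Dice loss.  Conventions:

- NHWC layout; float32 activations and parameters.
- `same` padding follows the TensorFlow convention (extra pixel on the
  bottom/right), which is also what stride-1 pooling with the even 2×2
  kernel requires to preserve the grid.
- Batch norm: conv → BN → ReLU ordering, momentum 0.99, eps 1e-3;
  batch statistics during training, running statistics at inference.
- Bilinear resize uses half-pixel-centre sampling; its gradient is the
  exact transpose of the interpolation weights.
- The global-average-pool branch is upsampled by broadcasting (nearest).
- Transposed convolutions produce `H×stride` outputs (`same`-style
  cropping, top-left offset `(k−s)//2`).
- Max-pool gradients distribute to all tied maxima (a valid
  subgradient; ties have measure zero for continuous activations).
- Adam with β₁ = 0.9, β₂ = 0.999, eps 1e-7.
- Soft Dice loss per sample, averaged over the batch:
  `1 − (2Σpy + s)/(Σp + Σy + s)` with smoothing `s = 1.0` by default
  (config-exposed); `s` keeps the loss finite on empty masks.

Every operation's analytic gradient is tested against central finite
differences, and forward convolution against `scipy.signal.correlate`.

## Preprocessing

Stage order: CLAHE → non-local-means denoising → morphological mask
refinement → standardize (resize, normalize to [0,1], binarize the mask
at 0.5).  Each enhancement stage has an enable flag; the four ablation
configurations (none / CLAHE / CLAHE+denoise / full) are exposed as
`ABLATION_CONFIGS`.

- **CLAHE** is applied to the L channel of CIELAB only, avoiding hue
  shifts in color endoscopic frames.  The clip limit is configured on
  the conventional CLAHE scale (default 2.0, tile grid 8×8) and mapped
  to scikit-image's clip fraction by /100 (2.0 → 0.02, a mild clip).
- **Denoising** uses fast-mode non-local means, strength 10/255 on [0,1]
  data, 7-px patches, 21-px search window.
- **Mask refinement** is opening then closing with a k×k *square*
  footprint (default 3×3).  A diamond/cross footprint was rejected
  because it erodes the corners of large compact structures; the square
  neighborhood removes isolated specks and fills pinholes while leaving
  large regions exactly intact.
- **Standardize** resizes images bilinearly and masks with
  nearest-neighbour (bilinear-then-threshold selectable), then
  binarizes strictly as `value > 0.5`.  Standardization runs last, after
  the enhancement stages, so they operate on the native resolution.

The pipeline contains no randomness and no augmentation.

## Metrics and their edge-case conventions

From pixel tallies TP/FP/FN/TN: Dice `2TP/(2TP+FP+FN)`, IoU
`TP/(TP+FP+FN)` (identity `DSC = 2·IoU/(1+IoU)` holds and is
property-tested), precision `TP/(TP+FP)`, recall `TP/(TP+FN)`.  MAE is
the mean absolute difference between the probability map and the mask.

- Both masks empty → Dice = IoU = 1.0, with a `degenerate` flag on the
  row; zero-denominator precision/recall are NaN (undefined), never 0.
  Undefined values serialize as empty CSV cells.
- **HD95**: boundary pixels are foreground with ≥1 background
  4-neighbour (out-of-image counts as background); distances come from
  exact Euclidean distance transforms; the statistic is the 95th
  percentile of the pooled directed distances in both directions.
  Either mask empty → undefined.
- **AUC-ROC** uses the Mann–Whitney/midrank convention
  (single-class truth → undefined); the test suite checks it against
  literal positive/negative pair enumeration.
- Predictions are binarized at 0.5 for counts-based metrics, matching
  the preprocessing mask threshold.

## Cross-validation, statistics, experiments

- **Folds**: 5-fold stratified by foreground-area quartile — the only
  per-sample scalar a binary segmentation dataset offers — with seeded
  shuffling; fold sizes differ by at most one.  Each training split
  donates a seeded 15% slice for convergence monitoring, so held-out
  folds are never seen during training (asserted every run).
- **Aggregation**: mean ± *population* standard deviation (divide by
  n).  With five folds the two conventions differ at the fourth decimal
  (e.g. 0.0024 vs 0.0027 on the same values); the population convention
  is used and stated wherever a summary is printed.  Rounding to 4
  decimals happens only at serialization.
- **Paired t-test**, two-sided, on per-fold scores; zero-variance
  differences are flagged degenerate (p undefined) rather than 0 or 1.
  Pixel-level tests are deliberately absent: neighbouring pixels are
  spatially correlated, which invalidates their independence
  assumptions.  Exact p-values are reported alongside conventional
  bands (<0.001, <0.01, <0.05, ns).
- **Convergence** ("loss plateau") is validation-loss patience of 10
  epochs with min-delta 1e-4; fixed epoch budgets and the patience rule
  are both implemented and the history records which fired.
- **Experiment runners**: architectural ablation (all four variants
  cross-validated under identical settings, Dice/IoU deltas vs the
  baseline), controlled comparison (one shared batch/epoch/learning-rate
  configuration for all variants, provenance columns and pairwise Dice
  differences), preprocessing ablation (the four stage-toggle
  configurations, one training each).  Loss-curve reports are stored
  unscaled; any display scaling is a plotting concern only.
- **Zero-shot external validation** is a report type: per-metric
  internal/external columns with recomputable deltas (Dice drop, the
  same in percentage points, AUC drop).

## Explainability

Occlusion importance at region granularity: the image is divided into a
grid (default 8×8), each cell is replaced by a constant baseline
(default 0) in turn, and the importance of the cell is the Dice the
perturbation costs against the ground truth.  The map is deterministic,
model-agnostic, and satisfies two identities used as tests: a
constant-output model has zero importance everywhere, and occluding a
region with its own pixel values changes nothing.  This deterministic
grid replaces random-superpixel surrogate methods; it keeps the intent —
which regions drive the prediction — without a sampling procedure whose
parameters would be unspecified.

## Synthetic scenes: what they emulate and what they do not

The generator produces laparoscopic-*like* scenes: one bright organ
region with an irregular boundary (ellipse with smoothed periodic radial
perturbation, amplitude = `boundary_irregularity` × mean radius) on
darker tissue, instrument-like straight bars rendered dark with a bright
specular edge and *removed from the mask* (the mask is the visible
organ; a flag restores amodal masks), a linear illumination ramp in a
random direction, occasional specular blobs, and additive Gaussian
sensor noise.  The pre-occlusion organ area fraction is controlled to
lie inside `organ_area_range` (default 0.1–0.5, config-exposed; the
distribution in real surgical frames is not documented anywhere
authoritative).  Samples with under 0.5% visible organ are redrawn up to
10 times, then an error is raised.  Randomness is substreamed per sample
index, so sample `i` is identical regardless of generation order.

What passing tests on these scenes show: the implementation learns, the
harness is leak-free and reproducible, metrics and explanations behave
as specified.  What they do not show: performance on real laparoscopic
data.  Real frames have texture, blood, smoke, deformable instruments,
camera motion and annotation noise that the generator does not model;
absolute Dice values obtained here do not transfer.

## Desk-scale problem sizes

The test suite and examples run narrow models by design: width 1/8–1/16,
160×160 or 256×256 inputs, 8–12 samples, ≤250 optimizer steps, k = 2
folds for runner checks.  The learnability check drives a width-0.125
hybrid model to train Dice ≥ 0.90 on eight 256×256 synthetic scenes
within 200 steps; the explainability check reuses that trained model.
Width 1.0 with the published budgets (batch 32, 50 epochs, Adam 1e-3)
is the full-scale configuration and runs unchanged, just longer.

## Known limitations

- Random-initialized backbone only; no ImageNet transfer.
- CPU-bound NumPy execution: full-width training is impractical here
  (inference is fine); desk-scale widths exist for exactly this reason.
- Binary (background/liver) scenes only; no multi-class heads.
- The measured full-width parameter count (62.2 M) exceeds smaller
  published totals for this architecture class, which are not
  derivable from the stated layers (see the parameter-count section).
- HD95 is grid-based (pixel units); no sub-pixel boundary model.
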