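# Methods

## Problem and model

The package classifies subjects as difficult / non-difficult airway from five
coordinated facial photographs. The design treats the five views as two
geometric groups — three frontal, two lateral — because the informative
anatomy differs: mouth opening and oropharyngeal visibility are frontal cues;
thyromental distance and neck extension are lateral cues. Each group is
stacked channel-wise (9 and 6 channels) and processed by an independent
backbone, so each path can specialise; the metric losses then shape the
relationship between the two paths' embeddings.

### Trimmed backbone

The extractor is a ResNet18-style network with one basic block per stage
instead of two, keeping the stride-2 projection block in stages 2–4. This
reading of the published "removed four convolutional modules" trim is the
reconstruction that reproduces the printed footprints exactly: 4,905,792
parameters (4.91 M at two decimals) and 0.889 G convolution MACs at a
3-channel 224 px input, and the printed 49% MAC ratio against ResNet18
(1.814 G under the same convention). No other natural trim we considered
(removing whole stages, halving widths) lands on all of these numbers at
once. The stem is the standard 7×7/2 convolution + BN + ReLU + 3×3/2
max-pool; initialisation is Kaiming normal (BN γ=1, β=0); there is no
pretraining — the 9- and 6-channel stems preclude direct weight transfer.

Footprint accounting convention: parameter counts exclude the classification
head and use 3 input channels; MACs count, per convolution, weight count ×
output positions. Reference architectures (ResNet18, MobileNetV2) are
represented as analytic layer tables for this accounting; the trimmed
backbone's table is additionally cross-checked against the instantiated
module's arrays in the tests. The deployed dual-path model is larger than
the per-path figure (two backbones, fusion, attention, heads); `num_params`
on the model reports it, but it is not a quoted footprint.

### Multi-scale fusion (MFFM)

Each pyramid scale passes a 1×1 convolution to a common width of 128
channels, shallow scales are adaptively average-pooled down and the deepest
scale bilinearly up-sampled to the stride-16 grid, and the four aligned maps
are concatenated (512 channels). The target grid (stride 16) and per-scale
width (128) are free choices: stride 16 balances resolution against the cost
of the attention module that follows, and 4×128 makes the fused width equal
the backbone's final width so ablations (MFFM on/off) feed the same head
widths. Bilinear resampling uses the half-pixel-centre convention and is
implemented as a separable linear map, which makes its adjoint (backward
pass) exact.

### Hybrid co-attention (HCAM)

The channel branch pools the fused map with (1,W) and (H,1) kernels to get
per-row and per-column channel descriptors, passes each through a kernel-3
1-D convolution along its spatial axis (channels preserved) and a sigmoid,
and gates the input with both weight maps; the spatial branch merges
channel-wise average- and max-pooled maps by a 1×1 convolution, extracts
column and row profiles with full-height (H,1) and full-width (1,W)
convolutions, and gates the input with their sigmoids. The 4C-channel
concatenation of the four gated copies is projected back to C channels by a
1×1 convolution. Published descriptions of this family leave the pooling
types, kernel sizes and merge order open; the choices here follow the
coordinate-attention style the design mirrors and are isolated inside the
`HCAM` module so alternatives can be swapped in. All gates are sigmoids, so
attention weights lie strictly in (0,1) in exact arithmetic (float32 can
round extreme activations to 0.0/1.0).

The full-size (H,1)/(1,W) spatial kernels depend on the input resolution, so
`DMFNet.build_for_input(size)` materialises them before an optimiser walks
the parameter list.

### Heads and classifier

Global average pooling gives one 512-vector per path. A single linear CPP
head and a single linear CSP head are shared across paths (a config flag
provides per-path heads); the projection width d_z = 128 is a free choice —
the losses only need a fixed width. The classifier is FC 1024→256 → ReLU →
dropout 0.5 → FC 256→1 → sigmoid; the hidden width 256 and single dropout
site between the two FC layers resolve an internally inconsistent
description of "two dropout layers between the two fully connected layers"
for a two-layer classifier.

## Objective

L = L_focal + 0.25·L_comple + 0.5·L_consist.

* Focal loss: mean −α_t(1−p_t)^γ log p_t with γ=2.0, α=0.25; probabilities
  are clamped at 1e−7 before the log. With γ=0 and α=0.5 it reduces to half
  the binary cross-entropy (tested).
* Complementarity: mean max(0, τ−‖z₁−z₂‖²), τ=1, on the CPP pair. The hinge
  saturates (zero loss, zero gradient) once paired embeddings are τ apart in
  squared distance; with randomly initialised high-dimensional embeddings it
  typically starts saturated and acts as a barrier rather than a driving
  force.
* Consistency: mean ‖z₁−z₂‖² on the CSP pair.

The trailing exponent in the published hinge/proximity definitions is read
as *squared* Euclidean distance — the standard contrastive form, and the one
that makes the two losses exact mirrors; `LossWeights(distance="plain")`
switches to the unsquared norm. All reductions are batch means.

## Training and evaluation protocol

Adam, lr 10⁻³ decayed ×0.1 every 30 epochs, batch 16, up to 120 epochs,
early stopping when the monitored loss fails to improve for 5 consecutive
epochs, restoring the best epoch's parameters. Early stopping monitors the
*training* loss: the protocol describes no validation split, and carving one
from 180 subjects with 20 positives would be noisy; a validation-monitor
variant can be added by splitting before `train_fold`. Batches of a single
sample are skipped (batch-norm needs ≥2 samples).

Cross-validation is stratified at subject level (scikit-learn
`StratifiedKFold`, shuffled, seeded); augmented copies carry their source
subject id and always follow it to the same side of the split — the harness
asserts this at run time. The default evaluates on *unaugmented* held-out
subjects (`eval_mode="original_only"`); `"augmented_test"` mirrors protocols
that score augmented test pools. Confusion counts use threshold 0.5; AUC is
the rank-based (Mann–Whitney) statistic with ties counted ½, computed by
scikit-learn and checked against a brute-force pairwise oracle in the tests.
Fold means are arithmetic means.

Determinism: every stochastic element (phantom sampling, augmentation draws,
weight init, batch order, dropout) flows from integer seeds through
numpy Generators; two runs with the same seeds produce bitwise-identical
parameters and scores in a single-threaded BLAS configuration.

## Synthetic cohort: what it does and does not show

The generator emulates the *statistical* structure of a multi-view airway
cohort, not its appearance. Latent geometry per subject: mouth opening
(mean 0.20 of image size, SD 0.04), thyromental distance (0.26, 0.05), neck
extension (25°, 6°), facial height/width ratio (1.30, 0.08); for difficult
subjects each mean is shifted by `class_separation` SDs in the clinical
direction (smaller opening/distance/extension, larger ratio). Defaults:
class_separation 1.5 and background noise SD 0.05, with grayscale rendering
and per-view pose jitter (SD 2 px, 2°).

The renderer is calibrated so a reduced-scale run lands in a
learnable-but-not-trivial regime (held-out AUC ≈ 0.85–0.95). Three choices
matter:

* the mouth aperture height scales 1:1 with the latent mouth opening, so the
  class shift stays several pixels wide even at 64 px;
* the background texture is shared across the cohort (keyed on the cohort
  seed and view role, like one clinic backdrop behind every subject), so it
  carries no subject identity a classifier could memorise — an early
  per-subject-keyed variant turned the background into an identity
  watermark, and networks learned it instead of the geometry;
* the generator emits face-region crop boxes (forehead to neck base, face
  edge to face edge) in its manifests, mirroring the central-cropping
  preprocessing step, which strips most of the remaining background before
  resizing.

Because the background is independent of the latent geometry, class features
perturb exactly the pixels they draw: mouth parameters leave lateral views
bitwise unchanged and vice versa (complementarity by construction), while
one latent vector drives all five views (consistency by construction).

Passing tests on phantoms therefore demonstrate that the architecture,
losses, augmentation and cross-validation machinery behave as specified and
that the network can extract a cross-view geometric signal; they say nothing
about performance on clinical photographs, whose nuisance structure
(illumination, pose, occlusion, demographics) the phantoms deliberately do
not model.

## Problem sizes used in tests and the acceptance script

Training with the numpy engine is CPU-bound, so the end-to-end checks run at
reduced scale as the package's own validation design: a 72-subject
(24 positive / 48 negative) 64 px training cohort, 30 epochs, evaluated on
an independent 120-subject (40 positive / 80 negative) phantom pool drawn
from the same distribution under a different seed. The large held-out pool
keeps the AUC estimate's standard error small (~0.03) where a ~24-subject
fold would swing by ±0.08 from sampling alone. Measured held-out AUC is
0.92–0.96 across seeds (≈3 minutes per run on one CPU). Unit tests use
16–32 px cohorts of 6–16 subjects; the augmentation and fold-arithmetic
checks use the full 225-subject cohort shape (25 positive) at 64 px.
Full-scale 224 px five-fold training is supported by the same code paths
(`dmfnet cv`) but is a long CPU run.

## Numerical choices and edge cases

* float32 parameters/activations; the loss oracles are evaluated in float64
  by passing float64 arrays (the engine preserves input dtype).
* Sigmoid uses the two-sided stable form with inputs clipped at ±60.
* Crop rectangles are half-open, 0-based; degenerate or out-of-bounds crops
  raise. Grayscale images are replicated to 3 channels; images are resized
  bilinearly without antialiasing and without padding to square (aspect
  distortion accepted, as the crop convention keeps faces roughly square).
* Adaptive down-pooling in the MFFM requires the input grid to be a multiple
  of the target grid, which holds for input sizes divisible by 16.
* `compute_metrics` reports NaN for a metric whose denominator is zero and
  rejects all-zero confusion matrices; report rounding is half-even to two
  decimals.
* Random erasing fills with per-pixel uniform noise, area fraction 2–20%,
  aspect ratio 0.3–3.3, at probability 0.5 per image; colour jitter is ±20%
  in brightness/contrast/saturation (magnitudes are free choices).
* The offline multiplier *includes* the original (original + m−1 copies), so
  25→400 and 200→800 at multipliers 16/4.

## Known limitations

* No face detection or landmarking: crop boxes are data (manifest columns),
  defaulting to full frame.
* The phantom renderer is 2-D and schematic; it cannot probe robustness to
  photographic nuisance.
* Training at 224 px is slow on CPU; the engine is single-threaded numpy
  with im2col convolutions and has no GPU path.
* The complementarity hinge is inactive for embeddings initialised beyond
  the margin; its effect is mainly regularising during later training.
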