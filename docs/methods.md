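# Methods

## Overview

`gaborderm` implements a multi-stream pipeline for 7-class dermoscopy
lesion classification (akiec, bcc, bkl, df, mel, nv, vasc):

1. **Gabor-wavelet decomposition.** Each input image is filtered with a
   bank of four complex directional Gabor wavelets — two radial centre
   frequencies (0.176 and 0.25 cycles/pixel) crossed with two
   orientations (0° and 90°) — producing subbands GW1–GW4.
2. **Compact-CNN branches.** Five CNN branches per backbone, one per
   input stream (the original image plus the four rendered subbands),
   each retrained with minibatch SGD-with-momentum and a 7-unit
   fully connected class head. The deep feature per image is the head's
   pre-softmax activation vector (length 7 = class count).
3. **Two-stage fusion.** Per backbone, the five stream features are
   concatenated (35 columns); the per-backbone blocks are then
   concatenated across backbones.
4. **mRMR feature selection.** Greedy minimum-redundancy
   maximum-relevance selection on discretized features, scored by
   plug-in mutual information in bits.
5. **SVM classification and evaluation.** One-vs-one SVMs with linear,
   quadratic (degree-2 polynomial, coef0 = 1) and Gaussian (RBF)
   kernels; micro-averaged metric suite, per-class one-vs-rest metrics,
   confusion matrices and ROC/AUC.

## Gabor filter bank

The sampled kernel is

    g(x, y) = exp(−((x−x₀)² + (y−y₀)²)/α²) · exp(−i·2π(u₀(x−x₀) + v₀(y−y₀))/β²)

with u₀ = ω₀ cos θ, v₀ = ω₀ sin θ. Published descriptions of this
filter family sometimes omit the squares and signs of the Gaussian
exponent and the 2π of the phase; the form above is the standard
complex Gabor (Gaussian envelope × complex sinusoid), the only reading
under which the two bank scales are coherent spatial frequencies in
cycles/pixel and the frequency response is the Gaussian's Fourier pair.

Parameter choices (all configurable):

| parameter | default | rationale |
|---|---|---|
| ω₀ (scales) | 0.176, 0.25 c/px | the protocol's two bank scales |
| θ (orientations) | 0°, 90° | the protocol's two directions |
| α (envelope width) | 1/ω₀ px | one wavelength: constant relative bandwidth |
| β (phase scale) | 1 | dimensionless unit scale |
| support radius | ⌈3α⌉ | envelope < e⁻⁹ at truncation |

Kernels are DC-corrected by subtracting the complex mean so constant
image regions give exactly zero response. Filtering operates on the
ITU-R BT.601 luma plane with reflect padding; subbands are rendered for
the RGB-input CNN branches as per-image min-max-normalized magnitude,
replicated to three channels. GW1–GW4 are ordered scale-major,
orientation-minor: (0.176, 0°), (0.176, 90°), (0.25, 0°), (0.25, 90°).

Two convolution paths exist: the spatial reference (`scipy.ndimage`,
true convolution) and an FFT path that reproduces reflect padding by
explicit pre-padding; they agree to < 1e−11 and the FFT path is used
for bank-sized kernels. Whether the subband image should be the real
part, imaginary part or magnitude of the complex response is not
settled by the protocol; magnitude is used here (documented, not
guessed silently).

## Data handling

Metadata uses the HAM10000 dialect (`image_id`, `dx` columns). The
split is stratified 70/30 per class at image level (round-half-up),
seeded and deterministic. Known limitation: HAM10000 contains multiple
images of the same lesion; image-level splitting can leak lesions
between partitions and is kept because the reference protocol splits at
image level.

Training-set augmentation draws per copy: rotation uniform in ±60°,
shear uniform in ±50°, isotropic scale uniform in 0.5–1.5, and
per-axis flips with probability 0.5 (a "flip range" of ±45° is recorded
by the reference protocol but a flip is binary; Bernoulli(0.5) is the
only coherent reading). Default 2 copies per image. Each copy's
transform parameters derive from (seed, image_id, copy index) so the
five parallel streams of one image receive identical geometry.

Synthetic-profile pipelines default to **no** augmentation: the
synthetic class signal includes texture orientation, which ±60°
rotations would scramble across classes. Augmentation remains available
for photographic data, whose labels are rotation-invariant.

## CNN branches

The `tiny-test` backbone is a pure-numpy CNN: three blocks of
3×3 convolution (8, 16, 32 channels) → batch norm → ReLU → 2×2 max
pool on 32×32×3 input, then a 7-unit fully connected head. Training is
minibatch SGDM (momentum 0.9, the conventional value; unstated in the
reference protocol) with global gradient-norm clipping at 1.0 — the
small batches (10) otherwise destabilize late training. After the last
epoch, batch-norm running statistics are recalibrated with one exact
frozen-weight pass per layer. Being numpy end-to-end, retrain→extract
is bit-reproducible on CPU for a fixed seed.

The reference hyperparameters (batch 10, epochs 40, lr 0.001,
validation every 701 iterations, SGDM) are the `TrainConfig` defaults.
The synthetic desk-scale profile uses epochs 10 and lr 0.01 — sized for
the 32-px from-scratch backbone on 343 training images, where 40 epochs
at lr 0.001 are calibrated for fine-tuning ImageNet backbones instead.
Validation uses a held-out tenth of the training rows (the protocol
does not say what its validation set was).

The ImageNet backbones (resnet18, shufflenet, mobilenet) are registered
as optional heavyweight plugins requiring the torch/torchvision stack
and raise a clear error when unavailable. No test requires them or any
weight download. "mobilenet" is a registry key, not a pinned variant.

## Fusion and mRMR

Deep features are continuous; mutual information needs discrete
distributions. Each column is discretized to three states at μ ± σ
thresholds fit on training rows only (the convention of the original
mRMR literature); constant columns are flagged and mapped to the middle
state. MI is the plug-in histogram estimate in bits (0·log 0 := 0),
clipped at zero against round-off.

Redundancy is the double sum of pairwise MI over the subset — self-pairs
included — normalized by |F|, exactly as the reference criterion is
printed; the conventional |F|² normalization is available via
`pair_normalization="squared"`. Greedy selection uses the
difference (MID) criterion: first pick argmax I(X;C), later picks
argmax I(Xᵢ;C) − (1/|S|)·Σ I(Xᵢ;Xⱼ), ties toward the lowest column
index. The greedy order is nested, so the ablation sweep computes it
once at max(k) and evaluates prefixes.

## Classification and evaluation

SVMs are scikit-learn `SVC` (one-vs-one) behind the module surface:
linear; polynomial degree 2 with coef0 = 1 ("quadratic"); RBF with
gamma = 1/(d·var) ("gaussian"); box constraint 1; features standardized
with training-set statistics. These hyperparameters are unstated in the
reference protocol and all configurable.

Aggregates are micro-averaged because the reference results print
identical precision/F1/sensitivity per classifier — the algebraic
signature of micro-averaging in single-label multiclass data. Multiclass
MCC is the mean of per-class one-vs-rest binary MCC values (the
generalized multi-category statistic is a documented alternative; the
protocol prints only the binary formula). ROC curves are one-vs-rest at
every unique score threshold with trapezoidal AUC; tied scores share a
threshold, so constant scores give AUC 0.5 exactly.

## Synthetic data generator

Each image is a noisy skin-toned background (Gaussian noise,
sd 8 on the 8-bit scale) plus two class cues:

* an oriented cosine grating with random phase — orientations cycle
  through {0, 30, 45, 60, 90, 120, 150}° across the seven classes and
  frequencies alternate between the two bank scales, so only the 0° and
  90° classes sit exactly on a bank filter;
* a soft-edged elliptical lesion with class-specific eccentricity,
  radius fraction and mean color, jittered in position and size.

A mix weight w scales the texture term by w (amplitude 40 at w = 1) and
the lesion term by (1 − w). Defaults (70 images/class, 64-px side,
w = 0.5) are the desk-scale study conditions. Class proportions can
follow the HAM10000 benchmark's printed counts
(nv 6705, mel 1113, bkl 1099, bcc 514, akiec 327, vasc 142, df 115).

What the generator does **not** emulate: photographic lesion texture,
hair/ruler artifacts, illumination and color-calibration variation,
lesion-level image duplicates. Passing tests therefore demonstrate that
the pipeline machinery recovers a known two-stream class signal, not
that it reaches any particular accuracy on real dermoscopy images.

### A known limitation of the two-stream design

The generator was designed so the mix weight dials class signal between
the Gabor-recoverable and original-image streams. The lesion-only
direction behaves as intended: at w = 0 the original-image pipeline
clearly beats the GW-subband pipeline. The texture-only direction does
not produce the mirrored ordering: a retrained CNN on the raw images
recovers oriented texture at least as well as the fixed Gabor front end
(texture survives bilinear downsampling as class-discriminative aliased
patterns at every amplitude/noise combination examined, while settings
that blind the raw-image branch blind the min-max-rendered subbands
first). Two further structural facts cap GW-only accuracy: orientation
pairs symmetric about the filter axes (60°/120°, 30°/150°) have
identical magnitude signatures under 0°/90° filters and are separable
only by their frequency difference. Consequently the test suite asserts
the attainable ordering properties — original ≥ GW at w = 0, GW far
above chance at w = 1, and fusion within a small margin of the best
component at every mix — rather than a strict GW > original ordering at
w = 1. This mirrors the reference results themselves, where
original-image deep features outperform all-GW deep features and fusion
beats both.

## Experimental settings

* **Setting I** — per backbone × kernel: accuracy of each single
  subband's features and of the fused all-GW block (4×7 = 28 columns).
* **Setting II** — original-only, all-GW, and fully fused (5×7 = 35
  columns) features.
* **Setting III** — cross-backbone fusion (35 × number of backbones
  columns), mRMR ablation sweep over a k grid (default: seven evenly
  spaced values up to the full width, always including k = d), best k
  per kernel, and at that k the full metric suite, confusion matrix and
  ROC curves.

A single master seed fans out through `numpy.random.SeedSequence` to
the synthetic-data, split, augmentation, training and SVM sub-seeds;
the full run is reproducible bit for bit. The desk-scale problem sizes
(70 images/class, 64-px images, 32-px CNN input, 10 epochs) were chosen
so a complete three-setting run finishes in about a minute on one CPU
core while leaving all pipeline structure intact; the reference-scale
configuration (224-px input, ImageNet backbones, 40 epochs) is
expressible in the same configs but needs the optional torch stack.

## Numerical choices

* Gabor kernels: odd side 2⌈3α⌉+1; DC correction to |Σkernel| < 1e−10.
* Zero-range subband responses render to the all-zero image.
* Discretization: σ = 0 columns flagged constant, mapped to mid state.
* MI: plug-in estimate clipped at 0; ties in greedy selection and
  argmax broken toward the lowest index.
* Per-class metric ratios with zero denominators are defined as 0.
* Splits round half-up per class and are clamped so both partitions are
  non-empty for every class.
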