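# Methods

## Problem and model

The package classifies axial cross-sections of occluded peripheral
arteries into four tissue classes and aggregates them into a per-lesion
tissue score.  The classifier is *semi-supervised*: an unsupervised
convolutional variational autoencoder (VAE) learns a 2-D embedding of the
pseudo-color slices, and a small labelled subset is then used only to place
two axis-aligned thresholds that partition the latent plane into four
rectangular class regions.

The generative model is the standard VAE: each 64×64×3 image `x` (on the
[0, 1] intensity scale internally) is assumed generated from a latent
`z ∈ R^2` with prior `N(0, I)`; the encoder outputs a diagonal Gaussian
posterior `q(z|x) = N(mu(x), diag(exp(lv(x))))` and the decoder a
deterministic reconstruction `x_hat(z)` with sigmoid output.  The training
objective per image is

    L = mean((x - x_hat)^2)  +  beta * 0.5 * sum(exp(lv) + mu^2 - 1 - lv)

minimized with Adam.  Embeddings used for classification are the posterior
means `mu(x)` — sampling is used only during training — so classification
is deterministic given a fitted model.

## Architecture

Encoder: five stride-2 3×3 convolutions of strictly increasing depth
(spatial chain 64 → 32 → 16 → 8 → 4 → 2), a flat fully connected layer with
as many units as the flattened last convolution stage, then two linear
heads of the latent dimension (2) for the posterior mean and log-variance.
Decoder: a dense layer from the latent code back to the 2×2 feature map,
then five stride-2 transposed convolutions mirroring the encoder, sigmoid
output.  ReLU activations elsewhere.  The transposed convolution is
implemented as the exact adjoint of the strided convolution (col2im of the
weight-projected input), which is also how the convolution backward pass is
computed; the pair is verified as an adjoint identity in the tests.

All layers are plain numpy (float64, NHWC, im2col + matmul).  Gradients of
every layer are validated against central finite differences.

## Parameters that matter

| parameter | default (full) | desk preset | notes |
|---|---|---|---|
| encoder depths | 32, 64, 128, 256, 512 | 12, 24, 36, 48, 64 | five stages, strictly increasing |
| epochs | 500 | 80–100 | desk runs use the 50–100 range |
| batch size | 128 | 32 | smaller batches give a few-hundred-image cohort enough Adam steps per epoch |
| learning rate | 5e-4 (Adam) | 5e-4 | unchanged across presets |
| latent dim | 2 | 2 | configurable, but the partition assumes 2 |
| kl_weight (beta) | 1.0 | 1/(64·64·3) ≈ 8.14e-5 | see below |
| lv head init scale | 0.01 | 0.01 | keeps the initial posterior near unit width |

**KL weight.**  The reconstruction term is a *per-pixel mean* squared
error.  With `beta = 1/(side^2 · channels)` the objective is exactly
equivalent to the sum-form Gaussian ELBO at unit temperature; a beta of 1.0
on the mean-MSE scale over-weights the KL term by four orders of magnitude
and collapses the posterior.  The desk preset therefore uses the
ELBO-equivalent value; `kl_weight` remains configurable for annealing
experiments.

**Initialization.**  He-normal for convolutions and hidden dense layers.
The mean head uses Xavier scale: it is the only gradient path from the
loss into the encoder besides the log-variance head, and a tiny
initialization there measurably starves encoder learning.  The
log-variance head starts near zero weights so early training samples from
approximately unit-width posteriors.

## Preprocessing chain

Cohort normalization maps the pooled 1st/99th intensity percentiles of
each contrast to 0/255 (shared mapping across lesions of one contrast), a
percentile choice that makes the mapping robust to hot pixels.  Fusion
assigns T1w/T2w/UTE to R/G/B without resampling.  Axial MPR is axis-aligned
reslicing of the outlined volume at original in-plane resolution; voxels
outside the outline are blacked.  Each slice is cropped to the minimal
non-black bounding box, bilinearly resized to 64×64, and wall pixels with
packed 24-bit RGB in the inclusive interval `[0x800000, 0xff0000]` are set
to black.  "Removed" means *set to black*: the autoencoder needs dense
fixed-size input, and calcium is legitimately black, so removal preserves
geometry while deleting wall signal.  The interval is interpreted literally
(red ≥ 0x80 up to pure red); both bounds are parameters, because the
alternative reading "any red-dominant pixel" (`0x800000`–`0xffffff`) is
defensible — callers can choose, the default is never silently changed.

The same crop/resize/wall-strip tail is applied to synthetic phantom
slices before training, so the model always sees wall-stripped,
size-normalized input regardless of source.  This matters: with only two
latent dimensions, leaving the wall and the vessel's position/radius jitter
in the input wastes most of the latent capacity on nuisance geometry.

## Synthetic phantom generator

Each slice is a disc-shaped vessel (outer radius 0.38–0.45 of the frame,
small center jitter) with a red/pink wall annulus, a green lumen, and
class-dependent occlusion: none (class 1), 30–70 % of lumen area (class 2),
or >70 % (classes 3 and 4), drawn as 1–3 irregular blobs region-grown from
random interior seeds.  Class 3 occlusion is bright-blue soft tissue;
class 4 is dark-blue collagen with a grown calcium (black) sub-blob
covering 20–40 % of the occlusion.  Color prototypes: wall (200,120,120),
lumen (0,200,0), soft (60,60,230), collagen (20,20,90), calcium (0,0,0).
i.i.d. Gaussian channel noise (sd on the [0,1] scale) is added and clipped.
The generator records the exact lumen/occlusion/calcium masks, so a
pixel-counting oracle can recover every intended label on noise-free
stacks.

The "partially patent" (30–70 %) and "mostly occluded" (>70 %) cutoffs are
generator conventions, echoed in the stack metadata — the source taxonomy
never quantifies them.  What the phantoms deliberately do **not** model:
MRI physics (no TR/TE/flip-angle signal equations, no k-space), partial
volume and coil shading, registration misalignment, anatomical wall
irregularity, or multi-vessel fields of view.  Passing the end-to-end
tests therefore shows that the pipeline machinery — fusion, reslicing,
filtering, VAE optimization, latent partitioning, scoring — works and is
reproducible; it does not certify classification accuracy on patient data.

## Classification and calibration

The four rectangular regions are half-open (a coordinate equal to a
threshold falls on the upper side), so the partition tiles the plane
exactly — the mixed strict/non-strict inequalities in the source
description (and its duplicated class-3/class-4 condition) are resolved to
the unique 2×2 partition, with the quadrant-to-class assignment
configurable.  Reference thresholds (0.8, 0.8) are kept as documented
defaults; since each training run realizes its own latent geometry,
`calibrate_boundaries` grid-searches threshold candidates (quantile grid
per axis) crossed with all 24 quadrant-to-class assignments, maximizing
agreement on the labelled subset.

Tissue scores are fixed: class 1 → 0, 2 → 1, 3 → 3, 4 → 5.  The lesion
average is the exact mean of per-slice scores.  Percentages are reported
to one decimal (raw fractions retained); note that four independently
rounded percentages can sum to 100 ± 0.2 in adversarial cases.

## Problem sizes used in the shipped studies

The end-to-end recovery study trains on a 400-slice cohort (100 slices per
class, noise-free, 64×64) for 100 epochs with the desk preset, calibrates
on a stratified half and evaluates agreement on the held-out half, for
three fixed seeds; the package's own acceptance bar is ≥80 % held-out
agreement in at least two of three seeds.  Miniature configurations
(depths 4–12, a handful of epochs) are used where only plumbing or
determinism is under test.

## Numerical choices and edge cases

- float64 throughout the network; images are uint8 externally, [0, 1]
  float internally; decode rounds back to uint8.
- log-variance clipped to [−15, 15] inside the encoder to keep `exp`
  finite in pathological early steps; the closed-form KL used in losses
  and tests is unclipped.
- Epoch-level reshuffling; final partial batches are kept.
- All randomness (init, shuffling, reparameterization noise, phantom
  geometry) flows from explicit `numpy` generators seeded by config, so
  equal configs give bit-identical runs on one platform.  Across BLAS
  builds/platforms, floating-point reduction order may differ; exact
  determinism is only claimed within a platform.
- Resizing an image already at target size returns it unchanged
  (bit-exact); interpolation is bilinear, an artifact choice since the
  original toolchain's resampling kernel is not documented.
- Degenerate inputs are rejected with informative errors: empty ROI
  masks, constant-intensity contrasts (p1 = p99), fully-background images
  in autocrop, empty lesions in scoring, missing classes in calibration,
  stride/side combinations that do not reduce 64 → 2 evenly.

## Known limitations

- Rectangular, axis-aligned latent boundaries cannot separate classes
  whose latent clusters adjoin diagonally; class 2 ("partially patent")
  borders both class 1 and class 3 along a continuous occlusion-fraction
  manifold, and most residual end-to-end error sits on those borders.
  Nonlinear or higher-dimensional partitions are out of scope.
- The 2-D latent is a deliberate capacity bottleneck; cohorts with more
  tissue types would need a larger latent space and non-rectangular
  classification.
- Volume mode assumes co-registered inputs; registration quality is the
  caller's responsibility and misregistration degrades fusion silently.
- The numpy VAE is CPU-bound; full-scale settings (depths to 512,
  500 epochs, thousands of slices) are practical only with patience —
  the desk preset exists precisely to keep phantom studies in the
  minutes range.
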