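# Methods

## Problem setting

Pixel-level segmentation of diabetic-retinopathy lesions (microaneurysms MA,
hemorrhages HE, hard exudates EX, cotton-wool spots CWS) in color fundus
photographs faces two coupled difficulties. First, lesions are rare (typically
well under 5% of pixels) and resemble normal anatomy — exudates look like the
optic disc, hemorrhages like vessels — so context-free training produces false
positives. Second, fundus cameras differ enough in spectral response and
illumination that models transfer poorly across datasets. This package
implements the data-side answers to both: anatomical-context label maps that
make the confusable structures explicit background subclasses, and a
photometric augmentation that re-renders training images under the illuminant
statistics of other cameras. It deliberately does not implement or train the
segmentation network itself; losses and schedules are pure functions that any
training loop can consume.

## Image formation model and phantoms

All photometric reasoning assumes a von Kries world: a stored image is an
elementwise product of a scene reflectance field and a global RGB illuminant,
so changing the illuminant is a per-channel gain. The phantom generator
(`retinaug.phantom`) realizes this model literally — it builds a reflectance
field from the generating geometry, multiplies by a known unit-norm illuminant,
adds optional Gaussian noise (default σ = 0, reference sets use σ = 0.005 in
[0,1] intensity units), and clips to [0,1]. Because the model is exact, the
phantom's `true_illuminant` and `reflectance` fields are usable as oracles:
every illuminant-recovery and adaptation-round-trip test compares against
quantities computed directly from them.

Phantom geometry (defaults chosen to mimic the gross layout of a fundus
photograph at 128×128): a circular FOV at 0.92 of the half-size, an optic disc
of radius 0.16·R at 0.45·R temporal of center, a fovea of radius 0.12·R on the
opposite side, six vessels random-walking out of the disc, and lesion counts
{MA: 4, HE: 2, EX: 2, CWS: 1} with radii 1.5–4 px. Anatomy is rendered as
scalar luminance multiples of one base chromaticity (vessels 0.45×, fovea
0.70×, disc 1.70×), which keeps the reflectance chromaticity spatially uniform;
this is what makes all three global estimators provably recover
normalize(base ∘ illuminant) on lesion-free noise-free phantoms. Lesions carry
class-distinct absolute colors (dark red dots/blobs, bright yellow, pale gray).
No clinical realism is claimed: the phantoms exist to give exact ground truth,
not to look like disease.

Reference sets draw illuminants with a dominant red component (raw vectors
(1, U(0.40, 0.90), U(0.15, 0.65)), then unit-normalized) — the plausible tint
range of retinal imagery — so pools built from them exercise realistic
chromatic transfers.

## Illuminant estimation

Three global estimators operate on FOV pixels only (the black surround carries
no scene information and would bias every estimate toward zero):

- **Gray World**: unit-normalized per-channel mean.
- **Retinex / white patch**: unit-normalized per-channel upper percentile,
  default 0.99 rather than the strict max so a single saturated speck cannot
  dominate; the percentile uses the order statistic at one-based rank
  ⌈p·n⌉ and is configurable back to 1.0.
- **PCA bright/dark**: project pixels onto the mean color direction, keep the
  top and bottom fraction (default 3.5%, the canonical choice of the
  bright-and-dark-pixel method family), and take the dominant eigenvector of
  the selection's uncentred second-moment matrix, sign-fixed to nonnegative
  components.

All outputs are unit L2 vectors: downstream use only needs chromatic direction,
and magnitude is renormalized by the adaptation anyway. A pool is one row per
(reference image, estimator) pair in image-major order, with provenance, so
|pool| = n_refs × n_estimators always; any estimator failure aborts pool
construction by design — silently dropping rows would corrupt the sampling
distribution. Pools serialize to CSV with 17-significant-digit floats and are
read back with round-trip parsing, giving bit-exact persistence.

## Chromatic adaptation

The transfer from source illuminant s to target t is the diagonal gain
g_c = t_c / s_c applied to FOV pixels. Two policies matter:

- **Brightness preservation** (default on): gains are rescaled to mean 1, so
  augmentation changes tint, not exposure. With it off and no clipping, the
  transform is exactly invertible (round-trip error at machine precision; the
  tests bound it at 1e-6).
- **Clipping**: results are hard-clipped to [0,1]; the clipped FOV fraction is
  recorded on every augmentation and a warning is raised above 5%, because
  silent saturation breaks the von Kries covariance that downstream estimates
  rely on.

The source illuminant must be estimated from the image itself (a transfer
needs a denominator); the estimator is configurable, default Gray World.
Source components ≤ 1e-6 are rejected as degenerate. Adaptation acts on stored
intensities without sRGB linearization — a documented simplification.

The operational correctness statement for the whole augmentation is
*recoverability*: with brightness preservation off and clipping below 1%, the
gray-world estimate of the augmented image has cosine similarity > 0.99 to the
sampled pool target. This follows analytically from von Kries covariance and
is what the acceptance suite measures on 100 phantoms.

The geometric baseline (rotation U(−15°, +15°), horizontal flip with
probability 0.5, scale U(0.8, 1.2)) applies one sampled parameter set to image
(bilinear) and labels (nearest-neighbour — interpolation must never invent
class ids) about the exact image center, preserving canvas size and filling
uncovered regions with background. Centering at ((H−1)/2, (W−1)/2) makes a
180° rotation an exact involution on the pixel grid, which the tests exploit.

## Label algebra

Otsu thresholding maximizes between-class variance over a 256-bin histogram of
the red channel (highest surround/retina contrast in fundus imagery); ties
break toward the lowest qualifying bin, and the implementation is verified
against an exhaustive scan. FOV extraction then closes thin dark gaps with a
5×5 structuring element (vessels crossing the rim would otherwise cut
corridors into the disc), keeps the largest connected component and fills
holes; on phantoms this recovers ≥ 99% of the generator's mask.

Merging overlays lesion masks on an ANAT5 anatomy map re-coded into the
nine-class schema. Lesions dominate anatomy (a hemorrhage on a vessel is a
hemorrhage — exactly the confusion the context classes exist to resolve), and
among lesions the fixed precedence MA > CWS > HE > EX applies, ordered by
ascending typical size so small lesions are never absorbed by large ones. The
precedence is total, so input ordering never changes the result and the merge
is idempotent. Lesion pixels outside the anatomy's non-background region are
clipped and counted, not painted and not fatal.

## Losses

Cross-entropy is the standard negative log-likelihood, mean over all pixels,
with optional per-class weights (uniform, inverse-frequency normalized to mean
1, or median-frequency); predictions are clamped to [1e-12, 1] before the log.
The Tversky index uses the soft formulation with a smoothing constant
(default 1e-6) in numerator and denominator so classes absent from both maps
score 1 rather than 0/0. Defaults α = 0.7, β = 0.3 bias toward precision —
the second stage's purpose is false-positive suppression — and are exposed in
config, as are the schedule defaults (stage-1 epochs 300, stage-2 100,
learning rate 0.001, momentum 0.90, batch size 6). α, β and the class weights
are package choices, not published values.

## Metrics

Hard metrics derive one-vs-rest from a multi-class confusion matrix; 0/0
ratios are reported as 0 with an explicit per-class flag (rare lesions missing
from single images are routine, and silent NaNs would poison averages). Both
AUCs enumerate the distinct observed score values as thresholds — exact
curves, not a grid. AUC-ROC prepends the (0,0) sentinel and equals the
Mann–Whitney statistic on tie-free data (tested to 1e-12); ties are handled
correctly by collapsing equal scores into single thresholds, matching
scikit-learn. The PR curve's left endpoint extends the precision at the
highest threshold horizontally to recall 0 — a convention that must be fixed
for the first trapezoid to be defined. Reports macro-average the four lesion
classes separately from all classes, since the lesion mean is the quantity of
interest. `evaluate` pools pixels of the image it is given; bootstrap
intervals (percentile, default 10,000 resamples, seeded) operate on per-image
metric lists supplied by the caller.

## What the phantoms do and do not show

Passing tests establish that the algebra is exactly right under the package's
own image-formation model: illuminant recovery, adaptation invertibility,
merge precedence, metric identities. Real fundus images violate the model in
known ways — spatially varying illumination, sensor nonlinearity and gamma,
JPEG artifacts, annotation noise, lesion appearance far richer than colored
discs — so phantom results say nothing about clinical segmentation accuracy.
Benchmark performance requires real datasets and a trained network, both out
of scope here.

## Problem sizes

The test and acceptance runs use 48–128 px phantoms, 100-phantom recovery
batches, 113-reference pools, 1,000-mask identity checks and 100,000-draw
sampling checks — sizes at which every statistical assertion is comfortably
powered while the whole suite runs in seconds.
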