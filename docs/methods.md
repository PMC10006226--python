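# Methods

## Problem setting

The package quantifies nuclear chromatin texture from 2-D grayscale
histology patches. Input is a manifest of (image, binary mask, group
label, animal id) rows, one per nucleus ROI; the surround of each
nucleus is assumed cleared (as produced by ROI isolation in common
image tools), and no segmentation, stain normalization or color
deconvolution is performed. Output is a per-ROI table of nine texture
features, per-feature group statistics, and classifier reports.

## ROI preparation

RGB images are converted to 8-bit luminance with BT.601 weights
(0.299 R + 0.587 G + 0.114 B, rounded). Each ROI is cropped to the
mask's bounding box (0-based, half-open intervals). Gray levels for
co-occurrence analysis are quantized per ROI to G levels
(G ∈ {8,…,256}, default 64) with one of three strategies:

* `minmax` (default): the masked-in min→0 and max→G−1, linear in
  between; a constant ROI maps to 0. This makes features invariant to
  per-ROI brightness and contrast, the behavior expected from
  dynamic-range normalization in legacy texture tools.
* `bitshift`: drop the low bits of the 8-bit value (global scale,
  comparable across ROIs).
* `sigma3`: clip to mean ± 3 SD of masked-in pixels, then min-max
  stretch — robust to isolated extreme pixels.

All strategies are monotone non-decreasing in intensity. Whether the
source data were normalized per ROI or per image is generally unknown
for published datasets, so the strategy is a configuration choice, and
sensitivity of the features to it should be checked when comparing to
numbers produced by other software (absolute GLCM feature values are
notoriously settings-dependent).

## Co-occurrence features

For displacement (dy, dx) — distance d = 1 at angles {0°, 45°, 90°,
135°} by default — co-occurrences are counted over all pixel pairs with
*both* endpoints inside the mask, in both orders (symmetric matrix),
then normalized. Pairs that cross the mask boundary are discarded
entirely so cleared background never contaminates the estimate. A ROI
too thin to contain any pair for a requested offset is an error naming
the offset.

The six features (ASM, IDM, CON, COR, SA, SVAR; formulas in the README)
are computed per angle and averaged arithmetically, which gives one
rotation-robust value per ROI; per-angle values remain available by
disabling `direction_averaging`. The contrast exponents (k, n) default
to the classical (2, 1) but are configurable. On a degenerate matrix
(σx·σy = 0, e.g. a constant ROI) the correlation is undefined and is
reported as NaN; group statistics exclude and count such values rather
than failing. SA ranges over [0, 2(G−1)] and, like SVAR, is computed
from the gray-level sum distribution p_{x+y}.

## Wavelet energies

A single-level orthonormal Haar analysis is applied to non-overlapping
2×2 blocks [[a,b],[c,d]] of the *raw* 8-bit patch (quantization is a
co-occurrence-specific step; a switch allows using quantized levels):
LL=(a+b+c+d)/2, LH=(a−b+c−d)/2, HL=(a+b−c−d)/2, HH=(a−b−c+d)/2. The
first subband letter denotes the filter along y (rows), the second
along x (columns): LH responds to variation along x, HL along y, HH to
diagonal structure. This convention differs between tools and is
therefore stated explicitly. Orthonormality gives Parseval's identity
(Σ pixel² = Σ coefficient²), which the tests verify to 1e-9 relative.

Masked-out pixels are filled with the rounded mean of masked-in pixels
before the transform, and odd dimensions are padded by edge
replication; a coefficient is included in the energy sum iff its 2×2
support contains at least one masked-in pixel. The energy divisor n is
the number of included coefficients (per-coefficient mean energy); a
config switch substitutes the ROI pixel count, which divides all
energies by ≈4. The fill-plus-overlap rule is an explicit approximation
— boundary coefficients mix real and filled pixels, slightly damping
boundary detail. Detail energies are exactly invariant to adding an
integer constant to all intensities and scale as c² under intensity
scaling by c; both are tested.

## Synthetic nucleus population

The generator emulates the statistical structure of a two-class
(control vs injured) nuclear ROI study: elliptical masks of random size
and orientation on a white (255) cleared background, 700 ROIs per class
from 7 "animals" per class (100 each, round-robin), fully reproducible
from (config, seed).

Interior texture is built from four ingredients:

1. a smooth chromatin field — Gaussian white noise blurred with a
   Gaussian kernel (radius `smoothness` = 3 px) and rescaled to SD
   `base_amplitude` = 12 around `base_mean` = 132;
2. bright "euchromatin pools" — a Poisson(5) number of saturating
   Gaussian-profile blobs (+45 at the plateau), identical in both
   classes;
3. dark chromatin clumps — saturating blobs of bounded depth (−90),
   Poisson(14) in the injured class and absent in controls, emulating
   chromatin condensation/margination;
4. i.i.d. pixel noise, SD 3 (control) vs 7 (injured), plus a small
   global mean shift (+5) in the injured class.

Blob profiles saturate (the summed Gaussian profile is capped before
scaling) so condensed or cleared chromatin approaches a bounded optical
density; clump cores are flat plateaus, not unbounded dark spikes.
This is deliberate: with per-ROI min-max quantization, a texture
feature sees only the *shape* of the intensity distribution relative to
its range. Unbounded dark spikes extend the range as fast as they add
variance, leaving the sum statistics unchanged; bounded clumps create a
genuine second intensity mode, which raises sum variance, and the
bright pools hold the control mean below mid-range so that the injured
class's extended dark tail raises the sum average. The defaults were
chosen (by simulation across several seeds, before being frozen) so
that the generator delivers its contract: ASM and IDM higher in
controls; CON, SA, SVAR and the three detail energies higher in the
injured class, each at Mann–Whitney p < 0.01 with 100 ROIs per class.
The direction of the correlation feature is deliberately left
unconstrained. A `null_variant()` configuration equalizes the classes
for negative controls.

What the generator does **not** emulate: H&E color and staining
variability, absolute feature scales of real nuclei (e.g. real
chromatin is spatially correlated, so its detail-energy spectrum falls
off steeply from LH/HL to HH, whereas i.i.d. noise feeds all three
bands equally), per-animal heterogeneity (ROIs within an animal are
i.i.d. here), nucleoli, overlapping nuclei, or imaging artifacts.
Passing tests on this population therefore validate the *machinery*
(feature definitions, masking semantics, statistics, classifiers) and
the qualitative class contrast, not performance on real micrographs.

## Statistics and classification

Per feature: mean and SD (n−1 denominator) per group, and the two-sided
Mann–Whitney U — exact enumeration when both groups have ≤ 12
observations and no ties, otherwise the tie-corrected normal
approximation with continuity correction. Raw p-values are reported
unadjusted (matching common practice in this literature), with a
Holm-adjusted column alongside for transparency. ROIs are treated as
independent observations; with ~100 ROIs per animal this
pseudo-replicates, which is acknowledged rather than corrected — the
animal id is retained in every table for users who want a hierarchical
reanalysis.

Classification uses the nine-feature vector with a stratified 80/20
train/test split at a fixed seed. Features are standardized by
training-set mean/SD only; NaNs are imputed by the training-set median.
Models: binomial logistic regression (C = 1), RBF-kernel SVM (C = 1,
γ = "scale", ranked by its continuous decision margin), and a
100-tree random forest (ranked by class probability). ROC curves come
from a threshold sweep with ties grouped; AUC is the trapezoidal area,
which equals the rank-statistic identity U/(n₁n₂) (tested to 1e-12).
A single binary rater has one operating point; its AUC is the area of
the two-segment ROC through it, (sensitivity + specificity)/2. A single
seeded split is reported (repeat with different seeds for a spread);
there is no hyperparameter search by design — these are baseline
reference models, not tuned ones.

## Numerical and design notes

* Gray levels are 0-based; co-occurrence marginals and p_{x+y} are
  exact sums over the normalized matrix (no sampling).
* Matrix normalization is validated to 1e-12; features of symmetric
  matrices are invariant to transposition.
* Degenerate inputs: ROIs need ≥ 8 masked-in pixels and a ≥ 2×2
  bounding box; classifier training needs ≥ 20 ROIs per class.
* The pipeline communicates between stages only via files (manifest,
  CSV, JSON), so real micrographs can replace the simulation at the
  feature stage unchanged. Each run directory records the SHA-256 hash
  of the serialized configuration in `run_info.json` and the run log;
  outputs keep fixed names so stages chain simply.
* Reported checks use these problem sizes: oracle equivalence on 50
  random 16×16 masked patches; Parseval on 100 random patches; noise
  monotonicity on 200 replicate nuclei at each of four noise levels;
  direction recovery at 100 ROIs per class; classifier sanity and the
  null-configuration chance check at 700 ROIs per class.

## Known limitations

* Only the six listed GLCM features and three level-1 detail energies
  are computed; other Haralick features, multi-scale energies and the
  LL energy are out of scope.
* Absolute feature values depend on quantization policy and offset
  configuration; compare numbers across tools only with identical
  settings.
* The masked-ROI coefficient-inclusion rule for the wavelet transform
  is an approximation near the boundary (see above).
* The synthetic population is a stand-in, not a simulation of kidney
  histology; claims about real-data classifier performance cannot be
  made from it.
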