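# Methods

This note records the models, parameter choices and numerical conventions
behind `lesionpipe`, and what the synthetic phantom suite does and does
not demonstrate.

## Contrast stretching

Each RGB channel is tiled into `grid_rows × grid_cols` blocks (3×4 = 12 by
default, so each block covers ≈ 8.3% of the image; remainder pixels are
absorbed into the last row/column so the rectangles always tile exactly).
Two per-block weights are computed:

* **Quartile coefficient ς.** The 3×3 Sobel gradient magnitude is summed
  per block; the 25/50/75-percentiles of the twelve sums define thresholds
  T₁ ≤ T₂ ≤ T₃, and blocks map to ς ∈ {0.25, 0.5, 0.75, 1.0} by ascending
  quartile. The coefficients are fixed, monotone in gradient, and spread
  the four intervals evenly over the observed gradient distribution.
* **Edge weight B_w = E_p / max E_p.** E_p counts Laplacian-of-Gaussian
  (σ = 2) zero-crossing pixels per block. A zero crossing is a sign change
  against the right or lower neighbour whose local response magnitude
  exceeds 10⁻⁴ of the image maximum — raw zero-crossing sets are dominated
  by numerical noise otherwise. If no block has any edge, every B_w is 1.

The combined gain g = ς·B_w is applied to the *deviation from the channel
mean*: `adjusted = rescale01(mean + g·(v − mean)) · 255`. Applying the
gain to raw intensities instead multiplies low-detail blocks toward
black; on low-contrast lesions that inverts the lesion/skin brightness
ordering and destroys the downstream hypo-intensity polarity rule, so the
deviation form is used. Within any block the map remains monotone
non-decreasing in input intensity, a constant image maps to a constant,
and the output always spans at most [0, 255].

The final stretch is φ(t) = C·log(β + v) with β = 3 (β ≤ 10; 3 gives the
strongest dark-range expansion without saturating) and C = 255/log(β+255)
fixed so the brightest value maps to 255; the output floor is
255·log β / log(β + 255) ≈ 50.4 for β = 3.

## Segmentation

Segmentation operates on the BT.601 luminance (0.299 R + 0.587 G +
0.114 B) of the enhanced image — the per-pixel activation needs a single
gray channel and luminance is the standard reduction.

Two statistics drive the two segmenters:

* uniform-distribution mean μ = (min + max)/2 of the enhanced gray range;
* normal mean absolute deviation M.D = 0.7979 σ (σ·√(2/π); σ is the
  *population* standard deviation). The constant is kept at the 4-decimal
  value 0.7979 so the `md/sigma` ratio is exact by construction; a 10⁶-draw
  Monte-Carlo check recovers it within 0.5%.

The activation A(v) = 1/(1 + stat/v)^α + 1/(2·stat) + C is strictly
increasing in v for fixed stat, so it is a monotone re-parameterization
of intensity whose histogram geometry the statistic controls. α = 7
(integer, ≤ 10). C is nominally random in [0, 1] but is fixed at 0.5: the
two additive terms shift the map uniformly and therefore provably cannot
change the Otsu partition (asserted in the tests), so a random C only
breaks reproducibility. Zero pixels are shifted by 10⁻⁶ before the
division; enhanced images have a positive floor anyway.

The map is min-max normalized to [0, 1] and thresholded by an in-package
Otsu implementation: 256 equal bins, bin-center threshold maximizing the
between-class variance, ties broken toward the lower bin (first argmax).
Mask polarity is then fixed so foreground is the class with the lower
mean enhanced intensity — dermoscopic lesions are hypo-intense, and the
threshold alone does not determine which side is lesion. A bright lesion
on dark skin is consequently missed by design; a constant image yields an
empty mask flagged as degenerate.

## Fusion and mask metrics

The mean-based and M.D-based masks are combined per pixel by logical OR
(union; equivalently the additive law P(X₁∪X₂) = P(X₁) + P(X₂) − P(∩)
on binary indicators). Post-processing — keep the largest 8-connected
component, fill interior holes — is ON for end-to-end runs and OFF in the
unit tests of the raw operators.

Mask agreement is reported as pixel accuracy in percent (the "similarity
rate"), Dice and Jaccard; Dice and Jaccard are defined as 1 when both
masks are empty, and the identity d = 2j/(1 + j) is asserted on random
pairs.

## Features

`crop_and_resize` crops the mask bounding box with a 10% margin, zeroes
background pixels and resizes to the 64×128 HOG window.

* **HOG** (scikit-image): 9 unsigned orientation bins, 8×8-pixel cells,
  2×2-cell blocks, 8-pixel stride, L2-Hys. The 64×128 window yields
  7×15 blocks × 36 = 3780 values. Reduction to 200 columns scores each
  column by W_f × H_f where W_f is the PCA importance (sum over
  components of |loading| × explained-variance share, min-max normalized
  to [0, 1]; full SVD, deterministic) and H_f is the base-2 Shannon
  entropy of the column's 16-bin histogram. The top 200 indices (ties to
  the lower index) are frozen at fit time and reused at prediction.
* **Haralick texture**: intensities inside the mask bounding box are
  min-max quantized to 32 levels; symmetric normalized GLCMs at distance
  1 for offsets 0°/45°/90°/135° (scikit-image `graycomatrix`). Fourteen
  statistics per offset — autocorrelation, contrast, cluster prominence,
  cluster shade, dissimilarity, energy (= angular second moment),
  entropy (base 2), homogeneity 1 (inverse difference), homogeneity 2
  (inverse difference moment), maximum probability, average, variance,
  inverse difference normalized, inverse difference moment normalized —
  with gray-level indices 1-based in the weighted sums. The output is,
  per statistic, its (mean, range, population variance) across the four
  offsets: 14 × 3 = 42 values in the order of the CSV header
  (`tex_autocorr_mean`, `tex_autocorr_range`, …).
* **Color moments**: mean, population variance, skewness and *excess*
  kurtosis of the lesion pixels (mask only) in each channel of RGB
  (0–255 scale), HSI (I = (R+G+B)/3, S = 1 − 3·min/(R+G+B), H by the
  arccos formula scaled to [0, 1]) and CIELAB (sRGB, D65, scikit-image).
  Higher moments are defined as 0 when the channel variance vanishes up
  to conversion round-off (≤ 10⁻¹⁸·(1 + mean²)).

**Parallel fusion** zero-pads texture and color to the HOG length: fused
position k is |h + i·t| + |h + i·c| = √(h² + t²) + √(h² + c²), a single
non-negative real vector of length 200 as the selector requires.

## Selection

Unsupervised, a pure function of the training matrix. Per column:
closeness = mean Bhattacharyya distance over the adjacent column pairs
containing it (columns normalized to sum 1 across samples; all-zero →
uniform; the Bhattacharyya coefficient is clamped to [10⁻¹², 1] so
disjoint supports give the finite cap −ln 10⁻¹²); a variance term
ln(m + σ² + ε) / (|ln(m + σ² + ε)| + |ln(|m − σ²| + ε)|) with ε = 10⁻⁹
guarding non-positive logs; and the base-2 entropy of the column's
16-bin histogram. The score is the product closeness × |variance term| ×
entropy; the 172 highest-scoring indices (ties to the lower index) are
frozen. 172 is a configuration constant — no stopping rule is attached
to it. Constant columns have zero entropy and are never preferred over
informative ones.

## Classification and evaluation

One binary SVC (linear kernel, C = 1) per class on z-scored features,
prediction by argmax decision value with ties to the earlier class in
sorted label order. Linear C = 1 is the plain one-against-all baseline;
kernelized variants are comparison classifiers, not the base machine.
Protocols: stratified 50:50 holdout or stratified 10-fold CV with a fixed
seed; the composite `LesionClassifier` refits HOG reduction, selection
and scaling inside each training fold, so the evaluation is leakage-free
(a constructed probe in the tests shows train-only vs all-data selection
produce different kept sets).

Report arithmetic: per-class sensitivity = diag/row-sum, accuracy =
trace/total, specificity and precision macro-averaged (classes with empty
rows/columns excluded with a warning), FNR = 100 − sensitivity in
percent, FPR = 1 − specificity/100 as a fraction, and macro one-vs-rest
ROC AUC from the decision scores.

## Synthetic phantoms

The generator emulates the statistical structure of dermoscopic archive
images: a warm skin background (RGB ≈ (205, 160, 140) with per-sample
jitter), a zero-mean linear illumination gradient (amplitude 25 gray
levels), Gaussian sensor noise (σ = 5), an exactly rasterized star-convex
lesion r(θ) = r₀(1 + a·Σ₂⁵ sinusoids) covering 5–40% of the frame, and —
with probability 0.3 — one to three dark anti-aliased hair strokes. Class
effect sizes: base gray intensity 40/90/140 (± 10) and border
irregularity a = 0.35/0.20/0.08 for melanoma/atypical/benign, with
smooth per-channel variegation of σ = 18/10/5. The intensity gaps and
irregularity amplitudes follow the ordering melanoma < atypical < benign
(darkness) and melanoma > atypical > benign (irregularity); variegation,
illumination, noise and hair parameters were fixed once at values that
make the classes separable but overlapping. A single mild Gaussian blur
(σ = 0.8) blends the lesion boundary into the background; the mask
remains the exact pre-blur rasterization, so segmentation scores are pure
algorithm measurements with no annotation noise.

What the phantoms do **not** model: real skin micro-texture, specular
reflections, gel bubbles, rulers and color charts, multi-focal or
non-star-convex lesions, and the intra-class diversity of real archives.
Passing the synthetic benchmarks therefore demonstrates internal
correctness and end-to-end separability under controlled conditions, not
clinical performance.

## Problem sizes and observed behaviour

The segmentation benchmark uses 100 phantoms (median fused Dice ≈ 0.997
at seed 0; the occasional low-contrast benign phantom fails, which the
median absorbs). The classification benchmark uses 50 phantoms per class
under the 50:50 protocol (accuracy 94.7%, AUC 0.96 at seed 0). Across
other seeds the end-to-end accuracy spans roughly 83–93%: the fixed
fusion formula adds texture and color contributions at the 36 overlapping
positions, so large-magnitude texture statistics (cluster prominence is
O(10⁵)) partially mask the color-moment signal — a color-moments-only
baseline reaches ≈ 99% on the same phantoms. This is a known limitation
of the fused representation, retained deliberately; per-block
standardization before fusion was tried and rejected because the
magnitude operation then discards the sign of the deviation and accuracy
collapses.

## Numerical conventions

* Variances are population (1/N) throughout, matching the skewness and
  kurtosis definitions.
* All tie-breaks (Otsu bin, feature ranking) resolve toward the lower
  index, making every fit a pure deterministic function of its input.
* Degenerate inputs: constant images yield empty masks (logged); empty
  masks propagate as skipped samples in the pipeline report; constant
  feature columns receive zero entropy.
* Images are float [0, 255] internally; masks are {0, 1} uint8 in memory
  and {0, 255} 8-bit PNG on disk.
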