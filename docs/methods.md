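# Methods

This note documents the models and procedures implemented in `sonoquant`,
the defaults that matter, the numerical choices, and what the synthetic
phantoms do and do not establish about clinical data.

## Quantization-assisted lesion refinement

Breast lesions in B-mode ultrasound are hypoechoic: darker than the
surrounding tissue. When a segmentation backend produces a mask that "needs
reconsideration", the refinement path replaces it with a two-step isolation:

1. **Multilevel Otsu quantization.** The image histogram (256 equal-width
   bins on [0, 1]) is split by the 1×n threshold vector maximizing
   between-class variance, equivalently Σ&#8342; w&#8342;·μ&#8342;² over classes. For n ≤ 2
   the search is an exhaustive vectorized scan over all threshold placements
   (ties broken toward the lexicographically smallest set, i.e. the first
   maximizer in scan order); for n ≥ 3 an exact boundary dynamic program
   over (class count × bin) states finds the same optimum in O(n·B²). The
   returned thresholds are upper bin edges, so they are strictly ascending
   and lie in (0, 1). Images with fewer than n+1 distinct values (or
   occupied bins) raise a degenerate-input error naming the observed count.
   Quantization assigns label(p) = index of the half-open bin
   [0,t₁), [t₁,t₂), …, [tₙ,1] containing p.

2. **Tumor-level selection.** The tumor level is the quantization level of
   lowest mean intensity (overridable; with a coarse mask present, the level
   of maximal IoU with it). Its 8-connected components are scored —
   `0.5·overlap(IoU) + 0.25·circularity + 0.25·relative area` when a coarse
   mask exists, `0.5·darkness + 0.5·relative area` otherwise — filtered by
   `min_area` (default 20 px) and the circularity/roundness ranges, and the
   winner is returned with holes filled. Nothing passing `min_area` yields
   an all-zero mask with a logged warning.

**Trigger rule.** The coarse mask is reconsidered when it is empty, its area
is below 0.1 % of the image, or its union solidity (foreground area over the
convex-hull area of *all* foreground pixels) is below 0.5. Union solidity is
deliberate: a fragmented guess whose pieces are individually solid still
scores low. Decisions are logged per image. When the trigger does not fire
the coarse mask passes through unchanged, so refinement can never degrade an
accepted mask.

**Pre-smoothing.** Speckle makes raw histograms multimodal at the noise
scale, so the quantization path first smooths with a truncated Gaussian
(σ = 1.5 by default; 0 disables). This is standard denoise-before-threshold
practice and is exposed as a parameter.

**Shape descriptors.** Circularity is 4πA/P² and roundness 4A/(π·major²),
both clamped to [0, 1]. The perimeter P uses the weighted
boundary-configuration estimator from `skimage.regionprops` rather than a
raw boundary-pixel count: pixel counting overestimates diagonal contour
length by up to √2, enough that a perfect rasterized disk would score
circularity ≈ 0.62 and the smooth/irregular distinction would be badly
compressed.

## ICA sparse filters and SUN saliency

Bottom-up saliency here follows the natural-statistics view: a pixel is
salient when its local feature response is improbable under the statistics
the filters were trained on, i.e. saliency = P(F)⁻¹.

- **Patches.** `patch_size` 11 (odd, so a center pixel exists), training
  stride 4, mapping stride 1, at most 50 000 training patches subsampled
  with a fixed seed. Each patch has its own mean removed — the grayscale
  analogue of channel-mean subtraction, and the reason saliency is exactly
  invariant to adding a constant to the image. Responses are defined on
  these mean-subtracted patches with no further centering, so a constant
  patch responds exactly zero.
- **PCA.** The single leading eigen-component (`drop_top` = 1) is excluded —
  after per-patch mean removal it is dominated by residual low-frequency
  luminance structure — then enough of the remaining components to reach
  95 % of the remaining variance are kept, capped at `k`.
- **ICA.** Fixed-point FastICA (seeded) in the reduced space yields `k` = 32
  unit-norm filters by default; non-convergence within `max_iter` = 500
  iterations is an error carrying the iteration count, and a reduced space
  that supports fewer than `k` filters logs a warning and proceeds with the
  supported number.
- **GGD response model.** Each filter's training responses are fit by a
  zero-mean generalized Gaussian P(f) = β/(2sΓ(1/β))·exp(−|f/s|^β) via
  moment matching: the shape β solves Γ(5/β)Γ(1/β)/Γ(3/β)² = sample
  kurtosis by bisection (kurtosis is strictly decreasing in β), clamped to
  [0.3, 4]; the scale follows from the variance,
  s = √(var·Γ(1/β)/Γ(3/β)). Moment matching is biased by a few percent at
  n = 10 000 (the acceptance script measures ≈ 2–4 % relative error), well
  inside the 10 % recovery tolerance the tests assert.
- **Saliency map.** −log P(F) = Σ&#8344; −log P(f&#8344;) is computed at every patch
  center (stride 1), edge-padded to image size, and shifted so its minimum
  is zero. The log domain is kept throughout: P(F)⁻¹ itself overflows for
  rare patches.
- **Feature vector f₁.** k mean absolute responses over patch centers inside
  the lesion mask, plus the mean of the log-saliency over those centers
  shifted by the *region* minimum (not the global one), then L2-normalized.
  Pooling region-locally makes f₁ depend only on the lesion neighbourhood
  (mask dilated by the patch radius) and makes a constant region yield the
  zero vector, which is returned with a warning instead of being normalized.
  A mask lying entirely within the border ring falls back to whole-image
  pooling; an empty mask is an error directing the caller to pool over the
  whole image explicitly.

## Serial fusion, the deep backend contract, and the lasso model

Serial fusion is concatenation: α = (f₁ ‖ f₂) with dim(α) = n + m. Each
block is min–max scaled to [0, 1] using statistics of the training split
only; the scaler stores them so the unscaled parts are exactly recoverable
and test-time data reuses the training ranges. Scaling precedes fusion so
neither block dominates kernel distances.

The deep-feature backend is a contract — `(image, mask) → fixed-length
vector`, deterministic in its inputs and seed — plus a stub implementation:
a 16-bin masked intensity histogram, the seven log-magnitude Hu moments of
the masked intensity image, and four contour descriptors (area fraction,
circularity, roundness, solidity). That 27-dimensional base is the default;
when a caller requests a larger fixed `dim` (to mirror a real network's
output width) the base is padded by a seeded random projection of itself.
The padding carries no new information and is off by default.

The lasso-binomial model minimizes mean deviance + λ‖w‖₁ (the glmnet
parametrization; internally mapped to liblinear's C = 1/(nλ) coordinate
descent). The grid descends log-uniformly over 4 decades from
λ_max = max|Xᵀ(y−ȳ)|/n, the smallest λ that zeroes every coefficient; λ is
chosen by mean held-out deviance over a seeded stratified internal CV
(5 folds by default, reduced when a class is small). All-zero coefficients
at the chosen λ log a warning and leave an intercept-only model.

## Segmentation losses and overlap metrics

With L_FP the predicted foreground probability, L_BP = 1 − L_FP, and
L_FR/L_BR the true masks:

- **Dice (standard).** 1 − ½[(2ΣL_FP·L_FR+ε)/(ΣL_FP+ΣL_FR+ε) +
  (2ΣL_BP·L_BR+ε)/(ΣL_BP+ΣL_BR+ε)] — bounded in [0, 1], zero at perfect
  overlap (within ε), symmetric under simultaneous class swap. A
  `literal` mode keeps an alternative formulation seen in the
  literature that omits the
  factor 2 and uses the background denominator Σ(2−L_FP+L_FR)+ε; it does not
  vanish at perfect overlap and exists for comparison only.
- **Focal.** Mean over pixels of −(1−p&#8348;)^γ·log p&#8348; with p&#8348; the predicted
  probability of the true class, predictions clipped to [10⁻⁷, 1−10⁻⁷];
  γ = 0 is exactly binary cross-entropy. Defaults γ = 2, ε = 10⁻⁶, w_t = 1
  (total loss = dice + w_t·focal); losses are means over pixels so values
  are image-size invariant.
- **Mean-IoU / Mean-F_β.** Per-image, averaged. Empty∪empty counts as
  IoU 1 and F 1; an empty prediction against a non-empty truth is F 0.
  β² = w_t, so w_t = 1 gives F1 and the binary-mask identity
  F1 = 2·IoU/(1+IoU) holds to machine precision.

## Classifier evaluation

Folds are seeded stratified partitions (per-fold class counts within one of
perfect stratification). Out-of-fold predictions across all k folds are
pooled into a single 2×2 confusion matrix per method — so the matrix total
equals the cohort size — and metrics are computed once from it: accuracy,
precision/recall/F1 for the positive class, and Cohen's kappa
(p_o − p_e)/(1 − p_e) with p_e from the row/column marginals. Benign is the
positive class; published benchmark tables in this domain are only
reproducible under that convention, which the test suite verifies cell by
cell. Values are ×100 and rounded half-up to two decimals; zero denominators
report 0 with a `degenerate` flag rather than NaN.

Classifier kinds mirror the common MATLAB-toolbox set: cubic and quadratic
polynomial SVMs (standardized inputs, C = 1, coef0 = 1), a medium decision
tree (≤ 20 leaves), bagged trees, a random-undersampling boost (seeded
balanced undersample of the majority class, then AdaBoost on depth-2 trees
— written in-package since no undersampling-ensemble library is available),
and the lasso-binomial model. None of these hyperparameters are canonical;
all are exposed.

## Phantom generator

Each phantom is one star-convex lesion on a speckled background:

- **Boundary.** r(θ) = r₀·e(θ)·clip(1 + irregularity·P(θ), ≥ 0.2), where e
  is an ellipse factor (seeded orientation, aspect 0.55–0.98) and P a
  band-limited perturbation (harmonics 2–6, 1/h-weighted seeded
  coefficients, normalized to max |P| = 1). The mask is the exact polygon
  rasterization, so mask area matches the shoelace area within a
  perimeter's worth of pixels. Lesions spilling outside the frame are
  re-centered with a logged warning.
- **Intensity.** Background level ~ U(0.5, 0.65); the lesion interior sits
  a negative offset below it (hypoechoic). Speckle is multiplicative
  gamma noise with shape `looks` (default 16) and unit mean — the fully
  developed speckle approximation for B-mode intensity, variance 1/looks —
  and the product is clipped to [0, 1].
- **Classes.** Benign: irregularity U(0, 0.08), offset U(−0.28, −0.20),
  aspect U(0.75, 0.98). Malignant: irregularity U(lo, lo+0.12) with
  lo = 0.10 + 0.40·(1−difficulty), offset shifted darker by
  0.18·(1−difficulty), aspect U(0.55, 0.85). The two class gaps — boundary
  roughness and echogenicity — shrink linearly with `difficulty`;
  at difficulty 0 the classes are trivially separable, at 1 they nearly
  abut. The default cohort is 437 benign / 210 malignant; the quality-bound
  checks use 200/100 at difficulty 0.3 and 128×128 images, sizes chosen so
  the full property suite runs comfortably on one CPU.

**What the phantoms do not emulate:** acoustic shadowing and posterior
enhancement, depth-dependent attenuation and focus, tissue texture other
than stationary speckle, multiple or absent lesions, and annotation noise in
ground-truth masks. Passing the pipeline bounds on phantoms shows the
machinery is correct and self-consistent — it does not certify clinical
accuracy, and the published real-data accuracies of trained deep networks
are out of reach by construction (no datasets, no trained weights). The
metric arithmetic, by contrast, is claimed exactly and verified against
published confusion-matrix/metric-row pairs.

## Numerical and degenerate-input choices

- Images are float64 in [0, 1]; 8-bit files are divided by 255 on read and
  rounded half-up on write. Color inputs collapse to grayscale by channel
  averaging. Coordinates are 0-based (row, col).
- Nearest-neighbour resizing uses center-aligned source coordinates rounded
  by INT(a + 0.5); it introduces no new intensity values.
- The Gaussian kernel is truncated at radius ⌈3σ⌉ and renormalized; reflect
  boundary handling preserves the image mean to 10⁻⁹.
- Histogram equalization maps each pixel to the empirical CDF of its bin
  (256 bins by default); constant images return unchanged with a warning.
- Otsu ties break toward the smallest threshold set; the DP breaks ties
  toward the smallest boundary at each stage.
- GGD β is clamped to [0.3, 4]; zero-variance responses get β = 2 with a
  vanishing scale.
- Augmentation defaults are conservative (|shift| ≤ 0.0625 of size, scale
  0.9–1.1, rotation ≤ 15°) and a seed fully determines the sampled
  transform; masks are warped nearest-neighbour so they stay binary.

## Known limitations

- The refinement assumes one dominant hypoechoic lesion; multifocal disease
  would need the component scorer to return several candidates.
- Moment-matched GGD fitting loses efficiency for β near the clamp
  boundaries; maximum-likelihood refinement is a straightforward extension.
- The lasso path uses per-λ refits rather than warm starts, which is slower
  than glmnet for large grids.
- The stub backend is a contract fixture, not a feature extractor of record;
  plugging in a real network requires only the `(image, mask) → vector`
  signature.
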