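# sonoquant

Quantization-assisted analysis of breast-ultrasound lesion images:
segmentation refinement, saliency features, feature fusion and
benign-vs-malignant evaluation — with a seeded speckle-phantom generator so
everything runs and tests without clinical data.

## Who this is for

Researchers building B-mode breast-ultrasound CAD pipelines who need (a) a
deterministic, learning-free fallback when a neural segmenter's lesion mask
"needs reconsideration", (b) compact statistical lesion descriptors that
complement deep features, and (c) exact, reproducible evaluation arithmetic
for k-fold classification studies.

## What it computes

**Quantization refinement.** A coarse lesion mask (from any backend) is
checked by a trigger rule (empty / too small / low solidity). When it fires,
the image is quantized into *n*+1 levels by a 1×*n* multilevel Otsu threshold
vector (exhaustive between-class-variance maximization for *n* ≤ 2, exact
dynamic program above), and the lesion is isolated from the hypoechoic
(darkest) level by scoring 8-connected components on area, circularity
4πA/P², roundness 4A/(π·major²) and overlap with the coarse mask.

**ICA/SUN saliency features.** Patches with per-patch mean removed are
reduced by PCA (dropping the leading high-eigenvalue component) and unmixed
by FastICA into sparse filters. Filter responses *f&#8344;* are modelled by
zero-mean generalized Gaussians P(*f&#8344;*) ∝ exp(−|*f&#8344;*/s|^β) fitted by moment
matching. Bottom-up saliency of a pixel is the inverse probability of its
joint response, P(F)⁻¹ with P(F) = Π&#8344; P(*f&#8344;*), kept in the log domain. The
per-lesion feature vector f₁ pools mean absolute responses and mean
log-saliency over the mask, L2-normalized.

**Serial fusion and classification.** f₁ is concatenated with a deep-feature
block f₂ (pluggable backend contract; a deterministic histogram + Hu-moment +
contour-descriptor stub ships in the box) into α = (f₁ ‖ f₂) of dimension
n + m, each block min–max scaled with training-split statistics. Evaluation
is stratified k-fold cross-validation with out-of-fold predictions pooled
into a single 2×2 confusion matrix, reported as accuracy, precision, recall,
F1 and Cohen's kappa (percentages, half-up to 2 decimals, benign positive).
An L1-penalized binomial (lasso-logistic) model with an internal
cross-validated λ path covers joint feature selection + classification.

**Segmentation metrics.** Two-class soft dice, cross-entropy, focal loss
−(1−p&#8348;)^γ log p&#8348;, their weighted "total loss", Mean-IoU and Mean-F_β.

**Phantoms.** Star-convex lesions (smooth ovals for benign, irregular
spiculated shapes for malignant) on speckled backgrounds — multiplicative
gamma noise with unit mean and variance 1/looks — with exact polygon masks
and fully seeded determinism.

## Worked example

```python
import numpy as np
import sonoquant as sq

# phantom with a known lesion
sample = sq.make_phantom(sq.PhantomSpec(seed=3, class_label="M", irregularity=0.45))

# refine an empty coarse mask: the trigger fires and quantization recovers the lesion
refined = sq.refine_segmentation(sample.image, np.zeros_like(sample.mask))
print("refined IoU vs truth:", round(sq.mean_iou([refined], [sample.mask]), 3))

# exact metrics from a 2x2 confusion matrix (benign positive)
rep = sq.confusion_metrics(sq.ConfusionMatrix2x2(bb=45, bm=3, mb=3, mm=49))
print("accuracy:", rep.accuracy, "kappa:", rep.kappa)

# small synthetic end-to-end run
report = sq.pipeline.run_pipeline({
    "data": {"n_benign": 40, "n_malignant": 20},
    "ica": {"max_patches": 8000, "k": 16},
})
print("segmentation:", {k: round(v, 3) for k, v in report["segmentation"].items()})
print("cv accuracy:", report["classification"]["metrics"]["accuracy"])
```

prints

```
refined IoU vs truth: 0.909
accuracy: 94.0 kappa: 87.98
segmentation: {'mean_iou': 0.946, 'mean_f1': 0.972}
cv accuracy: 100.0
```

The refinement recovers ~91% overlap with the true mask from an empty coarse
guess; the 45/3/3/49 confusion matrix yields 94% accuracy with strong
chance-corrected agreement (κ = 87.98%); and on the 60-phantom cohort the
quantization path averages 0.946 IoU while fused features classify the two
morphology classes perfectly under 5-fold cross-validation.

A `sonoquant` console script exposes the same stages
(`generate | prep | refine | ica-train | ica-features | fuse | cv | metrics |
seg-eval | run`); see `sonoquant --help`.

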