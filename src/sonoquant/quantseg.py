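"""Multilevel Otsu quantization and tumor-level lesion selection.

A coarse lesion mask from any segmentation backend can be refined by a
two-step isolation: quantize the image into ``n + 1`` discrete intensity
levels using an ``n``-threshold Otsu vector, then select the connected
component of the tumor level that best matches region criteria (area,
circularity = 4*pi*A/P^2, roundness = 4*A/(pi*major_axis^2), and overlap with
the coarse mask when one is available).  Breast lesions are hypoechoic, so the
darkest level is the default tumor level.

The same path doubles as a standalone baseline segmenter when no coarse mask
exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .imgprep import _as_image, _as_mask, gaussian_smooth

logger = logging.getLogger(__name__)

__all__ = [
    "RegionCriteria",
    "TriggerRule",
    "DegenerateInputError",
    "otsu_thresholds",
    "quantize",
    "select_lesion",
    "refine_segmentation",
    "QuantizationRefiner",
]

N_BINS = 256


class DegenerateInputError(ValueError):
    """Image has too few distinct intensities for the requested thresholds."""


@dataclass(frozen=True)
class RegionCriteria:
    """Scoring/filter criteria for candidate lesion components."""

    min_area: int = 20
    circularity_range: tuple[float, float] = (0.0, 1.0)
    roundness_range: tuple[float, float] = (0.0, 1.0)
    overlap_weight: float = 0.5

    def __post_init__(self):
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        for lo, hi in (self.circularity_range, self.roundness_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("criteria ranges must lie within [0, 1]")


@dataclass(frozen=True)
class TriggerRule:
    """When a coarse mask 'needs reconsideration' and the quantization path
    replaces it: empty mask, area below ``min_area_frac`` of the image, or
    solidity below ``solidity_floor``."""

    min_area_frac: float = 0.001
    solidity_floor: float = 0.5

    def fires(self, coarse: np.ndarray) -> tuple[bool, str]:
        area = int(coarse.sum())
        if area == 0:
            return True, "empty coarse mask"
        if area < self.min_area_frac * coarse.size:
            return True, f"coarse area {area} below {self.min_area_frac:.4f} of image"
        # union solidity: area over convex-hull area of ALL foreground pixels,
        # so a scattered/fragmented guess scores low even if each fragment is solid
        solidity = measure.regionprops((coarse > 0).astype(np.uint8))[0].solidity
        if solidity < self.solidity_floor:
            return True, f"solidity {solidity:.3f} below floor {self.solidity_floor}"
        return False, "coarse mask accepted"


# ---------------------------------------------------------------------------
# Otsu thresholds
# ---------------------------------------------------------------------------

def _histogram(img: np.ndarray) -> np.ndarray:
    idx = np.minimum((img * N_BINS).astype(int), N_BINS - 1)
    return np.bincount(idx.ravel(), minlength=N_BINS).astype(float)


def _between_class_terms(hist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative weight W and first moment S so that a class over bins
    [i, j] contributes (S_ij)^2 / W_ij to the between-class objective."""
    centers = (np.arange(N_BINS) + 0.5) / N_BINS
    w = np.concatenate([[0.0], np.cumsum(hist)])
    s = np.concatenate([[0.0], np.cumsum(hist * centers)])
    return w, s


def _class_term(w, s, i, j):
    """(sum of p*mu)^2 / weight over bins i..j inclusive; 0 for empty class."""
    wij = w[j + 1] - w[i]
    sij = s[j + 1] - s[i]
    return np.where(wij > 0, sij**2 / np.where(wij > 0, wij, 1.0), 0.0)


def _split_exhaustive(hist: np.ndarray, n: int) -> list[int]:
    """Exact maximization over all threshold placements for n <= 2,
    vectorized; the first (lexicographically smallest) maximizer wins."""
    w, s = _between_class_terms(hist)
    if n == 1:
        i = np.arange(N_BINS - 1)
        obj = _class_term(w, s, 0, i) + _class_term(w, s, i + 1, N_BINS - 1)
        return [int(np.argmax(obj))]
    ii, jj = np.meshgrid(np.arange(N_BINS - 2), np.arange(N_BINS - 1), indexing="ij")
    valid = jj > ii
    obj = np.where(
        valid,
        _class_term(w, s, 0, ii)
        + _class_term(w, s, ii + 1, jj)
        + _class_term(w, s, jj + 1, N_BINS - 1),
        -np.inf,
    )
    flat = int(np.argmax(obj))
    return [flat // (N_BINS - 1), flat % (N_BINS - 1)]


def _split_dp(hist: np.ndarray, n: int) -> list[int]:
    """Exact dynamic program over class boundaries (any n); ties resolved
    toward the smallest boundary index at each stage."""
    w, s = _between_class_terms(hist)
    j = np.arange(N_BINS)
    # cost[i, j]: contribution of one class spanning bins i..j (j >= i)
    cost = np.full((N_BINS, N_BINS), -np.inf)
    for i in range(N_BINS):
        cost[i, i:] = _class_term(w, s, i, j[i:])
    n_classes = n + 1
    dp = np.full((n_classes, N_BINS), -np.inf)
    arg = np.zeros((n_classes, N_BINS), dtype=int)
    dp[0] = cost[0]
    for c in range(1, n_classes):
        for jj in range(c, N_BINS):
            cand = dp[c - 1, c - 1 : jj] + cost[c : jj + 1, jj]
            best = int(np.argmax(cand))
            dp[c, jj] = cand[best]
            arg[c, jj] = best + c - 1
    cuts = []
    jj = N_BINS - 1
    for c in range(n_classes - 1, 0, -1):
        jj = arg[c, jj]
        cuts.append(jj)
    return cuts[::-1]


def otsu_thresholds(img, n: int = 3) -> np.ndarray:
    """Return the 1 x n vector of Otsu thresholds maximizing between-class
    variance over the 256-bin histogram of the image.

    Exhaustive search for n <= 2; an exact boundary dynamic program above.
    Thresholds are the upper bin edges of each class, strictly ascending, in
    (0, 1).
    """
    img = _as_image(img)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    n_distinct = np.unique(img).size
    if n_distinct < n + 1:
        raise DegenerateInputError(
            f"image has {n_distinct} distinct values; need at least {n + 1} "
            f"for {n} thresholds"
        )
    hist = _histogram(img)
    if np.count_nonzero(hist) < n + 1:
        raise DegenerateInputError(
            f"histogram occupies {np.count_nonzero(hist)} bins; need {n + 1}"
        )
    cuts = _split_exhaustive(hist, n) if n <= 2 else _split_dp(hist, n)
    return (np.asarray(cuts, dtype=float) + 1.0) / N_BINS


def quantize(img, thresholds) -> np.ndarray:
    """Map an image to n+1 discrete levels: label(p) = index of the half-open
    bin [0,t1), [t1,t2), ..., [tn,1] containing p."""
    img = _as_image(img)
    t = np.asarray(thresholds, dtype=float).ravel()
    if t.size < 1 or np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be non-empty and strictly ascending")
    return np.digitize(img, t)


# ---------------------------------------------------------------------------
# Lesion selection
# ---------------------------------------------------------------------------

def region_shape_features(component: np.ndarray) -> dict:
    """Area, circularity 4*pi*A/P^2 and roundness 4*A/(pi*major^2) of a single
    binary component (clamped to [0, 1]).

    Perimeter uses the weighted boundary-configuration estimator (the
    regionprops contour-length approximation): a raw boundary-pixel count
    overestimates the length of diagonal contours enough that even a perfect
    rasterized disk would score circularity ~0.6.
    """
    area = float(component.sum())
    props = measure.regionprops(component.astype(np.uint8))[0]
    perim = max(props.perimeter, 1.0)
    major = max(props.axis_major_length, 1.0)
    return {
        "area": area,
        "circularity": min(4.0 * np.pi * area / perim**2, 1.0),
        "roundness": min(4.0 * area / (np.pi * major**2), 1.0),
    }


def _pick_tumor_level(levels, img, coarse):
    labels = np.unique(levels)
    if coarse is not None and coarse.sum() > 0:
        best, best_iou = labels[0], -1.0
        for lv in labels:
            sel = levels == lv
            inter = np.logical_and(sel, coarse).sum()
            union = np.logical_or(sel, coarse).sum()
            iou = inter / union if union else 0.0
            if iou > best_iou:
                best, best_iou = lv, iou
        return best
    means = [img[levels == lv].mean() for lv in labels]
    return labels[int(np.argmin(means))]


def select_lesion(levels, img, coarse=None, crit: RegionCriteria = RegionCriteria()):
    """Pick the lesion component from a quantized level map.

    The tumor level is the darkest level (hypoechoic assumption) or, when a
    coarse mask is supplied, the level of maximal IoU with it.  8-connected
    components of that level are scored by area, circularity, roundness and
    (when available) coarse overlap; the best component is returned with its
    holes filled.  An all-zero mask is returned when nothing passes
    ``crit.min_area``.
    """
    img = _as_image(img)
    levels = np.asarray(levels)
    if levels.shape != img.shape:
        raise ValueError("level map and image shapes differ")
    if coarse is not None:
        coarse = _as_mask(coarse)
        if coarse.shape != img.shape:
            raise ValueError("coarse mask and image shapes differ")

    if levels.size == 0 or np.unique(levels).size == 0:
        logger.warning("select_lesion: empty level map")
        return np.zeros(img.shape, dtype=np.uint8)

    tumor_level = _pick_tumor_level(levels, img, coarse)
    comp_labels, n_comp = ndimage.label(levels == tumor_level, structure=np.ones((3, 3)))
    if n_comp == 0:
        logger.warning("select_lesion: tumor level has no components")
        return np.zeros(img.shape, dtype=np.uint8)

    areas = ndimage.sum_labels(np.ones_like(comp_labels), comp_labels,
                               index=np.arange(1, n_comp + 1))
    max_area = float(areas.max())
    best_score, best_mask = -np.inf, None
    for ci in np.flatnonzero(areas >= crit.min_area) + 1:
        comp = comp_labels == ci
        feats = region_shape_features(comp)
        if not (crit.circularity_range[0] <= feats["circularity"] <= crit.circularity_range[1]):
            continue
        if not (crit.roundness_range[0] <= feats["roundness"] <= crit.roundness_range[1]):
            continue
        area_score = feats["area"] / max_area
        if coarse is not None and coarse.sum() > 0:
            inter = np.logical_and(comp, coarse).sum()
            union = np.logical_or(comp, coarse).sum()
            score = (
                crit.overlap_weight * (inter / union)
                + 0.25 * feats["circularity"]
                + 0.25 * area_score
            )
        else:
            darkness = 1.0 - img[comp].mean()
            score = 0.5 * darkness + 0.5 * area_score
        if score > best_score:
            best_score, best_mask = score, comp
    if best_mask is None:
        logger.warning("select_lesion: no component passed criteria")
        return np.zeros(img.shape, dtype=np.uint8)
    return ndimage.binary_fill_holes(best_mask).astype(np.uint8)


def refine_segmentation(
    img,
    coarse,
    n: int = 3,
    crit: RegionCriteria = RegionCriteria(),
    trigger: TriggerRule = TriggerRule(),
    presmooth_sigma: float = 1.5,
) -> np.ndarray:
    """Two-step isolation of the lesion: if the coarse mask needs
    reconsideration (per ``trigger``), quantization replaces it —
    otsu_thresholds -> quantize -> select_lesion on the (optionally
    pre-smoothed) image; otherwise the coarse mask passes through unchanged.

    Speckle is suppressed with a Gaussian (``presmooth_sigma``; 0 disables)
    before histogram thresholding.  On a degenerate-input error from Otsu the
    coarse mask is returned unchanged.
    """
    img = _as_image(img)
    coarse = _as_mask(coarse)
    if img.shape != coarse.shape:
        raise ValueError("image and coarse mask shapes differ")
    fired, reason = trigger.fires(coarse)
    logger.info("refine_segmentation: trigger %s (%s)", "fired" if fired else "not fired", reason)
    if not fired:
        return coarse.copy()
    work = gaussian_smooth(img, presmooth_sigma) if presmooth_sigma > 0 else img
    try:
        t = otsu_thresholds(work, n)
    except DegenerateInputError as exc:
        logger.warning("refine_segmentation: %s; keeping coarse mask", exc)
        return coarse.copy()
    levels = quantize(work, t)
    coarse_arg = coarse if coarse.sum() > 0 else None
    return select_lesion(levels, work, coarse_arg, crit)


class QuantizationRefiner:
    """Estimator-style wrapper around :func:`refine_segmentation`.

    Stateless (nothing is learned); ``transform`` maps ``(image, coarse)``
    pairs to refined masks so the refiner slots into pipeline code that
    expects the fit/transform protocol.
    """

    def __init__(self, n_levels: int = 3, crit: RegionCriteria = RegionCriteria(),
                 trigger: TriggerRule = TriggerRule(), presmooth_sigma: float = 1.5):
        self.n_levels = n_levels
        self.crit = crit
        self.trigger = trigger
        self.presmooth_sigma = presmooth_sigma

    def get_params(self, deep=True):
        return {
            "n_levels": self.n_levels,
            "crit": self.crit,
            "trigger": self.trigger,
            "presmooth_sigma": self.presmooth_sigma,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None):
        return self

    def transform(self, pairs):
        return [
            refine_segmentation(
                img, coarse, self.n_levels, self.crit, self.trigger,
                self.presmooth_sigma,
            )
            for img, coarse in pairs
        ]
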