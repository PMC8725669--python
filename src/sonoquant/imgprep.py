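"""Image preparation: I/O, nearest-neighbour resizing, Gaussian smoothing,
histogram equalization and paired image/mask augmentation.

All images live on a canonical float scale in [0, 1]; 8-bit files are divided
by 255 on read and rounded half-up back to 8-bit on write.  Coordinates are
0-based, row-major ``(row, col)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import exposure, transform

logger = logging.getLogger(__name__)

__all__ = [
    "AugmentSpec",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "resize_nearest",
    "gaussian_smooth",
    "hist_equalize",
    "augment_pair",
]


def _as_image(img) -> np.ndarray:
    """Validate and canonicalize an image to 2-D float64 in [0, 1].

    3-channel inputs are collapsed to grayscale by channel averaging
    (ultrasound "RGB" files are replicated luminance).
    """
    a = np.asarray(img, dtype=float)
    if a.ndim == 3:
        if a.shape[2] not in (1, 3):
            raise ValueError(f"expected 1 or 3 channels, got {a.shape[2]}")
        a = a.mean(axis=2)
    if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
        raise ValueError(f"expected a 2-D image, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("image intensities must lie in [0, 1]")
    return a


def _as_mask(mask) -> np.ndarray:
    m = np.asarray(mask)
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask must contain only values {0, 1}")
    return m.astype(np.uint8)


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as float64 in [0, 1] (grayscale)."""
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr / 255.0
    return _as_image(np.clip(arr, 0.0, 1.0))


def write_image(path, img) -> None:
    """Write a [0, 1] image to an 8-bit file, rounding half-up."""
    img = _as_image(img)
    u8 = np.floor(img * 255.0 + 0.5).clip(0, 255).astype(np.uint8)
    Image.fromarray(u8).save(path)


def read_mask(path) -> np.ndarray:
    """Read a 0/255 8-bit mask file as a {0, 1} array."""
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr >= 128).astype(np.uint8)


def write_mask(path, mask) -> None:
    m = _as_mask(mask)
    Image.fromarray((m * 255).astype(np.uint8)).save(path)


# ---------------------------------------------------------------------------
# Geometry / intensity operators
# ---------------------------------------------------------------------------

def _nearest_source_indices(n_out: int, n_in: int) -> np.ndarray:
    # Center-aligned continuous source coordinate, rounded by INT(a + 0.5).
    a = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    return np.floor(a + 0.5).astype(int).clip(0, n_in - 1)


def resize_nearest(img, target: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize to ``target = (rows, cols)``.

    Each output pixel copies the input pixel whose center-aligned source
    coordinate, rounded by adding 0.5 and truncating, is nearest; no new
    intensity values are introduced.
    """
    img = _as_image(img)
    rows, cols = int(target[0]), int(target[1])
    if rows < 1 or cols < 1:
        raise ValueError(f"target dimensions must be positive, got {target}")
    ri = _nearest_source_indices(rows, img.shape[0])
    ci = _nearest_source_indices(cols, img.shape[1])
    return img[np.ix_(ri, ci)]


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Normalized 2-D Gaussian kernel truncated at radius ceil(3*sigma)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    r = int(np.ceil(3 * sigma))
    ii, jj = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    k = np.exp(-(ii**2 + jj**2) / (2.0 * sigma**2)) / (2.0 * np.pi * sigma**2)
    return k / k.sum()


def gaussian_smooth(img, sigma: float) -> np.ndarray:
    """Convolve with a truncated, renormalized Gaussian (reflect boundary)."""
    img = _as_image(img)
    out = ndimage.convolve(img, gaussian_kernel(sigma), mode="reflect")
    return np.clip(out, 0.0, 1.0)


def hist_equalize(img, bins: int = 256) -> np.ndarray:
    """Histogram equalization by the cumulative-distribution mapping.

    Builds the empirical CDF over ``bins`` equal-width bins on [0, 1] and maps
    every pixel to the CDF value of its bin — a monotone non-decreasing
    intensity transform.  A constant image is returned unchanged (its CDF is
    degenerate) with a logged warning.
    """
    img = _as_image(img)
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    if np.ptp(img) == 0:
        logger.warning("hist_equalize: constant image, returning unchanged")
        return img.copy()
    idx = np.minimum((img * bins).astype(int), bins - 1)
    hist = np.bincount(idx.ravel(), minlength=bins)
    cdf = np.cumsum(hist) / idx.size
    return cdf[idx]


# ---------------------------------------------------------------------------
# Paired augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentSpec:
    """One sampled augmentation: geometric parts apply to image and mask
    identically, photometric parts to the image only."""

    shift: tuple[float, float] = (0.0, 0.0)  # (row, col) fraction of size
    scale: float = 1.0
    rotate: float = 0.0  # degrees, about image center
    hflip: bool = False
    clahe: bool = False
    brightness_delta: float = 0.0
    sharpen: bool = False
    contrast_stretch: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if max(abs(self.shift[0]), abs(self.shift[1])) >= 1:
            raise ValueError("|shift| must be < 1")

    @classmethod
    def random(
        cls,
        seed: int,
        max_shift: float = 0.0625,
        scale_range: tuple[float, float] = (0.9, 1.1),
        max_rotate: float = 15.0,
    ) -> "AugmentSpec":
        """Sample a spec from conservative default ranges; the seed fully
        determines the transform."""
        rng = np.random.default_rng(seed)
        return cls(
            shift=tuple(rng.uniform(-max_shift, max_shift, size=2)),
            scale=float(rng.uniform(*scale_range)),
            rotate=float(rng.uniform(-max_rotate, max_rotate)),
            hflip=bool(rng.random() < 0.5),
            clahe=bool(rng.random() < 0.5),
            brightness_delta=float(rng.uniform(-0.1, 0.1)),
            sharpen=bool(rng.random() < 0.5),
            contrast_stretch=bool(rng.random() < 0.5),
            seed=seed,
        )

    @property
    def is_geometric_identity(self) -> bool:
        return (
            self.shift == (0.0, 0.0)
            and self.scale == 1.0
            and self.rotate == 0.0
            and not self.hflip
        )


def _geometric_transform(spec: AugmentSpec, shape) -> transform.AffineTransform:
    rows, cols = shape
    center = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])  # (x, y)
    t_center = transform.AffineTransform(translation=-center)
    t_core = transform.AffineTransform(
        scale=spec.scale, rotation=np.deg2rad(spec.rotate)
    )
    t_back = transform.AffineTransform(
        translation=center + np.array([spec.shift[1] * cols, spec.shift[0] * rows])
    )
    return t_center + t_core + t_back


def augment_pair(img, mask, spec: AugmentSpec) -> tuple[np.ndarray, np.ndarray]:
    """Apply one augmentation to an image and its mask.

    The shift/scale/rotate/flip part is applied identically to both; the mask
    is resampled nearest-neighbour so it stays binary.  CLAHE, brightness,
    sharpening and contrast stretching touch the image only.
    """
    img = _as_image(img)
    mask = _as_mask(mask)
    if img.shape != mask.shape:
        raise ValueError(f"shape mismatch: image {img.shape} vs mask {mask.shape}")

    if not spec.is_geometric_identity:
        tf = _geometric_transform(spec, img.shape)
        img = transform.warp(img, tf.inverse, order=1, mode="reflect",
                             preserve_range=True)
        mask = transform.warp(
            mask.astype(float), tf.inverse, order=0, mode="constant", cval=0.0,
            preserve_range=True,
        ).astype(np.uint8)
        if spec.hflip:
            img = img[:, ::-1]
            mask = mask[:, ::-1]
        img = np.clip(img, 0.0, 1.0)

    if spec.clahe:
        img = exposure.equalize_adapthist(img)
    if spec.brightness_delta:
        img = np.clip(img + spec.brightness_delta, 0.0, 1.0)
    if spec.sharpen:
        from skimage.filters import unsharp_mask

        img = np.clip(unsharp_mask(img, radius=1.0, amount=1.0), 0.0, 1.0)
    if spec.contrast_stretch:
        lo, hi = np.percentile(img, (2, 98))
        img = exposure.rescale_intensity(img, in_range=(lo, hi))

    return np.ascontiguousarray(img), np.ascontiguousarray(mask)
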