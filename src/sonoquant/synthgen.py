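"""Seeded ultrasound-like speckle phantoms with one hypoechoic lesion each.

Benign lesions are smooth, round-to-oval; malignant lesions are irregular
and spiculated.  The lesion boundary is a star-convex polygon,
``r(theta) = r0 * e(theta) * (1 + irregularity * P(theta))`` with ``e`` an
ellipse factor and ``P`` a seeded band-limited perturbation, so the mask is
an exact polygon rasterization and boundary roughness is a single dial.
Speckle is modelled as fully developed multiplicative gamma noise with shape
``speckle_looks`` (unit mean; variance 1/looks), the standard approximation
for B-mode intensity images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask

logger = logging.getLogger(__name__)

__all__ = ["PhantomSpec", "PhantomSample", "make_phantom", "make_dataset",
           "write_dataset"]

_N_BOUNDARY = 720
_HARMONICS = range(2, 7)


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int] = (128, 128)
    class_label: str = "B"
    lesion_center: tuple[float, float] = (0.5, 0.5)  # fractional (row, col)
    lesion_radius: float = 0.18  # fraction of min dimension
    irregularity: float = 0.05
    lesion_intensity_offset: float = -0.3
    speckle_looks: int = 16
    background_level: float = 0.55
    aspect: float = 0.85  # minor/major axis ratio of the ellipse base
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.lesion_radius < 0.5):
            raise ValueError("lesion_radius must lie in (0, 0.5)")
        if self.class_label not in ("B", "M"):
            raise ValueError("class_label must be 'B' or 'M'")
        if self.speckle_looks < 1:
            raise ValueError("speckle_looks must be >= 1")
        if self.lesion_intensity_offset >= 0:
            raise ValueError("lesion must be hypoechoic (negative offset)")


@dataclass(frozen=True)
class PhantomSample:
    image: np.ndarray
    mask: np.ndarray
    label: str
    spec: PhantomSpec


def _boundary_polygon(spec: PhantomSpec, rng) -> np.ndarray:
    """Star-convex boundary vertices in (row, col) pixel coordinates."""
    rows, cols = spec.shape
    r0 = spec.lesion_radius * min(rows, cols)
    theta = np.linspace(0.0, 2.0 * np.pi, _N_BOUNDARY, endpoint=False)

    phi = rng.uniform(0, np.pi)  # ellipse orientation
    e = 1.0 / np.sqrt(
        np.cos(theta - phi) ** 2 + (np.sin(theta - phi) / spec.aspect) ** 2
    )

    pert = np.zeros_like(theta)
    for h in _HARMONICS:
        a, b = rng.standard_normal(2) / h
        pert += a * np.cos(h * theta) + b * np.sin(h * theta)
    amp = np.abs(pert).max()
    if amp > 0:
        pert /= amp

    radius = r0 * e * np.clip(1.0 + spec.irregularity * pert, 0.2, None)
    cr = spec.lesion_center[0] * rows
    cc = spec.lesion_center[1] * cols

    rr = cr + radius * np.sin(theta)
    cc_ = cc + radius * np.cos(theta)
    # re-center if the lesion spills outside the image
    shift_r = max(0.0, 1.0 - rr.min()) - max(0.0, rr.max() - (rows - 2))
    shift_c = max(0.0, 1.0 - cc_.min()) - max(0.0, cc_.max() - (cols - 2))
    if shift_r or shift_c:
        logger.warning("phantom lesion re-centered by (%.1f, %.1f)", shift_r, shift_c)
        rr += shift_r
        cc_ += shift_c
    return np.column_stack([rr, cc_])


def make_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom: clean two-level scene times gamma speckle, with
    the exact polygon mask.  The seed fully determines the sample."""
    rng = np.random.default_rng(spec.seed)
    poly = _boundary_polygon(spec, rng)
    mask = polygon2mask(spec.shape, poly).astype(np.uint8)
    clean = np.full(spec.shape, spec.background_level)
    clean[mask == 1] = max(spec.background_level + spec.lesion_intensity_offset, 0.02)
    looks = spec.speckle_looks
    speckle = rng.gamma(shape=looks, scale=1.0 / looks, size=spec.shape)
    image = np.clip(clean * speckle, 0.0, 1.0)
    return PhantomSample(image=image, mask=mask, label=spec.class_label, spec=spec)


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of the boundary polygon (for rasterization checks)."""
    r, c = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


def _class_spec(label: str, difficulty: float, seed: int, shape,
                speckle_looks: int) -> PhantomSpec:
    """Class-conditional spec draw.  Separation between the classes — the
    boundary-irregularity gap and the echogenicity gap — scales with
    (1 - difficulty)."""
    rng = np.random.default_rng(seed)
    sep = 1.0 - np.clip(difficulty, 0.0, 1.0)
    center = tuple(rng.uniform(0.38, 0.62, size=2))
    radius = float(rng.uniform(0.12, 0.22))
    background = float(rng.uniform(0.5, 0.65))
    if label == "B":
        irregularity = float(rng.uniform(0.0, 0.08))
        offset = float(rng.uniform(-0.28, -0.20))
        aspect = float(rng.uniform(0.75, 0.98))
    else:
        lo = 0.10 + 0.40 * sep
        irregularity = float(rng.uniform(lo, lo + 0.12))
        offset = float(rng.uniform(-0.28, -0.20)) - 0.18 * sep
        aspect = float(rng.uniform(0.55, 0.85))
    return PhantomSpec(
        shape=tuple(shape), class_label=label, lesion_center=center,
        lesion_radius=radius, irregularity=irregularity,
        lesion_intensity_offset=max(offset, -background + 0.02),
        speckle_looks=speckle_looks, background_level=background,
        aspect=aspect, seed=seed,
    )


def make_dataset(n_benign: int = 437, n_malignant: int = 210, seed: int = 0,
                 difficulty: float = 0.3, shape=(128, 128),
                 speckle_looks: int = 16) -> list[PhantomSample]:
    """Generate a labelled phantom dataset (defaults mirror a 437 benign /
    210 malignant cohort).  Deterministic per seed."""
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("counts must be non-negative")
    root = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   root.spawn(n_benign + n_malignant)]
    samples = []
    for i in range(n_benign + n_malignant):
        label = "B" if i < n_benign else "M"
        spec = _class_spec(label, difficulty, child_seeds[i], shape, speckle_looks)
        samples.append(make_phantom(spec))
    return samples


def write_dataset(samples, out_dir) -> pd.DataFrame:
    """Write images/*.png, masks/*.png and labels.csv (id,label,seed)."""
    from pathlib import Path

    from .imgprep import write_image, write_mask

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        sid = f"{s.label.lower()}_{i:04d}"
        write_image(out / "images" / f"{sid}.png", s.image)
        write_mask(out / "masks" / f"{sid}.png", s.mask)
        rows.append({"id": sid, "label": s.label, "seed": s.spec.seed})
    labels = pd.DataFrame(rows)
    labels.to_csv(out / "labels.csv", index=False)
    return labels
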