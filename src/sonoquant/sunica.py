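"""ICA sparse-filter saliency features (SUN framework).

Small patches are extracted from lesion images with their per-patch mean
removed (the grayscale analogue of LMS channel-mean subtraction), reduced by
PCA with the dominant high-eigenvalue component(s) excluded, and unmixed by
fixed-point ICA into a bank of sparse filters.  Each filter's training
responses are modelled by a zero-mean generalized Gaussian
``P(f_i) ~ exp(-|f_i / s_i|^beta_i)`` fitted by moment matching (variance ->
scale, kurtosis -> shape).  Bottom-up saliency of a pixel is the inverse
probability of its joint response, ``P(F)^-1`` with ``P(F) = prod_i P(f_i)``;
the map is kept in the log domain, ``-sum_i log P(f_i)``, shifted so its
minimum is zero.  The per-image feature vector pools mean absolute filter
responses and mean log-saliency over the lesion mask, then L2-normalizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import optimize, special
from sklearn.decomposition import PCA, FastICA

from .imgprep import _as_image, _as_mask

logger = logging.getLogger(__name__)

__all__ = [
    "PatchConfig",
    "IcaSaliencyExtractor",
    "extract_patches",
    "fit_ica_model",
    "saliency_map",
    "ica_feature_vector",
    "fit_ggd",
    "ggd_neg_log_pdf",
]


@dataclass(frozen=True)
class PatchConfig:
    patch_size: int = 11
    stride: int = 4
    max_patches: int = 50_000
    seed: int = 0

    def __post_init__(self):
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be odd and >= 3")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def extract_patches(imgs, cfg: PatchConfig = PatchConfig()) -> np.ndarray:
    """Vectorized row-major patches from a list of images, per-patch mean
    subtracted, subsampled to ``cfg.max_patches`` with ``cfg.seed``."""
    p = cfg.patch_size
    blocks = []
    for img in imgs:
        img = _as_image(img)
        if img.shape[0] < p or img.shape[1] < p:
            raise ValueError(
                f"image {img.shape} smaller than patch size {p}"
            )
        win = sliding_window_view(img, (p, p))[:: cfg.stride, :: cfg.stride]
        blocks.append(win.reshape(-1, p * p))
    patches = np.concatenate(blocks, axis=0)
    if patches.shape[0] > cfg.max_patches:
        rng = np.random.default_rng(cfg.seed)
        keep = rng.choice(patches.shape[0], size=cfg.max_patches, replace=False)
        patches = patches[np.sort(keep)]
    return patches - patches.mean(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Generalized Gaussian moment-matching fit
# ---------------------------------------------------------------------------

def _ggd_kurtosis(beta: float) -> float:
    g = special.gammaln
    return float(np.exp(g(5.0 / beta) + g(1.0 / beta) - 2.0 * g(3.0 / beta)))


def fit_ggd(x, beta_bounds=(0.3, 4.0)) -> tuple[float, float]:
    """Fit a zero-mean generalized Gaussian by moment matching.

    The shape ``beta`` solves kurtosis(beta) = sample kurtosis (clamped to
    ``beta_bounds``); the scale follows from the variance,
    ``s = sqrt(var * Gamma(1/beta) / Gamma(3/beta))``.
    """
    x = np.asarray(x, dtype=float).ravel()
    var = x.var()
    if var <= 0:
        return 2.0, 1e-12
    kurt = float(np.mean(x**4) / var**2)
    lo, hi = beta_bounds
    # kurtosis is strictly decreasing in beta
    if kurt >= _ggd_kurtosis(lo):
        beta = lo
    elif kurt <= _ggd_kurtosis(hi):
        beta = hi
    else:
        beta = optimize.brentq(lambda b: _ggd_kurtosis(b) - kurt, lo, hi)
    s = float(np.sqrt(var * np.exp(special.gammaln(1.0 / beta) - special.gammaln(3.0 / beta))))
    return float(beta), s


def ggd_neg_log_pdf(x, beta: float, s: float) -> np.ndarray:
    """-log P(x) for the normalized GGD
    P(x) = beta / (2 s Gamma(1/beta)) * exp(-|x/s|^beta)."""
    log_norm = np.log(2.0 * s) + special.gammaln(1.0 / beta) - np.log(beta)
    return np.abs(np.asarray(x, dtype=float) / s) ** beta + log_norm


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class IcaSaliencyExtractor:
    """Learn ICA sparse filters + GGD response models; map images to saliency
    and lesion feature vectors.

    Parameters
    ----------
    patch_size : odd patch side in pixels.
    stride : training patch stride (saliency mapping always uses stride 1).
    k : number of ICA filters requested.
    drop_top : leading high-eigenvalue PCA components excluded before ICA
        (the luminance/DC-dominated directions).
    var_keep : fraction of the remaining variance retained, capped at ``k``
        components.
    max_patches, seed : training subsample size and RNG seed.

    Fitted attributes (trailing underscore): ``mean_patch_``, ``pca_basis_``
    (d_kept x patch_dim), ``kept_indices_``, ``ica_filters_`` (k x d_kept,
    unit-norm rows), ``ggd_shape_``, ``ggd_scale_``.
    """

    def __init__(self, patch_size: int = 11, stride: int = 4, k: int = 32,
                 drop_top: int = 1, var_keep: float = 0.95,
                 max_patches: int = 50_000, seed: int = 0,
                 max_iter: int = 500):
        self.patch_size = patch_size
        self.stride = stride
        self.k = k
        self.drop_top = drop_top
        self.var_keep = var_keep
        self.max_patches = max_patches
        self.seed = seed
        self.max_iter = max_iter

    # -- sklearn-style plumbing -------------------------------------------
    _param_names = ("patch_size", "stride", "k", "drop_top", "var_keep",
                    "max_patches", "seed", "max_iter")

    def get_params(self, deep=True):
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self._param_names:
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- fitting -----------------------------------------------------------
    def fit(self, imgs, y=None):
        cfg = PatchConfig(self.patch_size, self.stride, self.max_patches, self.seed)
        patches = extract_patches(imgs, cfg)
        return self.fit_patches(patches)

    def fit_patches(self, patches: np.ndarray):
        """Fit from an already-extracted (mean-subtracted) patch matrix."""
        patches = np.asarray(patches, dtype=float)
        if patches.shape[0] < 10 * self.k:
            raise ValueError(
                f"need at least {10 * self.k} patches for k={self.k}, "
                f"got {patches.shape[0]}"
            )
        self.mean_patch_ = patches.mean(axis=0)
        centered = patches - self.mean_patch_

        n_comp = min(centered.shape[0], centered.shape[1])
        pca = PCA(n_components=n_comp, svd_solver="full", random_state=self.seed)
        pca.fit(centered)
        evr = pca.explained_variance_ratio_
        nonzero = int(np.sum(pca.explained_variance_ > 1e-12 * pca.explained_variance_[0]))
        # per-patch mean subtraction removes exactly one dimension, so rank
        # n_comp - 1 is the expected full rank here
        if nonzero < n_comp - 1:
            logger.warning("rank-deficient patch matrix: rank %d < %d", nonzero, n_comp - 1)
        start = min(self.drop_top, nonzero - 1)
        rest = evr[start:nonzero]
        cum = np.cumsum(rest) / rest.sum()
        n95 = int(np.searchsorted(cum, self.var_keep) + 1)
        d_kept = max(1, min(n95, self.k, nonzero - start))
        self.kept_indices_ = np.arange(start, start + d_kept)
        self.pca_basis_ = pca.components_[self.kept_indices_]

        # responses are defined on per-patch-mean-subtracted patches without
        # further centering, so a constant patch responds exactly zero
        reduced = patches @ self.pca_basis_.T
        k_eff = min(self.k, d_kept)
        if k_eff < self.k:
            logger.warning("reduced space supports only %d filters (k=%d)", k_eff, self.k)
        ica = FastICA(
            n_components=k_eff, whiten="unit-variance", max_iter=self.max_iter,
            tol=1e-5, random_state=self.seed,
        )
        ica.fit(reduced)
        if ica.n_iter_ >= self.max_iter:
            raise RuntimeError(
                f"ICA did not converge within {self.max_iter} iterations"
            )
        filt = ica.components_
        self.ica_filters_ = filt / np.linalg.norm(filt, axis=1, keepdims=True)

        responses = reduced @ self.ica_filters_.T
        params = [fit_ggd(responses[:, i]) for i in range(k_eff)]
        self.ggd_shape_ = np.array([p[0] for p in params])
        self.ggd_scale_ = np.array([p[1] for p in params])
        return self

    @property
    def n_filters_(self) -> int:
        return self.ica_filters_.shape[0]

    # -- mapping -----------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "ica_filters_"):
            raise RuntimeError("extractor is not fitted")

    def _responses(self, img: np.ndarray) -> np.ndarray:
        """Per-pixel filter responses at every valid patch center
        (stride 1), shape (rows-p+1, cols-p+1, k)."""
        self._check_fitted()
        p = self.patch_size
        img = _as_image(img)
        if img.shape[0] < p or img.shape[1] < p:
            raise ValueError(f"image {img.shape} smaller than patch size {p}")
        win = sliding_window_view(img, (p, p))
        flat = win.reshape(win.shape[0], win.shape[1], p * p)
        flat = flat - flat.mean(axis=2, keepdims=True)
        pixel_filters = self.ica_filters_ @ self.pca_basis_  # (k, patch_dim)
        return flat @ pixel_filters.T

    def saliency_map(self, img) -> np.ndarray:
        """Log-domain SUN saliency, -sum_i log P(f_i), edge-padded to the
        image shape and shifted so the minimum is zero."""
        resp = self._responses(img)
        sal = np.zeros(resp.shape[:2])
        for i in range(self.n_filters_):
            sal += ggd_neg_log_pdf(resp[..., i], self.ggd_shape_[i], self.ggd_scale_[i])
        r = self.patch_size // 2
        full = np.pad(sal, r, mode="edge")
        return full - full.min()

    def feature_vector(self, img, mask) -> np.ndarray:
        """Lesion feature vector f1: k mean absolute filter responses over
        patch centers inside the mask, plus the mean log-saliency over the
        mask; L2-normalized."""
        img = _as_image(img)
        mask = _as_mask(mask)
        if mask.shape != img.shape:
            raise ValueError("image and mask shapes differ")
        if mask.sum() == 0:
            raise ValueError(
                "empty mask: pool over the whole image instead (pass a full mask)"
            )
        resp = self._responses(img)
        r = self.patch_size // 2
        inner = mask[r:-r, r:-r].astype(bool) if r else mask.astype(bool)
        if not inner.any():  # mask entirely within the border ring
            inner = np.ones(resp.shape[:2], dtype=bool)
        means = np.abs(resp[inner]).mean(axis=0)
        # log-saliency pooled over patch centers in the lesion, shifted by the
        # region minimum: local to the lesion and zero for a constant region
        logsal = np.zeros(resp.shape[:2])
        for i in range(self.n_filters_):
            logsal += ggd_neg_log_pdf(resp[..., i], self.ggd_shape_[i],
                                      self.ggd_scale_[i])
        region = logsal[inner]
        vec = np.concatenate([means, [(region - region.min()).mean()]])
        norm = np.linalg.norm(vec)
        if norm == 0:
            logger.warning("degenerate region: zero feature vector")
            return vec
        return vec / norm

    def transform(self, pairs) -> np.ndarray:
        """Map a sequence of (image, mask) pairs to the f1 feature matrix."""
        return np.vstack([self.feature_vector(img, m) for img, m in pairs])

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        self._check_fitted()
        np.savez(
            path,
            params=np.array(
                [self.patch_size, self.stride, self.k, self.drop_top,
                 self.max_patches, self.seed, self.max_iter]),
            var_keep=np.array([self.var_keep]),
            mean_patch=self.mean_patch_,
            pca_basis=self.pca_basis_,
            kept_indices=self.kept_indices_,
            ica_filters=self.ica_filters_,
            ggd_shape=self.ggd_shape_,
            ggd_scale=self.ggd_scale_,
        )

    @classmethod
    def load(cls, path) -> "IcaSaliencyExtractor":
        with np.load(path) as z:
            p = z["params"].astype(int)
            obj = cls(patch_size=int(p[0]), stride=int(p[1]), k=int(p[2]),
                      drop_top=int(p[3]), var_keep=float(z["var_keep"][0]),
                      max_patches=int(p[4]), seed=int(p[5]), max_iter=int(p[6]))
            obj.mean_patch_ = z["mean_patch"]
            obj.pca_basis_ = z["pca_basis"]
            obj.kept_indices_ = z["kept_indices"]
            obj.ica_filters_ = z["ica_filters"]
            obj.ggd_shape_ = z["ggd_shape"]
            obj.ggd_scale_ = z["ggd_scale"]
        return obj


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def fit_ica_model(patches, k: int = 32, drop_top: int = 1, seed: int = 0,
                  patch_size: int | None = None) -> IcaSaliencyExtractor:
    """Fit the ICA/GGD model from a patch matrix; returns the fitted
    extractor (the model object)."""
    if patch_size is None:
        patch_size = int(round(np.sqrt(patches.shape[1])))
    model = IcaSaliencyExtractor(patch_size=patch_size, k=k, drop_top=drop_top,
                                 seed=seed)
    return model.fit_patches(np.asarray(patches, dtype=float))


def saliency_map(img, model: IcaSaliencyExtractor) -> np.ndarray:
    return model.saliency_map(img)


def ica_feature_vector(img, mask, model: IcaSaliencyExtractor) -> np.ndarray:
    return model.feature_vector(img, mask)
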