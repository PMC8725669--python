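"""Serial feature fusion, the pluggable deep-feature backend contract, and
lasso-regularized binomial feature selection/classification.

Serial fusion concatenates an ICA feature block f1 (n-dimensional) with a
deep-feature block f2 (m-dimensional) into alpha = (f1 || f2) of dimension
n + m, after min-max scaling each block with statistics of the training split
only.  Any real deep extractor must satisfy the backend contract
``(image, mask) -> fixed-length vector``; a deterministic stub (masked
histogram + Hu-moment magnitudes + seeded random projection) stands in so the
pipeline runs end to end without pretrained weights.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage import measure
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .imgprep import _as_image, _as_mask

logger = logging.getLogger(__name__)

__all__ = [
    "SerialFusion",
    "DeepFeatureStub",
    "LassoBinomialClassifier",
    "serial_fuse",
    "deep_feature_stub",
    "lasso_fit",
]


class SerialFusion(BaseEstimator, TransformerMixin):
    """Serial fusion of two feature blocks with train-split min-max scaling.

    ``fit`` stores per-column minima and maxima of each block;
    ``transform`` scales each block to [0, 1] with those statistics and
    concatenates.  Stored parameters allow exact recovery of the unscaled
    parts (``inverse_transform``).
    """

    def fit(self, F1, F2=None, y=None):
        F1 = np.atleast_2d(np.asarray(F1, dtype=float))
        F2 = (np.atleast_2d(np.asarray(F2, dtype=float))
              if F2 is not None and np.size(F2) else np.empty((F1.shape[0], 0)))
        if F1.shape[1] == 0 and F2.shape[1] == 0:
            raise ValueError("both feature blocks are empty")
        self.n_ = F1.shape[1]
        self.m_ = F2.shape[1]
        self.min_ = np.concatenate([F1.min(axis=0) if self.n_ else [],
                                    F2.min(axis=0) if self.m_ else []])
        span = np.concatenate([np.ptp(F1, axis=0) if self.n_ else [],
                               np.ptp(F2, axis=0) if self.m_ else []])
        self.span_ = np.where(span > 0, span, 1.0)
        return self

    def transform(self, F1, F2=None):
        F1 = np.atleast_2d(np.asarray(F1, dtype=float))
        F2 = (np.atleast_2d(np.asarray(F2, dtype=float))
              if F2 is not None and np.size(F2) else np.empty((F1.shape[0], 0)))
        if F1.shape[1] != self.n_ or F2.shape[1] != self.m_:
            raise ValueError(
                f"block dims ({F1.shape[1]}, {F2.shape[1]}) do not match "
                f"fitted ({self.n_}, {self.m_})"
            )
        alpha = np.hstack([F1, F2])
        return (alpha - self.min_) / self.span_

    def fit_transform(self, F1, F2=None, y=None):
        return self.fit(F1, F2).transform(F1, F2)

    def inverse_transform(self, alpha):
        alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
        raw = alpha * self.span_ + self.min_
        return raw[:, : self.n_], raw[:, self.n_:]


def serial_fuse(f1, f2, scaler: SerialFusion | None = None):
    """Fuse two feature matrices (or single vectors) serially.

    Without a pre-fitted ``scaler`` the inputs are treated as the training
    split (fit + transform).  Returns ``(alpha, scaler)``.
    """
    f1 = np.atleast_2d(np.asarray(f1, dtype=float))
    f2 = np.atleast_2d(np.asarray(f2, dtype=float)) if np.size(f2) else None
    if scaler is None:
        scaler = SerialFusion().fit(f1, f2)
    return scaler.transform(f1, f2), scaler


# ---------------------------------------------------------------------------
# Deep-feature backend contract + stub
# ---------------------------------------------------------------------------

class DeepFeatureStub(BaseEstimator, TransformerMixin):
    """Deterministic stand-in for a pretrained deep feature extractor.

    Features: a 16-bin intensity histogram of the masked region, the seven
    log-magnitude Hu moments of the masked intensity image, four contour
    descriptors of the mask (area fraction, circularity, roundness,
    solidity), and a seeded random projection of those 27 numbers padded to
    ``dim``.  Identical ``(img, mask, dim, seed)`` always yields identical
    output, which is the contract any real backend must honour.
    """

    N_HIST = 16
    BASE_DIM = 27  # histogram 16 + Hu 7 + contour 4

    def __init__(self, dim: int = 27, seed: int = 0):
        self.dim = dim
        self.seed = seed

    def fit(self, X=None, y=None):
        return self

    def _base_features(self, img, mask) -> np.ndarray:
        img = _as_image(img)
        mask = _as_mask(mask)
        if mask.sum() == 0:
            logger.warning("deep stub: empty mask, pooling over whole image")
            mask = np.ones_like(mask)
        vals = img[mask.astype(bool)]
        hist, _ = np.histogram(vals, bins=self.N_HIST, range=(0.0, 1.0))
        hist = hist / vals.size
        mu = measure.moments_central(img * mask)
        hu = measure.moments_hu(measure.moments_normalized(mu))
        hu = np.log1p(np.abs(hu))
        from .quantseg import region_shape_features

        shape = region_shape_features(mask.astype(bool))
        solidity = measure.regionprops(
            (mask > 0).astype(np.uint8))[0].solidity
        contour = np.array([shape["area"] / mask.size, shape["circularity"],
                            shape["roundness"], solidity])
        return np.concatenate([hist, hu, contour])

    def extract(self, img, mask) -> np.ndarray:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        base = self._base_features(img, mask)
        if self.dim <= base.size:
            return base[: self.dim]
        rng = np.random.default_rng(self.seed)
        proj = rng.standard_normal((self.dim - base.size, base.size))
        proj /= np.sqrt(base.size)
        return np.concatenate([base, proj @ base])

    def transform(self, pairs) -> np.ndarray:
        return np.vstack([self.extract(img, m) for img, m in pairs])


def deep_feature_stub(img, mask, dim: int = 27, seed: int = 0) -> np.ndarray:
    return DeepFeatureStub(dim=dim, seed=seed).extract(img, mask)


# ---------------------------------------------------------------------------
# Lasso-regularized binomial classification
# ---------------------------------------------------------------------------

class LassoBinomialClassifier(BaseEstimator, ClassifierMixin):
    """L1-penalized logistic (binomial) regression with an internal
    cross-validated lambda path — simultaneous feature selection and
    classification.

    The penalty parametrization follows the glmnet convention: the objective
    is mean deviance + lambda * ||w||_1.  The grid descends log-uniformly
    from ``lambda_max`` (the smallest lambda that zeroes every coefficient)
    over ``decades`` decades; lambda is chosen by mean held-out deviance over
    a seeded stratified internal CV.  Coordinate descent via liblinear.

    Fitted attributes: ``coef_``, ``intercept_``, ``lambda_``, ``selected_``
    (indices of non-zero coefficients), ``lambda_grid_``, ``classes_``.
    """

    def __init__(self, lambda_grid=None, n_lambdas: int = 50,
                 decades: float = 4.0, folds: int = 5, seed: int = 0):
        self.lambda_grid = lambda_grid
        self.n_lambdas = n_lambdas
        self.decades = decades
        self.folds = folds
        self.seed = seed

    @staticmethod
    def _lambda_max(X, y01) -> float:
        resid = y01 - y01.mean()
        return float(np.max(np.abs(X.T @ resid)) / X.shape[0])

    def _make_grid(self, X, y01) -> np.ndarray:
        if self.lambda_grid is not None:
            return np.sort(np.asarray(self.lambda_grid, dtype=float))[::-1]
        lmax = max(self._lambda_max(X, y01), 1e-12)
        return np.geomspace(lmax, lmax * 10.0 ** (-self.decades), self.n_lambdas)

    def _fit_one(self, X, y01, lam) -> LogisticRegression:
        C = 1.0 / (max(lam, 1e-12) * X.shape[0])
        clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                 max_iter=2000, random_state=self.seed)
        clf.fit(X, y01)
        return clf

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"binomial model requires exactly 2 classes, got {self.classes_.size}"
            )
        y01 = (y == self.classes_[1]).astype(int)
        counts = np.bincount(y01)
        if counts.min() < 2:
            raise ValueError("need at least 2 samples per class")
        grid = self._make_grid(X, y01)

        n_folds = min(self.folds, counts.min())
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=self.seed)
        deviance = np.zeros(grid.size)
        for tr, te in cv.split(X, y01):
            for gi, lam in enumerate(grid):
                clf = self._fit_one(X[tr], y01[tr], lam)
                prob = clf.predict_proba(X[te])[:, 1]
                deviance[gi] += log_loss(y01[te], prob, labels=[0, 1])
        best = int(np.argmin(deviance))
        self.lambda_grid_ = grid
        self.cv_deviance_ = deviance / n_folds
        self.lambda_ = float(grid[best])

        final = self._fit_one(X, y01, self.lambda_)
        self.coef_ = final.coef_.ravel()
        self.intercept_ = float(final.intercept_[0])
        self.selected_ = np.flatnonzero(self.coef_)
        if self.selected_.size == 0:
            logger.warning("all coefficients zero at lambda=%.3g; intercept-only "
                           "model", self.lambda_)
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        from scipy.special import expit

        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    def selection_path(self, X, y):
        """Number of selected features at each grid lambda (diagnostic)."""
        X = np.asarray(X, dtype=float)
        y01 = (np.asarray(y) == np.unique(y)[1]).astype(int)
        grid = self._make_grid(X, y01)
        return grid, np.array([
            np.count_nonzero(self._fit_one(X, y01, lam).coef_) for lam in grid
        ])


def lasso_fit(features, labels, lambda_grid=None, folds: int = 5,
              seed: int = 0) -> LassoBinomialClassifier:
    """Fit the lasso-binomial model; thin wrapper over the estimator."""
    model = LassoBinomialClassifier(lambda_grid=lambda_grid, folds=folds, seed=seed)
    return model.fit(features, labels)
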