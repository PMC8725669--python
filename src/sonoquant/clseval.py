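"""Classifier evaluation: stratified k-fold cross-validation with a pooled
out-of-fold confusion matrix, and exact confusion-matrix metrics —
accuracy, precision, recall, F1 and Cohen's kappa, reported as percentages
rounded half-up to two decimals.

Class order is fixed as (B, M) — benign, malignant — with benign as the
positive class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ConfusionMatrix2x2",
    "MetricsReport",
    "FoldAssignment",
    "ClassifierSpec",
    "confusion_metrics",
    "stratified_kfold",
    "make_classifier",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Counts with rows = actual class, columns = predicted class, in the
    fixed order (B, M): bb, bm / mb, mm."""

    bb: int
    bm: int
    mb: int
    mm: int

    def __post_init__(self):
        if min(self.bb, self.bm, self.mb, self.mm) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.bb + self.bm + self.mb + self.mm

    @classmethod
    def from_labels(cls, actual, predicted) -> "ConfusionMatrix2x2":
        a = np.asarray(actual)
        p = np.asarray(predicted)
        return cls(
            bb=int(np.sum((a == "B") & (p == "B"))),
            bm=int(np.sum((a == "B") & (p == "M"))),
            mb=int(np.sum((a == "M") & (p == "B"))),
            mm=int(np.sum((a == "M") & (p == "M"))),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([[self.bb, self.bm], [self.mb, self.mm]],
                            index=["B", "M"], columns=["B", "M"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConfusionMatrix2x2":
        return cls(bb=int(df.loc["B", "B"]), bm=int(df.loc["B", "M"]),
                   mb=int(df.loc["M", "B"]), mm=int(df.loc["M", "M"]))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="Class")

    @classmethod
    def read_csv(cls, path) -> "ConfusionMatrix2x2":
        return cls.from_frame(pd.read_csv(path, index_col=0))


@dataclass(frozen=True)
class MetricsReport:
    """Percentages rounded half-up to 2 decimals; ``degenerate`` flags any
    metric whose denominator was zero (reported as 0)."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    kappa: float
    positive_class: str = "B"
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), ROUND_HALF_UP))


def confusion_metrics(cm: ConfusionMatrix2x2, positive: str = "B") -> MetricsReport:
    """Exact metric arithmetic on a 2x2 confusion matrix.

    accuracy = (bb + mm) / total; precision/recall/F1 for the positive
    class; Cohen's kappa = (p_o - p_e) / (1 - p_e) with chance agreement
    p_e from the row/column marginals.  All values x100, rounded half-up to
    2 decimals.
    """
    if positive not in ("B", "M"):
        raise ValueError("positive class must be 'B' or 'M'")
    bb, bm, mb, mm = cm.bb, cm.bm, cm.mb, cm.mm
    total = cm.total
    if positive == "B":
        tp, fn, fp, tn = bb, bm, mb, mm
    else:
        tp, fn, fp, tn = mm, mb, bm, bb

    degenerate = False

    def _safe(num, den):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    acc = (bb + mm) / total
    prec = _safe(tp, tp + fp)
    rec = _safe(tp, tp + fn)
    f1 = _safe(2.0 * prec * rec, prec + rec)
    p_o = acc
    p_e = ((bb + bm) * (bb + mb) + (mb + mm) * (bm + mm)) / total**2
    kappa = _safe(p_o - p_e, 1.0 - p_e)
    return MetricsReport(
        accuracy=_round2(100.0 * acc),
        precision=_round2(100.0 * prec),
        recall=_round2(100.0 * rec),
        f1=_round2(100.0 * f1),
        kappa=_round2(100.0 * kappa),
        positive_class=positive,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Folds and cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    fold_index: np.ndarray  # test-fold index per sample
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


def stratified_kfold(labels, k: int, seed: int = 0) -> FoldAssignment:
    """Seeded stratified partition into k folds; per-fold class counts differ
    by at most one from perfect stratification."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    for cls_, cnt in zip(classes, counts):
        if cnt < k:
            raise ValueError(f"class {cls_!r} has {cnt} samples, fewer than k={k}")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_index = np.empty(labels.size, dtype=int)
    for fi, (_, test) in enumerate(cv.split(np.zeros((labels.size, 1)), labels)):
        fold_index[test] = fi
    return FoldAssignment(fold_index=fold_index, k=k, seed=seed)


@dataclass(frozen=True)
class ClassifierSpec:
    """Named classical classifier with overridable hyperparameters.

    Kinds mirror the MATLAB-toolbox family the field reports: cubic and
    quadratic SVMs, a medium decision tree, random-undersampling boost,
    bagged trees, and the lasso-binomial model.
    """

    kind: str = "svm_cubic"
    hyperparameters: tuple = ()
    seed: int = 0

    KINDS = ("svm_cubic", "svm_quadratic", "tree_medium", "rus_boost",
             "bag_boost", "lasso_binomial")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)


class _RusBoost:
    """AdaBoost on a seeded random undersample of the majority class
    (balanced training set)."""

    def __init__(self, n_estimators=50, seed=0):
        self.n_estimators = n_estimators
        self.seed = seed

    def fit(self, X, y):
        rng = np.random.default_rng(self.seed)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        n_min = counts.min()
        keep = np.concatenate([
            rng.choice(np.flatnonzero(y == c), size=n_min, replace=False)
            for c in classes
        ])
        keep.sort()
        self._boost = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=2, random_state=self.seed),
            n_estimators=self.n_estimators, random_state=self.seed,
        )
        self._boost.fit(X[keep], y[keep])
        return self

    def predict(self, X):
        return self._boost.predict(X)


def make_classifier(spec: ClassifierSpec):
    """Instantiate the classifier named by a spec (common defaults; all
    hyperparameters overridable via ``spec.hyperparameters``)."""
    from .fusesel import LassoBinomialClassifier

    p = spec.params
    if spec.kind == "svm_cubic":
        return make_pipeline(StandardScaler(), SVC(
            kernel="poly", degree=3, C=p.get("C", 1.0), coef0=1.0,
            gamma="scale", random_state=spec.seed))
    if spec.kind == "svm_quadratic":
        return make_pipeline(StandardScaler(), SVC(
            kernel="poly", degree=2, C=p.get("C", 1.0), coef0=1.0,
            gamma="scale", random_state=spec.seed))
    if spec.kind == "tree_medium":
        return DecisionTreeClassifier(
            max_leaf_nodes=p.get("max_leaf_nodes", 20), random_state=spec.seed)
    if spec.kind == "rus_boost":
        return _RusBoost(n_estimators=p.get("n_estimators", 50), seed=spec.seed)
    if spec.kind == "bag_boost":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=spec.seed),
            n_estimators=p.get("n_estimators", 50), random_state=spec.seed)
    if spec.kind == "lasso_binomial":
        return LassoBinomialClassifier(
            folds=p.get("folds", 5), seed=spec.seed)
    raise ValueError(spec.kind)  # unreachable


def cross_validate(features, labels, spec: ClassifierSpec, k: int,
                   seed: int = 0) -> tuple[ConfusionMatrix2x2, MetricsReport]:
    """k-fold cross-validation with out-of-fold predictions pooled into one
    confusion matrix (one matrix per method and k), then exact metrics."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    folds = stratified_kfold(y, k, seed)
    predicted = np.empty(y.shape, dtype=y.dtype)
    for fold in range(k):
        tr, te = folds.train_indices(fold), folds.test_indices(fold)
        clf = make_classifier(spec)
        try:
            clf.fit(X[tr], y[tr])
            predicted[te] = clf.predict(X[te])
        except Exception as exc:  # noqa: BLE001 - annotate fold context
            raise RuntimeError(
                f"classifier {spec.kind!r} failed on fold {fold}: {exc}"
            ) from exc
    cm = ConfusionMatrix2x2.from_labels(y, predicted)
    return cm, confusion_metrics(cm)
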