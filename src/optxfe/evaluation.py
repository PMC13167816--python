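"""1-NN / city-block classification, cross-validation protocols and metrics.

Two validation protocols are provided.  Segment-level stratified k-fold
treats every segment as exchangeable and so can place segments of the same
subject in both training and test folds — an optimistic, within-dataset
estimate.  Leave-one-subject-out (LOSO) holds out all segments of one
subject at a time and is the subject-independent protocol; on data with
subject-level structure its accuracy is expected at or below the k-fold
figure.

Class convention: label 1 = epilepsy (positive), label 2 = control
(negative).  Metrics are reported as percentages; the geometric mean is
``sqrt(sensitivity * specificity)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "knn_predict",
    "kfold_cv",
    "loso_cv",
    "metrics",
    "cv_accuracy",
]

POSITIVE_LABEL = 1
NEGATIVE_LABEL = 2


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts indexed (true, predicted) with class 1 positive."""

    tp: int
    fn: int
    fp: int
    tn: int

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos, neg = POSITIVE_LABEL, NEGATIVE_LABEL
        return cls(
            tp=int(np.sum((y_true == pos) & (y_pred == pos))),
            fn=int(np.sum((y_true == pos) & (y_pred != pos))),
            fp=int(np.sum((y_true == neg) & (y_pred != neg))),
            tn=int(np.sum((y_true == neg) & (y_pred == neg))),
        )

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_array(self) -> np.ndarray:
        """Rows = true class (1, 2), columns = predicted class (1, 2)."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, sensitivity, specificity and geometric mean, in percent.

    A metric whose denominator is empty (no positive or no negative test
    samples) is NaN and listed in ``undefined`` rather than silently zero.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    geometric_mean: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "geometric_mean": self.geometric_mean,
            "undefined": list(self.undefined),
        }


def knn_predict(train_X, train_y, test_X, k: int = 1, metric: str = "L1") -> np.ndarray:
    """k-nearest-neighbour prediction under city-block (L1) distance.

    Distance ties are broken toward the smaller training-row index; for
    k > 1 the majority label wins, ties toward the label of the nearer
    neighbour.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_y = np.asarray(train_y)
    if train_X.size == 0 or len(train_y) == 0:
        raise ValueError("training set must be non-empty")
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError("feature dimensions of train and test must match")
    if metric.upper() not in ("L1", "CITYBLOCK", "MANHATTAN"):
        raise ValueError(f"unsupported metric: {metric}")

    d = cdist(test_X, train_X, metric="cityblock")
    if k == 1:
        # argmin returns the first minimum -> smallest training-row index.
        return train_y[np.argmin(d, axis=1)]
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    preds = np.empty(test_X.shape[0], dtype=train_y.dtype)
    for i, nb in enumerate(order):
        labels = train_y[nb]
        uniq, first_pos = np.unique(labels, return_index=True)
        counts = np.array([np.sum(labels == u) for u in uniq])
        best = counts == counts.max()
        # among tied labels, prefer the one whose first neighbour is nearer
        preds[i] = uniq[best][np.argmin(first_pos[best])]
    return preds


def kfold_cv(X, y, folds: int = 10, seed: int = 0, k: int = 1) -> ConfusionMatrix:
    """Stratified segment-level k-fold CV; aggregates out-of-fold predictions."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2 or folds > len(y):
        raise ValueError(f"folds must be in 2..{len(y)}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    for tr, te in skf.split(X, y):
        y_pred[te] = knn_predict(X[tr], y[tr], X[te], k=k)
    return ConfusionMatrix.from_predictions(y, y_pred)


def loso_cv(X, y, subjects, k: int = 1) -> ConfusionMatrix:
    """Leave-one-subject-out CV: one fold per subject."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    if uniq.size < 2:
        raise ValueError("LOSO requires at least 2 subjects")
    y_pred = np.empty_like(y)
    for s in uniq:
        te = subjects == s
        y_pred[te] = knn_predict(X[~te], y[~te], X[te], k=k)
    return ConfusionMatrix.from_predictions(y, y_pred)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Compute the four headline metrics from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined = []
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fn > 0:
        sensitivity = 100.0 * cm.tp / (cm.tp + cm.fn)
    else:
        sensitivity = float("nan")
        undefined.append("sensitivity")
    if cm.tn + cm.fp > 0:
        specificity = 100.0 * cm.tn / (cm.tn + cm.fp)
    else:
        specificity = float("nan")
        undefined.append("specificity")
    if math.isnan(sensitivity) or math.isnan(specificity):
        gm = float("nan")
        undefined.append("geometric_mean")
    else:
        gm = math.sqrt(sensitivity * specificity / 10000.0) * 100.0
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        geometric_mean=gm,
        undefined=tuple(undefined),
    )


def cv_accuracy(X, y, folds: int = 10, seed: int = 0, k: int = 1) -> float:
    """10-fold CV accuracy in percent — the default CWINCA candidate evaluator."""
    return metrics(kfold_cv(X, y, folds=folds, seed=seed, k=k)).accuracy
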