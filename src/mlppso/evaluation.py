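"""Confusion-matrix metrics, ROC/AUC from first principles, and the k-fold
cross-validation harness.

Metric definitions (positive = disease present):

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)          (= TPR)
    F1        = 2 * precision * recall / (precision + recall)
    FPR       = FP / (FP + TN)

The ROC curve sweeps the decision threshold over the unique scores (rule:
score >= t -> positive, matching the classifier's tie rule) plus a +inf
sentinel, giving a monotone path from (0, 0) to (1, 1); AUC is its
trapezoidal area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .data_io import Dataset

_METRICS = ("accuracy", "precision", "recall", "f1", "auc")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _check_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 labels")
    return a.astype(int)


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Exact TP/FP/TN/FN counts for binary labels."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _nonempty(cm: ConfusionMatrix) -> None:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")


def accuracy(cm: ConfusionMatrix) -> float:
    _nonempty(cm)
    return (cm.tp + cm.tn) / cm.total


def precision(cm: ConfusionMatrix) -> float:
    """TP / (TP + FP); with no predicted positives the value is undefined
    and the documented convention returns 0 (with a warning)."""
    _nonempty(cm)
    if cm.tp + cm.fp == 0:
        warnings.warn("no predicted positives: precision undefined, returning 0")
        return 0.0
    return cm.tp / (cm.tp + cm.fp)


def recall(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN); requires actual positives in the evaluation set."""
    _nonempty(cm)
    if cm.tp + cm.fn == 0:
        raise ValueError("no actual positives: recall undefined")
    return cm.tp / (cm.tp + cm.fn)


def f1(cm: ConfusionMatrix) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    p = precision(cm) if cm.tp + cm.fp else 0.0
    r = recall(cm)
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def fpr(cm: ConfusionMatrix) -> float:
    """FP / (FP + TN); requires actual negatives."""
    _nonempty(cm)
    if cm.fp + cm.tn == 0:
        raise ValueError("no actual negatives: FPR undefined")
    return cm.fp / (cm.fp + cm.tn)


def roc_curve(y_true, scores) -> list[tuple[float, float, float]]:
    """Threshold sweep producing ordered (threshold, FPR, TPR) points.

    Thresholds are +inf (nothing predicted positive, the (0, 0) corner)
    followed by the unique scores in descending order; the final point, at
    the minimum score, is (1, 1).  Both coordinates are non-decreasing.
    """
    y_true = _check_binary(y_true, "y_true")
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("length mismatch")
    n_pos = int(y_true.sum())
    n_neg = int(y_true.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    points = [(np.inf, 0.0, 0.0)]
    order = np.argsort(-scores, kind="stable")
    y_sorted = y_true[order]
    s_sorted = scores[order]
    tp = fp = 0
    i = 0
    n = y_true.size
    while i < n:
        t = s_sorted[i]
        while i < n and s_sorted[i] == t:  # all instances tied at this score
            if y_sorted[i] == 1:
                tp += 1
            else:
                fp += 1
            i += 1
        points.append((float(t), fp / n_neg, tp / n_pos))
    return points


def auc(points: Sequence[tuple[float, float, float]]) -> float:
    """Trapezoidal area under an ordered (threshold, FPR, TPR) sweep."""
    fprs = np.asarray([p[1] for p in points])
    tprs = np.asarray([p[2] for p in points])
    if fprs.size < 2:
        raise ValueError("need at least 2 ROC points")
    return float(np.trapezoid(tprs, fprs))


def roc_auc(y_true, scores) -> float:
    return auc(roc_curve(y_true, scores))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    n_test: int
    roc_points: list[tuple[float, float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "n_test": self.n_test,
            "roc_points": [list(p) for p in self.roc_points],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FoldMetrics":
        return cls(
            accuracy=d["accuracy"],
            precision=d["precision"],
            recall=d["recall"],
            f1=d["f1"],
            auc=d["auc"],
            n_test=d["n_test"],
            roc_points=[tuple(p) for p in d.get("roc_points", [])],
        )


@dataclass
class MetricsReport:
    """Per-fold metrics plus their unweighted means."""

    folds: list[FoldMetrics]

    def means(self) -> dict[str, float]:
        return {
            m: float(np.mean([getattr(f, m) for f in self.folds])) for m in _METRICS
        }

    def to_dict(self) -> dict:
        return {"folds": [f.to_dict() for f in self.folds], "means": self.means()}

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(folds=[FoldMetrics.from_dict(f) for f in d["folds"]])


def evaluate_scores(y_true, scores, threshold: float = 0.5) -> FoldMetrics:
    """All five metrics (plus ROC points) for one evaluation set."""
    y_true = _check_binary(y_true, "y_true")
    labels = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    cm = confusion(y_true, labels)
    points = roc_curve(y_true, scores)
    return FoldMetrics(
        accuracy=accuracy(cm),
        precision=precision(cm),
        recall=recall(cm),
        f1=f1(cm),
        auc=auc(points),
        n_test=cm.total,
        roc_points=points,
    )


def kfold_indices(
    n: int, k: int, seed: int = 0, stratify: np.ndarray | None = None
) -> list[np.ndarray]:
    """Shuffle once, then partition into k folds of size floor(n/k) or
    ceil(n/k) (the first n mod k folds take the extra row)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds n = {n}")
    rng = np.random.default_rng(seed)
    if stratify is None:
        perm = rng.permutation(n)
        sizes = np.full(k, n // k)
        sizes[: n % k] += 1
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        return [np.sort(perm[bounds[i] : bounds[i + 1]]) for i in range(k)]
    stratify = np.asarray(stratify)
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(stratify):
        rows = np.flatnonzero(stratify == c)
        rows = rows[rng.permutation(len(rows))]
        for i, r in enumerate(rows):
            folds[i % k].append(int(r))
    return [np.sort(np.asarray(f)) for f in folds]


def kfold_cv(
    data: Dataset,
    k: int = 5,
    train_fn: Callable[[Dataset], Callable[[Dataset], np.ndarray]] | None = None,
    seed: int = 0,
    stratified: bool = False,
    threshold: float = 0.5,
) -> MetricsReport:
    """k-fold cross-validation of a training procedure.

    ``train_fn(train_data)`` must return a scorer mapping a Dataset to
    per-row probabilities; everything it fits (imputation, scaling, the
    network) must be fitted on the training folds only — this harness hands
    it nothing else.  Each fold serves as the test set exactly once.
    """
    if train_fn is None:
        raise ValueError("train_fn is required")
    folds = kfold_indices(
        data.n_rows, k, seed=seed, stratify=data.target if stratified else None
    )
    all_rows = np.arange(data.n_rows)
    results: list[FoldMetrics] = []
    for test_rows in folds:
        train_rows = np.setdiff1d(all_rows, test_rows)
        train_data = data.subset(train_rows)
        if len(np.unique(train_data.target)) < 2:
            raise ValueError("a training portion contains a single class")
        scorer = train_fn(train_data)
        test_data = data.subset(test_rows)
        scores = np.asarray(scorer(test_data), dtype=float)
        results.append(evaluate_scores(test_data.target, scores, threshold))
    return MetricsReport(folds=results)
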