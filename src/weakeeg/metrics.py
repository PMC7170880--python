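"""Confusion-derived metrics, ROC/AUROC, operating points, seed aggregation.

Precision = TP/(TP+FP), Recall = TP/(TP+FN),
F1 = 2 * precision * recall / (precision + recall), FPR = FP/(FP+TN).
Zero-denominator conventions: precision 0 when no positive predictions,
recall 0 when no positives, F1 0 when precision + recall = 0.

AUROC is the probability that a uniformly random positive outscores a
uniformly random negative, ties counting one half; the ROC curve is recall
as a function of FPR over all distinct score thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from weakeeg.errors import (
    InsufficientReplicatesError,
    NoFeasibleThresholdError,
    UndefinedMetricError,
)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    fpr: float
    threshold: float
    counts: ConfusionCounts
    auroc: float | None = None
    #: (fpr, tpr, threshold) arrays of the ROC curve, if computed
    roc: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(default=None, repr=False)


def _check_inputs(labels, probs) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    probs = np.asarray(probs, dtype=np.float64)
    if labels.shape != probs.shape:
        raise ValueError(f"length mismatch: {labels.shape} labels vs {probs.shape} scores")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return labels.astype(int), probs


def confusion_metrics(labels, probs, threshold: float = 0.5) -> MetricsReport:
    """Threshold the scores at ``>= threshold`` and evaluate the four metrics."""
    labels, probs = _check_inputs(labels, probs)
    pred = probs >= threshold
    pos = labels == 1
    counts = ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    fpr = counts.fp / (counts.fp + counts.tn) if counts.fp + counts.tn else 0.0
    return MetricsReport(precision, recall, f1, fpr, threshold, counts)


def roc_auroc(labels, probs) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray], float]:
    """ROC curve enumerated at all distinct thresholds, and its area."""
    labels, probs = _check_inputs(labels, probs)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUROC requires both classes present")
    fpr, tpr, thr = roc_curve(labels, probs, drop_intermediate=False)
    return (fpr, tpr, thr), float(roc_auc_score(labels, probs))


def evaluate_probs(labels, probs, threshold: float = 0.5) -> MetricsReport:
    """Full report: thresholded metrics plus ROC/AUROC."""
    report = confusion_metrics(labels, probs, threshold)
    report.roc, report.auroc = roc_auroc(labels, probs)
    return report


def operating_point(
    roc: tuple[np.ndarray, np.ndarray, np.ndarray],
    target_tpr: float | None = None,
    target_fpr: float | None = None,
) -> tuple[float, float, float]:
    """Pick a threshold meeting a TPR floor or an FPR ceiling.

    For ``target_tpr``: the largest threshold whose TPR >= target, ties
    broken toward lower FPR.  For ``target_fpr``: the smallest threshold
    whose FPR <= target, ties broken toward higher TPR.  Returns
    ``(threshold, tpr, fpr)``.
    """
    if (target_tpr is None) == (target_fpr is None):
        raise ValueError("specify exactly one of target_tpr / target_fpr")
    fpr, tpr, thr = (np.asarray(a, dtype=np.float64) for a in roc)
    if target_tpr is not None:
        ok = tpr >= target_tpr
        if not ok.any():
            raise NoFeasibleThresholdError(f"no threshold reaches TPR >= {target_tpr}")
        cand = np.nonzero(ok)[0]
        best = cand[np.lexsort((fpr[cand], -thr[cand]))][0]
    else:
        ok = fpr <= target_fpr
        if not ok.any():
            raise NoFeasibleThresholdError(f"no threshold keeps FPR <= {target_fpr}")
        cand = np.nonzero(ok)[0]
        best = cand[np.lexsort((-tpr[cand], thr[cand]))][0]
    return float(thr[best]), float(tpr[best]), float(fpr[best])


@dataclass
class SeedAggregate:
    mean: float
    ci_low: float
    ci_high: float
    median: float
    n: int

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low


def aggregate_over_seeds(values) -> SeedAggregate:
    """Mean, Student-t 95% CI and median over per-seed metric values."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise InsufficientReplicatesError("need at least 2 replicate values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    half = float(stats.t.ppf(0.975, values.size - 1)) * sd / np.sqrt(values.size)
    return SeedAggregate(mean, mean - half, mean + half, float(np.median(values)), values.size)


def median_roc(
    curves: list[tuple[np.ndarray, np.ndarray, np.ndarray]], n_grid: int = 101
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise-median TPR over a common FPR grid (the ROC-band convention)."""
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = np.stack([np.interp(grid, fpr, tpr) for fpr, tpr, _ in curves])
    return grid, np.median(tprs, axis=0)
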