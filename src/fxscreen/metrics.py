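"""Native evaluation metrics for binary screening.

Implements the standard confusion-matrix statistics

.. math::

    \\mathrm{Sens} = \\frac{TP}{TP+FN},\\quad
    \\mathrm{Spec} = \\frac{TN}{TN+FP},\\quad
    \\mathrm{Acc} = \\frac{TP+TN}{TP+FP+TN+FN},

    \\mathrm{MCC} = \\frac{TP\\cdot TN - FP\\cdot FN}
        {\\sqrt{(TP+FP)(TP+FN)(TN+FP)(TN+FN)}},\\quad
    F_1 = \\frac{2TP}{2TP+FN+FP},

the ROC curve with trapezoidal AUC (equivalent to the pairwise rank
formulation with ties counted 1/2), the Bayesian positive predictive value
of a screen applied at a population prevalence, and the two-sample t test
from summary statistics (mean, SD, n per group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _scipy_stats

__all__ = [
    "ConfusionMatrix",
    "ScreeningEstimate",
    "SummaryStats",
    "TTestResult",
    "RocCurve",
    "confusion_from_predictions",
    "metrics_from_confusion",
    "roc_curve",
    "roc_auc",
    "screening_ppv",
    "two_sample_t",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts; positives are the carrier class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


def confusion_from_predictions(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> ConfusionMatrix:
    """Build a confusion matrix from 0/1 truth and prediction vectors."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionMatrix(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def metrics_from_confusion(cm: ConfusionMatrix) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, MCC and F1 from a confusion matrix.

    Conventions for degenerate denominators: a metric whose denominator is
    zero is reported as 0.0 (MCC's zero denominator is the continuous limit
    of 0).  An all-zero matrix is an error.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is all zero")
    tp, tn, fp, fn = (float(cm.tp), float(cm.tn), float(cm.fp), float(cm.fn))

    def _div(num: float, den: float) -> float:
        return num / den if den > 0 else 0.0

    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "sensitivity": _div(tp, tp + fn),
        "specificity": _div(tn, tn + fp),
        "accuracy": (tp + tn) / cm.total,
        "mcc": _div(tp * tn - fp * fn, mcc_den),
        "f1": _div(2 * tp, 2 * tp + fn + fp),
    }


@dataclass(frozen=True)
class RocCurve:
    """ROC points (one per distinct threshold, plus the (0,0)/(1,1) ends)."""

    thresholds: tuple[float, ...]
    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    auc: float


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve over all distinct score thresholds, AUC by the trapezoid rule.

    ``scores`` are oriented so larger means more carrier-like; ``labels`` are
    0/1 with 1 the carrier (positive) class.  Tied scores collapse into a
    single threshold, making the trapezoidal AUC equal to the pairwise rank
    statistic with ties counted 1/2.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")

    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    # keep the last point of each tied-score run
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        thresholds=tuple(float(t) for t in thresholds),
        fpr=tuple(float(v) for v in fpr),
        tpr=tuple(float(v) for v in tpr),
        auc=auc,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    return roc_curve(scores, labels).auc


@dataclass(frozen=True)
class ScreeningEstimate:
    """Population-screening yield of a test at a given prevalence.

    ``ppv`` follows Bayes' rule:
    ``sens * prev / (sens * prev + (1 - spec) * (1 - prev))``;
    ``enrichment`` = ppv / prevalence is the fold-reduction in confirmatory
    genetic tests needed per true carrier found.
    """

    sensitivity: float
    specificity: float
    prevalence: float
    ppv: float
    enrichment: float

    @property
    def ppv_percent(self) -> float:
        return 100.0 * self.ppv

    @property
    def prevalence_percent(self) -> float:
        return 100.0 * self.prevalence


def screening_ppv(
    sensitivity: float, specificity: float, prevalence: float
) -> ScreeningEstimate:
    """Positive predictive value of a screen at a population prevalence."""
    if not (0.0 < prevalence < 1.0):
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not (0.0 < v <= 1.0):
            raise ValueError(f"{name} must be in (0, 1], got {v}")
    numerator = sensitivity * prevalence
    denominator = numerator + (1.0 - specificity) * (1.0 - prevalence)
    ppv = numerator / denominator if denominator > 0 else 1.0
    return ScreeningEstimate(
        sensitivity=sensitivity,
        specificity=specificity,
        prevalence=prevalence,
        ppv=ppv,
        enrichment=ppv / prevalence,
    )


@dataclass(frozen=True)
class SummaryStats:
    """Per-group mean, SD and n, as printed in demographic tables."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "SummaryStats":
        arr = np.asarray(values, dtype=float)
        return cls(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=arr.size)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    pooled: bool


def two_sample_t(
    a: SummaryStats | Sequence[float],
    b: SummaryStats | Sequence[float],
    pooled: bool = True,
) -> TTestResult:
    """Independent two-sample t test from summary statistics or raw values.

    ``pooled`` gives the Student (equal-variance) statistic, otherwise Welch
    with Satterthwaite degrees of freedom.  With equal group sizes the two
    statistics coincide.  Zero variance in both groups with equal means is
    reported as t = 0.
    """
    sa = a if isinstance(a, SummaryStats) else SummaryStats.from_values(a)
    sb = b if isinstance(b, SummaryStats) else SummaryStats.from_values(b)
    va, vb = sa.sd**2, sb.sd**2
    diff = sa.mean - sb.mean
    if pooled:
        df = float(sa.n + sb.n - 2)
        sp2 = ((sa.n - 1) * va + (sb.n - 1) * vb) / df
        se = math.sqrt(sp2 * (1.0 / sa.n + 1.0 / sb.n))
    else:
        qa, qb = va / sa.n, vb / sb.n
        se = math.sqrt(qa + qb)
        if qa + qb > 0:
            df = (qa + qb) ** 2 / (qa**2 / (sa.n - 1) + qb**2 / (sb.n - 1))
        else:
            df = float(sa.n + sb.n - 2)
    if se == 0:
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        t = diff / se
    p = float(2.0 * _scipy_stats.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    return TTestResult(t=t, df=df, p=p, pooled=pooled)
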