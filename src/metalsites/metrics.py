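"""Evaluation metrics for the two-class site classifier.

Positive class is "physiological" throughout.  The metric suite is the
standard confusion-matrix family (PPV, TPR, NPV, TNR, FDR, ACC, MCC); metrics
with a zero denominator are reported as undefined (None) rather than 0, so
degenerate folds cannot silently distort averages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .classifier import POSITIVE_CLASS, Prediction

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "ROCCurve",
    "ConfidenceBinReport",
    "confusion",
    "metric_set",
    "roc",
    "confidence_bins",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fn + other.fn,
                               self.fp + other.fp, self.tn + other.tn)


@dataclass(frozen=True)
class MetricSet:
    """Derived metrics; None marks an undefined (zero-denominator) value."""

    ppv: float | None
    tpr: float | None
    npv: float | None
    tnr: float | None
    fdr: float | None
    acc: float
    mcc: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def confusion(predictions: list[Prediction], labels: dict[str, str],
              beta: float = 0.5) -> ConfusionMatrix:
    """Confusion matrix at threshold β (positive call iff p_phys > β)."""
    missing = [p.site_id for p in predictions if p.site_id not in labels]
    if missing:
        raise KeyError(f"labels missing for site ids: {missing[:10]}")
    tp = fn = fp = tn = 0
    for p in predictions:
        called_pos = p.p_physiological > beta
        is_pos = labels[p.site_id] == POSITIVE_CLASS
        if is_pos and called_pos:
            tp += 1
        elif is_pos:
            fn += 1
        elif called_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fn, fp, tn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metric_set(cm: ConfusionMatrix) -> MetricSet:
    """PPV, TPR, NPV, TNR, FDR, ACC and Matthews correlation from counts."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    tpr = _ratio(cm.tp, cm.tp + cm.fn)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    tnr = _ratio(cm.tn, cm.tn + cm.fp)
    fdr = None if ppv is None else 1.0 - ppv
    acc = (cm.tp + cm.tn) / cm.total
    denom = math.sqrt(
        float(cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    mcc = ((cm.tp * cm.tn - cm.fp * cm.fn) / denom) if denom > 0 else None
    return MetricSet(ppv=ppv, tpr=tpr, npv=npv, tnr=tnr, fdr=fdr, acc=acc,
                     mcc=mcc)


@dataclass
class ROCCurve:
    """ROC as the threshold sweep of (1−TNR(β), TPR(β)); AUC by trapezoid."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc(predictions: list[Prediction], labels: dict[str, str]) -> ROCCurve:
    from sklearn.metrics import roc_curve

    y = np.array([labels[p.site_id] == POSITIVE_CLASS for p in predictions])
    if y.all() or not y.any():
        raise ValueError("ROC requires both classes among the labels")
    scores = np.array([p.p_physiological for p in predictions])
    fpr, tpr, thr = roc_curve(y.astype(int), scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


@dataclass
class ConfidenceBinReport:
    """Counts and error rates of predictions binned by confidence.

    Bins are [0,0.1), …, [0.8,0.9), [0.9,1.0] (the last bin closed so a
    confidence of exactly 1 is counted once).  ``high_confidence_*`` report
    the aggregate at/above ``cutoff``.
    """

    edges: np.ndarray
    counts: np.ndarray
    error_rates: list[float | None]
    cutoff: float
    high_confidence_count: int
    high_confidence_error_rate: float | None

    def to_dict(self) -> dict:
        return {
            "edges": self.edges.tolist(),
            "counts": self.counts.tolist(),
            "error_rates": self.error_rates,
            "cutoff": self.cutoff,
            "high_confidence_count": self.high_confidence_count,
            "high_confidence_error_rate": self.high_confidence_error_rate,
        }


def confidence_bins(predictions: list[Prediction], labels: dict[str, str],
                    width: float = 0.1,
                    cutoff: float = 0.85) -> ConfidenceBinReport:
    nbins = round(1.0 / width)
    if abs(nbins * width - 1.0) > 1e-9:
        raise ValueError("bin width must divide 1 evenly")
    conf = np.array([p.confidence for p in predictions])
    wrong = np.array(
        [p.assigned_class != labels[p.site_id] for p in predictions]
    )
    idx = np.minimum((conf / width).astype(int), nbins - 1)
    counts = np.bincount(idx, minlength=nbins)
    error_rates: list[float | None] = []
    for b in range(nbins):
        in_bin = idx == b
        error_rates.append(
            float(wrong[in_bin].mean()) if in_bin.any() else None
        )
    high = conf >= cutoff
    return ConfidenceBinReport(
        edges=np.arange(nbins + 1) * width,
        counts=counts,
        error_rates=error_rates,
        cutoff=cutoff,
        high_confidence_count=int(high.sum()),
        high_confidence_error_rate=(
            float(wrong[high].mean()) if high.any() else None
        ),
    )


def metrics_report(predictions: list[Prediction], labels: dict[str, str],
                   beta: float = 0.5, path: str | Path | None = None) -> dict:
    """Bundle confusion matrix, metric set, AUC and confidence bins as JSON."""
    cm = confusion(predictions, labels, beta)
    report = {
        "confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
        "metrics": metric_set(cm).as_dict(),
        "auc": roc(predictions, labels).auc,
        "confidence_bins": confidence_bins(predictions, labels).to_dict(),
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=1))
    return report
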