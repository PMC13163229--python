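"""Classification metrics for the binary PI-RADS task.

The positive class is high suspicion (PI-RADS 4-5, label 1). Threshold
metrics are derived from the 2×2 confusion matrix by exact arithmetic;
metrics with a zero denominator are reported as ``None`` (undefined), never
silently 0. Ranking metrics (ROC AUC, average precision) follow the standard
threshold-sweep definitions: AUC equals the probability that a random
positive outranks a random negative, counting ties as one half.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import average_precision_score, roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "classification_metrics",
    "roc_curve_auc",
    "average_precision",
    "as_percent",
    "evaluate_scores",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for v in (self.tp, self.tn, self.fp, self.fn):
            if v < 0 or int(v) != v:
                raise ValueError("confusion-matrix cells must be nonnegative integers")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


def confusion_matrix(labels, predictions) -> ConfusionMatrix:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError(f"length mismatch: {labels.shape} vs {predictions.shape}")
    if not (np.isin(labels, (0, 1)).all() and np.isin(predictions, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary (0/1)")
    return ConfusionMatrix(
        tp=int(((labels == 1) & (predictions == 1)).sum()),
        tn=int(((labels == 0) & (predictions == 0)).sum()),
        fp=int(((labels == 0) & (predictions == 1)).sum()),
        fn=int(((labels == 1) & (predictions == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def _prf(tp: int, fp: int, fn: int) -> tuple:
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    per_class: dict
    macro: dict
    weighted: dict
    roc_auc: float | None = None
    average_precision: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """All threshold metrics from a confusion matrix.

    Class 1 (high suspicion) is the positive class; the class-0 row treats
    label 0 as positive. Macro averages are unweighted means over the two
    classes, weighted averages use class support.
    """
    p1, r1, f1_1 = _prf(cm.tp, cm.fp, cm.fn)
    p0, r0, f1_0 = _prf(cm.tn, cm.fn, cm.fp)
    support = {0: cm.negatives, 1: cm.positives}
    per_class = {
        0: {"precision": p0, "recall": r0, "f1": f1_0, "support": support[0]},
        1: {"precision": p1, "recall": r1, "f1": f1_1, "support": support[1]},
    }

    def _avg(key, weights=None):
        vals = [per_class[0][key], per_class[1][key]]
        if any(v is None for v in vals):
            return None
        if weights is None:
            return float(np.mean(vals))
        return float(np.average(vals, weights=weights))

    total = cm.total
    macro = {k: _avg(k) for k in ("precision", "recall", "f1")}
    weighted = {k: _avg(k, weights=[support[0], support[1]]) for k in ("precision", "recall", "f1")}
    return MetricsReport(
        accuracy=(cm.tp + cm.tn) / total,
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        per_class=per_class,
        macro=macro,
        weighted=weighted,
    )


def roc_curve_auc(labels, scores):
    """ROC points over the unique-score threshold sweep and trapezoidal AUC."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("length mismatch between labels and scores")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: both classes must be present")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr, thresholds), auc


def average_precision(labels, scores) -> float:
    """Step-sum average precision in descending score order, ties grouped."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.sum() == 0:
        raise ValueError("average precision undefined: no positive labels")
    return float(average_precision_score(labels, scores))


def as_percent(x: float | None, decimals: int = 1) -> str | None:
    """Format a rate as a percentage, rounding half away from zero."""
    if x is None:
        return None
    q = Decimal(10) ** -decimals
    return f"{Decimal(repr(x * 100)).quantize(q, rounding=ROUND_HALF_UP)}%"


def evaluate_scores(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full report: threshold metrics at ``threshold`` plus ranking metrics."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    cm = confusion_matrix(labels, (scores >= threshold).astype(int))
    report = classification_metrics(cm)
    if len(np.unique(labels)) == 2:
        _, report.roc_auc = roc_curve_auc(labels, scores)
        report.average_precision = average_precision(labels, scores)
    return report


def report_table(report: MetricsReport) -> str:
    """Human-readable per-class table in the conventional layout."""
    lines = [f"{'Class':<16}{'Precision':>10}{'Recall':>10}{'F1':>10}{'Support':>10}"]

    def fmt(v):
        return "undef" if v is None else f"{v:.2f}"

    names = {0: "PI-RADS 2-3", 1: "PI-RADS 4-5"}
    total = sum(report.per_class[c]["support"] for c in (0, 1))
    for c in (0, 1):
        row = report.per_class[c]
        lines.append(f"{names[c]:<16}{fmt(row['precision']):>10}{fmt(row['recall']):>10}{fmt(row['f1']):>10}{row['support']:>10}")
    for name, avg in (("Macro Avg", report.macro), ("Weighted Avg", report.weighted)):
        lines.append(f"{name:<16}{fmt(avg['precision']):>10}{fmt(avg['recall']):>10}{fmt(avg['f1']):>10}{total:>10}")
    lines.append(f"Accuracy: {fmt(report.accuracy)}  Sensitivity: {fmt(report.sensitivity)}  Specificity: {fmt(report.specificity)}")
    return "\n".join(lines)
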