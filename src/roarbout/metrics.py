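"""Confusion matrices and classification metrics.

Metrics follow the four textbook one-vs-rest formulas applied to the
per-class TP/FP/TN/FN counts of a confusion matrix:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1        = 2 * precision * recall / (precision + recall)

Note the accuracy definition is TN-inclusive: for k > 2 classes it
exceeds the plain fraction-correct (trace/total) because every correct
decision also counts as a true negative for the other k-1 classes. Both
are reported — ``accuracy`` (TN-inclusive, as above) and
``trace_accuracy`` (fraction of decisions correct) — so there is no
ambiguity about which is quoted.

Micro averaging pools TP/FP/TN/FN over classes before applying the
formulas; macro averaging is the unweighted mean of the per-class
metrics. Counts may be fractional (e.g. averaged over repeats).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "ClassificationReport", "confusion", "report"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """True-by-predicted counts over an ordered label list."""

    labels: tuple
    counts: np.ndarray  # (k, k), rows = true, cols = predicted

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.float64)
        k = len(self.labels)
        if counts.shape != (k, k):
            raise ValueError("counts must be (k, k) for k labels")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("label sets differ")
        return ConfusionMatrix(self.labels, self.counts + other.counts)

    def scaled(self, factor: float) -> "ConfusionMatrix":
        return ConfusionMatrix(self.labels, self.counts * factor)

    def one_vs_rest(self, label) -> dict[str, float]:
        """TP/FP/TN/FN counts treating ``label`` as the positive class."""
        i = self.labels.index(label)
        tp = self.counts[i, i]
        fn = self.counts[i, :].sum() - tp
        fp = self.counts[:, i].sum() - tp
        tn = self.total - tp - fn - fp
        return {"TP": float(tp), "FP": float(fp), "TN": float(tn), "FN": float(fn)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def confusion(true_labels, predicted_labels, labels=None, weights=None) -> ConfusionMatrix:
    """Accumulate (possibly weighted) counts[t][p] over label pairs.

    ``labels`` declares the class set (defaults to the sorted union);
    an observed label outside it is an error.
    """
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    if labels is None:
        labels = sorted(set(true_labels) | set(predicted_labels))
    labels = tuple(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    if weights is None:
        weights = np.ones(len(true_labels))
    counts = np.zeros((len(labels), len(labels)))
    for t, p, w in zip(true_labels, predicted_labels, weights):
        if t not in index or p not in index:
            unknown = t if t not in index else p
            raise ValueError(f"label {unknown!r} not in declared class set {labels}")
        counts[index[t], index[p]] += w
    return ConfusionMatrix(labels, counts)


def _four_metrics(tp: float, fp: float, tn: float, fn: float) -> dict[str, float]:
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total if total else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision = 0.0
        log.info("no positive predictions; precision set to 0")
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return {"accuracy": accuracy, "recall": recall, "precision": precision, "f1": f1}


@dataclass(frozen=True)
class ClassificationReport:
    """Per-class, micro and macro metrics of one confusion matrix."""

    cm: ConfusionMatrix
    per_class: dict
    micro: dict
    macro: dict
    trace_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        rows = {str(lab): m for lab, m in self.per_class.items()}
        rows["micro"] = self.micro
        rows["macro"] = self.macro
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        frame = self.to_frame()
        lines = [
            "Classification report",
            "=" * 60,
            frame.to_string(float_format=lambda v: f"{v:.4f}"),
            "",
            f"trace accuracy (fraction correct): {self.trace_accuracy:.4f}",
            "",
            "confusion matrix (true x predicted):",
            self.cm.to_frame().to_string(float_format=lambda v: f"{v:.2f}"),
        ]
        return "\n".join(lines)


def report(cm: ConfusionMatrix) -> ClassificationReport:
    """Apply the four metric formulas per class, micro- and macro-averaged."""
    if cm.total <= 0:
        raise ValueError("confusion matrix is all zero")
    per_class = {
        lab: _four_metrics(*(cm.one_vs_rest(lab)[k] for k in ("TP", "FP", "TN", "FN")))
        for lab in cm.labels
    }
    pooled = {key: sum(cm.one_vs_rest(lab)[key] for lab in cm.labels)
              for key in ("TP", "FP", "TN", "FN")}
    micro = _four_metrics(pooled["TP"], pooled["FP"], pooled["TN"], pooled["FN"])
    macro = {
        name: float(np.mean([per_class[lab][name] for lab in cm.labels]))
        for name in ("accuracy", "recall", "precision", "f1")
    }
    trace = float(np.trace(cm.counts) / cm.total)
    return ClassificationReport(cm=cm, per_class=per_class, micro=micro, macro=macro,
                                trace_accuracy=trace)
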