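"""Confusion matrices and classification metrics.

Instance-level predictions (mapped dominant clusters) are compared with the
clinician-assigned MDS-UPDRS 3.17 labels. Binary tasks report accuracy,
precision = TP/(TP+FP), recall = TP/(TP+FN) and the F1 harmonic mean for a
stated positive class; multiclass tasks report one-vs-rest metrics per
score plus their unweighted (macro) averages. A precision or recall whose
denominator is zero is reported as 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


def confusion_matrix(
    truth: Sequence[int] | np.ndarray,
    predicted: Sequence[int] | np.ndarray,
    classes: Sequence[int],
) -> np.ndarray:
    """Count matrix with entry (a, b) = instances with true a, predicted b."""
    truth = np.asarray(truth).ravel()
    predicted = np.asarray(predicted).ravel()
    if truth.size != predicted.size:
        raise ValueError("truth and predicted must have equal length")
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for a, b in zip(truth, predicted):
        if a not in index or b not in index:
            raise ValueError(f"label pair ({a}, {b}) outside classes {classes}")
        cm[index[a], index[b]] += 1
    return cm


@dataclass(frozen=True)
class BinaryMetrics:
    """Accuracy/precision/recall/F1 for one positive class."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    precision_defined: bool = True
    recall_defined: bool = True


def _safe_ratio(num: int, den: int) -> tuple[float, bool]:
    return (num / den, True) if den > 0 else (0.0, False)


def _f1(precision: float, recall: float) -> float:
    return 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)


def binary_metrics(
    confusion: np.ndarray, classes: Sequence[int], positive: int
) -> BinaryMetrics:
    """Metrics of a 2-class confusion matrix for the stated positive class."""
    cm = np.asarray(confusion)
    classes = list(classes)
    if cm.shape != (2, 2) or len(classes) != 2:
        raise ValueError("binary_metrics requires a 2x2 confusion matrix")
    p = classes.index(positive)
    n = 1 - p
    tp, fn = int(cm[p, p]), int(cm[p, n])
    fp, tn = int(cm[n, p]), int(cm[n, n])
    total = tp + tn + fp + fn
    precision, p_def = _safe_ratio(tp, tp + fp)
    recall, r_def = _safe_ratio(tp, tp + fn)
    return BinaryMetrics(
        accuracy=(tp + tn) / total,
        precision=precision,
        recall=recall,
        f1=_f1(precision, recall),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        precision_defined=p_def,
        recall_defined=r_def,
    )


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics for a single score."""

    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    support: int
    precision_defined: bool = True
    recall_defined: bool = True


@dataclass(frozen=True)
class EvaluationReport:
    """Full evaluation of one classification task."""

    classes: tuple[int, ...]
    confusion: np.ndarray = field(repr=False)
    accuracy: float
    per_class: Mapping[int, ClassMetrics]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    task: int | None = None

    @property
    def n_instances(self) -> int:
        return int(np.asarray(self.confusion).sum())

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "classes": list(self.classes),
            "confusion": np.asarray(self.confusion).tolist(),
            "n_instances": self.n_instances,
            "accuracy": self.accuracy,
            "per_class": {
                str(c): {
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "tp": m.tp,
                    "fp": m.fp,
                    "fn": m.fn,
                    "support": m.support,
                    "precision_defined": m.precision_defined,
                    "recall_defined": m.recall_defined,
                }
                for c, m in self.per_class.items()
            },
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
        }

    def summary(self) -> str:
        """Human-readable report, metrics rendered at two decimals."""
        lines = []
        head = f"Evaluation ({self.n_instances} instances"
        head += f", task {self.task})" if self.task is not None else ")"
        lines.append(head)
        lines.append(f"accuracy: {self.accuracy:.2f}")
        lines.append("class  precision  recall  f1  support")
        for c in self.classes:
            m = self.per_class[c]
            flag = "" if m.precision_defined and m.recall_defined else "  (undefined->0)"
            lines.append(
                f"{c:>5}  {m.precision:9.2f}  {m.recall:6.2f}  {m.f1:.2f}  {m.support:7d}{flag}"
            )
        lines.append(
            f"macro  {self.macro_precision:9.2f}  {self.macro_recall:6.2f}  {self.macro_f1:.2f}"
        )
        return "\n".join(lines)


def multiclass_metrics(
    confusion: np.ndarray, classes: Sequence[int], task: int | None = None
) -> EvaluationReport:
    """One-vs-rest per-class metrics with unweighted macro averages."""
    cm = np.asarray(confusion)
    classes = list(classes)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.shape[0] != len(classes):
        raise ValueError("confusion must be square and aligned with classes")
    total = int(cm.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict[int, ClassMetrics] = {}
    for i, c in enumerate(classes):
        tp = int(cm[i, i])
        fp = int(cm[:, i].sum() - tp)
        fn = int(cm[i, :].sum() - tp)
        precision, p_def = _safe_ratio(tp, tp + fp)
        recall, r_def = _safe_ratio(tp, tp + fn)
        per_class[c] = ClassMetrics(
            precision=precision,
            recall=recall,
            f1=_f1(precision, recall),
            tp=tp,
            fp=fp,
            fn=fn,
            support=tp + fn,
            precision_defined=p_def,
            recall_defined=r_def,
        )
    return EvaluationReport(
        classes=tuple(classes),
        confusion=cm,
        accuracy=float(np.trace(cm) / total),
        per_class=per_class,
        macro_precision=float(np.mean([m.precision for m in per_class.values()])),
        macro_recall=float(np.mean([m.recall for m in per_class.values()])),
        macro_f1=float(np.mean([m.f1 for m in per_class.values()])),
        task=task,
    )


def plot_confusion(report: EvaluationReport, ax=None):
    """Heatmap of the confusion matrix (presentation only)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    cm = np.asarray(report.confusion)
    ax.imshow(cm, cmap="Blues")
    for (i, j), v in np.ndenumerate(cm):
        ax.text(j, i, str(v), ha="center", va="center")
    ax.set_xticks(range(len(report.classes)), report.classes)
    ax.set_yticks(range(len(report.classes)), report.classes)
    ax.set_xlabel("predicted score")
    ax.set_ylabel("true score")
    if report.task is not None:
        ax.set_title(f"Task {report.task} (accuracy {report.accuracy:.2f})")
    return ax
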