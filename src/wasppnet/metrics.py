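"""Classification metrics: accuracy, precision, recall, F1.

For a one-vs-rest view of a class, with true/false positive/negative
tallies ``TP, TN, FP, FN`` over ``Ts`` total samples:

    accuracy  Ac = (TP + TN) / Ts
    precision Pr = TP / (TP + FP)
    recall    Re = TP / (TP + FN)
    F1           = 2 * Pr * Re / (Pr + Re)

A 0/0 precision, recall or F1 resolves to 0 (with a warning), so a
perfect classifier scores F1 = 1 and one with zero precision or recall
scores F1 = 0.  The multi-class report evaluates each class one-vs-rest
and aggregates both ways: macro (unweighted mean over classes, the
headline figure, matching the micro-expression community's unweighted-F1
convention) and micro (pooled counts over classes).
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_from_predictions",
           "accuracy", "precision_recall_f1", "multiclass_report",
           "UndefinedMetricError"]


class UndefinedMetricError(ZeroDivisionError):
    pass


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion tallies."""
    t_pos: int
    t_neg: int
    f_pos: int
    f_neg: int

    def __post_init__(self):
        if min(self.t_pos, self.t_neg, self.f_pos, self.f_neg) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def ts(self) -> int:
        return self.t_pos + self.t_neg + self.f_pos + self.f_neg

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.t_pos + other.t_pos,
                               self.t_neg + other.t_neg,
                               self.f_pos + other.f_pos,
                               self.f_neg + other.f_neg)


@dataclasses.dataclass
class MetricsReport:
    """Overall accuracy plus per-class and aggregated Pr/Re/F1."""
    accuracy: float
    classes: list
    per_class: dict          # label -> {precision, recall, f1, support}
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    def to_rows(self) -> list[dict]:
        """CSV-friendly rows: one per class plus macro/micro aggregates."""
        rows = []
        for label in self.classes:
            entry = self.per_class[label]
            rows.append({"class": str(label), **entry})
        rows.append({"class": "macro", "precision": self.macro_precision,
                     "recall": self.macro_recall, "f1": self.macro_f1,
                     "support": sum(self.per_class[c]["support"]
                                    for c in self.classes)})
        rows.append({"class": "micro", "precision": self.micro_precision,
                     "recall": self.micro_recall, "f1": self.micro_f1,
                     "support": sum(self.per_class[c]["support"]
                                    for c in self.classes)})
        return rows


def confusion_from_predictions(true_labels, predicted_labels,
                               class_id) -> ConfusionCounts:
    """One-vs-rest confusion counts treating ``class_id`` as positive."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    tpos = t == class_id
    ppos = p == class_id
    return ConfusionCounts(
        t_pos=int(np.sum(tpos & ppos)),
        t_neg=int(np.sum(~tpos & ~ppos)),
        f_pos=int(np.sum(~tpos & ppos)),
        f_neg=int(np.sum(tpos & ~ppos)),
    )


def accuracy(c: ConfusionCounts) -> float:
    if c.ts == 0:
        raise UndefinedMetricError("accuracy undefined for zero samples")
    return (c.t_pos + c.t_neg) / c.ts


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} is 0/0; returning 0", stacklevel=3)
        return 0.0
    return num / den


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    pr = _safe_div(c.t_pos, c.t_pos + c.f_pos, "precision")
    re = _safe_div(c.t_pos, c.t_pos + c.f_neg, "recall")
    f1 = _safe_div(2.0 * pr * re, pr + re, "F1")
    return pr, re, f1


def multiclass_report(true_labels, predicted_labels) -> MetricsReport:
    """Overall accuracy plus one-vs-rest Pr/Re/F1 per class with macro
    and micro aggregation.

    Classes are the sorted union of labels appearing in either vector.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.size == 0:
        raise ValueError("empty label vectors")
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    classes = sorted(set(t.tolist()) | set(p.tolist()))
    per_class = {}
    pooled = ConfusionCounts(0, 0, 0, 0)
    macro = np.zeros(3)
    for label in classes:
        c = confusion_from_predictions(t, p, label)
        pr, re, f1 = precision_recall_f1(c)
        per_class[label] = {"precision": pr, "recall": re, "f1": f1,
                            "support": int(np.sum(t == label))}
        pooled = pooled + c
        macro += (pr, re, f1)
    macro /= len(classes)
    mpr, mre, mf1 = precision_recall_f1(pooled)
    return MetricsReport(
        accuracy=float(np.mean(t == p)),
        classes=classes,
        per_class=per_class,
        macro_precision=float(macro[0]),
        macro_recall=float(macro[1]),
        macro_f1=float(macro[2]),
        micro_precision=mpr,
        micro_recall=mre,
        micro_f1=mf1,
    )
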