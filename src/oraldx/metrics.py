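"""Classification indicators: precision, recall, accuracy, F1.

Counts are one-vs-rest per class; precision and recall are macro-averaged
over the classes present, accuracy pools the per-class tables, and F1 is
the harmonic mean of the macro precision and recall.  Division-by-zero
terms are defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class ClassCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts per class label."""

    per_class: dict

    @property
    def n_classes(self) -> int:
        return len(self.per_class)


def confusion(y_true, y_pred, labels=None) -> ConfusionCounts:
    """One-vs-rest confusion counts for each class label.

    ``labels`` fixes the class set (and order); passing a subset restricts
    the report to those one-vs-rest tables (anything else counts as
    "rest").  By default the classes are the sorted union of the true
    labels, and a prediction outside that set raises an input error.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if labels is None:
        classes = sorted(set(y_true))
        known = set(classes)
        for v in y_pred:
            if v not in known:
                raise ValueError(
                    f"prediction label {v!r} outside known classes {classes}"
                )
    else:
        classes = list(labels)
    per_class = {}
    for cls in classes:
        c = ClassCounts()
        for t, p in zip(y_true, y_pred):
            if t == cls and p == cls:
                c.tp += 1
            elif t == cls:
                c.fn += 1
            elif p == cls:
                c.fp += 1
            else:
                c.tn += 1
        per_class[cls] = c
    return ConfusionCounts(per_class=per_class)


@dataclass
class MetricsReport:
    precision: float
    recall: float
    accuracy: float
    f1: float

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "f1": self.f1,
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Macro precision/recall, pooled accuracy, F1 of the macro pair."""
    if counts.n_classes == 0:
        raise ValueError("no classes in confusion counts")
    precisions, recalls = [], []
    num_acc = den_acc = 0
    for c in counts.per_class.values():
        precisions.append(_safe_div(c.tp, c.tp + c.fp))
        recalls.append(_safe_div(c.tp, c.tp + c.fn))
        num_acc += c.tp + c.tn
        den_acc += c.tp + c.tn + c.fp + c.fn
    precision = sum(precisions) / len(precisions)
    recall = sum(recalls) / len(recalls)
    accuracy = _safe_div(num_acc, den_acc)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    return MetricsReport(precision=precision, recall=recall, accuracy=accuracy, f1=f1)
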