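"""Classification evaluation: per-class precision / recall / F1 / support,
overall accuracy and macro / weighted averages.

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)
    accuracy  = successful cases / total cases

0/0 is defined as 0 (with a warning); the averages follow the usual
conventions: macro = unweighted class mean, weighted = support-weighted
mean, so weighted recall equals overall accuracy on a full confusion
matrix.  Reports are emitted as a DataFrame, CSV, or a pretty text table
with columns Precision / Recall / F1-Score / Support / % Accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix
from sklearn.metrics import precision_recall_fscore_support as _sk_prfs

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "precision_recall_f1",
    "accuracy",
    "classification_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class true-positive / false-positive / false-negative counts."""

    classes: tuple
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    n: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            arr = np.asarray(getattr(self, name))
            if np.any(arr < 0):
                raise ValueError(f"{name} counts must be non-negative")
            object.__setattr__(self, name, arr.astype(int))
        if int(self.tp.sum()) > self.n:
            raise ValueError("sum of true positives exceeds the instance count")

    @classmethod
    def from_labels(cls, y_true, y_pred, classes=None) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if len(y_true) != len(y_pred):
            raise ValueError("label sequences have different lengths")
        if classes is None:
            classes = np.unique(np.concatenate([y_true, y_pred]))
        classes = np.asarray(classes)
        cm = _sk_confusion_matrix(y_true, y_pred, labels=classes)
        tp = np.diag(cm)
        return cls(
            classes=tuple(classes.tolist()),
            tp=tp,
            fp=cm.sum(axis=0) - tp,
            fn=cm.sum(axis=1) - tp,
            n=len(y_true),
        )


def _safe_div(num: float, den: float) -> float:
    if den == 0:
        if num != 0:
            raise ValueError("inconsistent counts")
        warnings.warn("0/0 metric encountered; defined as 0", stacklevel=3)
        return 0.0
    return num / den


def precision_recall_f1(counts: ConfusionCounts, cls) -> tuple[float, float, float]:
    """Precision, recall and F1 for one class, with the 0/0 -> 0 convention."""
    try:
        i = counts.classes.index(cls)
    except ValueError as err:
        raise KeyError(f"class {cls!r} not in the class set") from err
    tp, fp, fn = int(counts.tp[i]), int(counts.fp[i]), int(counts.fn[i])
    p = _safe_div(tp, tp + fp)
    r = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * p * r, p + r) if (p + r) else 0.0
    return p, r, f1


def accuracy(n_success: int, n_total: int) -> float:
    """Fraction of successful recognition cases (0..1)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_success <= n_total):
        raise ValueError("n_success must lie in [0, n_total]")
    return n_success / n_total


@dataclass
class EvalReport:
    """Per-class metric table plus the overall / macro / weighted summary."""

    table: pd.DataFrame  # columns: class, precision, recall, f1, support
    accuracy: float
    macro: tuple[float, float, float]
    weighted: tuple[float, float, float]

    @property
    def n(self) -> int:
        return int(self.table["support"].sum())

    def to_csv(self, path) -> None:
        df = self.table.copy()
        summary = pd.DataFrame(
            [
                {"class": "accuracy", "precision": np.nan, "recall": np.nan,
                 "f1": self.accuracy, "support": self.n},
                {"class": "macro avg", "precision": self.macro[0],
                 "recall": self.macro[1], "f1": self.macro[2], "support": self.n},
                {"class": "weighted avg", "precision": self.weighted[0],
                 "recall": self.weighted[1], "f1": self.weighted[2],
                 "support": self.n},
            ]
        )
        pd.concat([df, summary], ignore_index=True).to_csv(path, index=False)

    def to_text(self) -> str:
        lines = [f"{'Class':>12}  {'Precision':>9}  {'Recall':>7}  "
                 f"{'F1-Score':>8}  {'Support':>7}"]
        for _, row in self.table.iterrows():
            lines.append(
                f"{str(row['class']):>12}  {row['precision']:>9.2f}  "
                f"{row['recall']:>7.2f}  {row['f1']:>8.2f}  "
                f"{int(row['support']):>7d}"
            )
        lines.append(f"{'Accuracy':>12}  {'':>9}  {'':>7}  "
                     f"{self.accuracy:>8.2f}  {self.n:>7d}"
                     f"   ({100.0 * self.accuracy:.1f}% Accuracy)")
        lines.append(f"{'Macro Avg.':>12}  {self.macro[0]:>9.2f}  "
                     f"{self.macro[1]:>7.2f}  {self.macro[2]:>8.2f}  {self.n:>7d}")
        lines.append(f"{'Weighted Avg.':>13}  {self.weighted[0]:>8.2f}  "
                     f"{self.weighted[1]:>7.2f}  {self.weighted[2]:>8.2f}  "
                     f"{self.n:>7d}")
        return "\n".join(lines)


def classification_report(y_true, y_pred, classes=None) -> EvalReport:
    """Full evaluation report from true/predicted label sequences.

    ``classes`` fixes the row order (default: sorted union of labels).
    Pure: identical inputs produce identical reports.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences have different lengths")
    if len(y_true) == 0:
        raise ValueError("empty label sequences")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn's own zero-division notice
        p, r, f1, support = _sk_prfs(
            y_true, y_pred, labels=classes, zero_division=0
        )
    table = pd.DataFrame(
        {"class": classes, "precision": p, "recall": r, "f1": f1,
         "support": support.astype(int)}
    )
    acc = float((y_true == y_pred).mean())
    macro = (float(p.mean()), float(r.mean()), float(f1.mean()))
    total = support.sum()
    if total == 0:
        raise ValueError("no true instances in the class set")
    w = support / total
    weighted = (float(p @ w), float(r @ w), float(f1 @ w))
    return EvalReport(table=table, accuracy=acc, macro=macro, weighted=weighted)
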