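"""Confusion-matrix bookkeeping and AUROC.

The confusion table convention follows the source tables this package
reproduces: rows are actual classes, columns predicted.  In those tables
"PRECISION" is the row-wise diagonal ratio and "RECALL" the column-wise one —
the reverse of the conventional naming.  Both the table-verbatim names
(:func:`row_precision` / :func:`col_recall`) and the conventional aliases
(:func:`recall_conventional` / :func:`precision_conventional`) are exposed.

Reported percentages round half-up to the printed number of decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import rankdata


class UndefinedMetricError(ValueError):
    """A ratio with an empty denominator (zero row/column/total)."""


@dataclass
class ConfusionMatrix:
    counts: np.ndarray          # K x K, rows = actual, cols = predicted
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match class_names")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index(self, cls: str) -> int:
        try:
            return self.class_names.index(cls)
        except ValueError:
            raise KeyError(f"unknown class {cls!r}") from None

    def to_markdown(self) -> str:
        names = self.class_names
        header = "| Actual \\ Predicted | " + " | ".join(names) + " | PRECISION (%) |"
        sep = "|" + "---|" * (len(names) + 2)
        lines = [header, sep]
        for i, name in enumerate(names):
            cells = " | ".join(str(int(c)) for c in self.counts[i])
            try:
                prec = f"{row_precision(self, name):.2f}"
            except UndefinedMetricError:
                prec = "-"
            lines.append(f"| {name} | {cells} | {prec} |")
        recalls = []
        for name in names:
            try:
                recalls.append(f"{col_recall(self, name):.2f}")
            except UndefinedMetricError:
                recalls.append("-")
        lines.append("| RECALL (%) | " + " | ".join(recalls) + " | |")
        return "\n".join(lines)


def confusion(y_true, y_pred, classes: list[str]) -> ConfusionMatrix:
    """Count table counts[i][j] = #(actual=classes[i], predicted=classes[j])."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    lut = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in lut or p not in lut:
            bad = t if t not in lut else p
            raise ValueError(f"label {bad!r} not in class list {classes}")
        counts[lut[t], lut[p]] += 1
    return ConfusionMatrix(counts=counts, class_names=list(classes))


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal round-half-up, matching how the reproduced tables print."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def row_precision(cm: ConfusionMatrix, cls: str, decimals: int = 2) -> float:
    """Diagonal over row sum, as a percent (table 'PRECISION' convention)."""
    i = cm.index(cls)
    row = cm.counts[i].sum()
    if row == 0:
        raise UndefinedMetricError(f"row {cls!r} has no instances")
    return round_half_up(100.0 * cm.counts[i, i] / row, decimals)


def col_recall(cm: ConfusionMatrix, cls: str, decimals: int = 2) -> float:
    """Diagonal over column sum, as a percent (table 'RECALL' convention)."""
    i = cm.index(cls)
    col = cm.counts[:, i].sum()
    if col == 0:
        raise UndefinedMetricError(f"column {cls!r} has no predictions")
    return round_half_up(100.0 * cm.counts[i, i] / col, decimals)


# Conventional naming (precision = over predictions, recall = over actuals):
def precision_conventional(cm: ConfusionMatrix, cls: str, decimals: int = 2) -> float:
    return col_recall(cm, cls, decimals)


def recall_conventional(cm: ConfusionMatrix, cls: str, decimals: int = 2) -> float:
    return row_precision(cm, cls, decimals)


def accuracy(cm: ConfusionMatrix, decimals: int = 2) -> float:
    """Trace over total, as a percent."""
    if cm.total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    return round_half_up(100.0 * np.trace(cm.counts) / cm.total, decimals)


def auroc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties 1/2).

    Mann-Whitney rank form; ``labels`` are truthy for positives.  Returns a
    fraction in [0, 1].
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def metrics_report(cm: ConfusionMatrix) -> dict:
    """Per-class table metrics plus overall accuracy, JSON-serializable."""
    report = {"classes": cm.class_names, "counts": cm.counts.tolist(),
              "accuracy_pct": accuracy(cm), "per_class": {}}
    for name in cm.class_names:
        entry = {}
        try:
            entry["precision_pct"] = row_precision(cm, name)
        except UndefinedMetricError:
            entry["precision_pct"] = None
        try:
            entry["recall_pct"] = col_recall(cm, name)
        except UndefinedMetricError:
            entry["recall_pct"] = None
        report["per_class"][name] = entry
    return report
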