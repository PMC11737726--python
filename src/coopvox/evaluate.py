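"""Confusion matrices and one-vs-rest classification metrics.

Counts are tabulated with actual classes in rows and predicted classes in
columns, in the fixed order C1..C6. Per class i, TP = counts[i][i],
FN = row_i - TP, FP = col_i - TP, TN = total - TP - FN - FP, and

    precision = TP/(TP+FP)   recall = TP/(TP+FN)
    F1 = 2PR/(P+R)           FPR = FP/(FP+TN)

with overall (micro) accuracy = trace/total. A zero denominator yields 0
and raises a flag instead of an exception, so degenerate validation splits
report cleanly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import CLASS_ORDER, VocalClass

DEFAULT_CLASS_ORDER: tuple[str, ...] = tuple(c.name for c in CLASS_ORDER)
METRIC_NAMES = ("precision", "recall", "f1", "fpr")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray                       # rows = actual, cols = predicted
    class_order: tuple[str, ...] = DEFAULT_CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_order,
                            columns=self.class_order)


@dataclass
class ClassMetrics:
    """Per-class and aggregate metrics; ``flags`` lists (class, metric)
    pairs whose denominator was zero (value reported as 0)."""

    per_class: pd.DataFrame                  # index class, cols METRIC_NAMES
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_accuracy: float
    flags: list[tuple[str, str]] = field(default_factory=list)


def _name(label) -> str:
    return label.name if isinstance(label, VocalClass) else str(label)


def build_confusion(labels, predictions,
                    class_order: tuple[str, ...] = DEFAULT_CLASS_ORDER
                    ) -> ConfusionMatrix:
    """Tally counts[i][j] = #(actual = class i, predicted = class j)."""
    if len(labels) != len(predictions):
        raise ValueError("labels and predictions differ in length")
    lut = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for a, p in zip(labels, predictions):
        a, p = _name(a), _name(p)
        if a not in lut or p not in lut:
            raise ValueError(f"label outside class order: {a!r} / {p!r}")
        counts[lut[a], lut[p]] += 1
    return ConfusionMatrix(counts, tuple(class_order))


def _safe_div(num: float, den: float, cls: str, metric: str,
              flags: list[tuple[str, str]]) -> float:
    if den == 0:
        flags.append((cls, metric))
        return 0.0
    return num / den


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """One-vs-rest precision/recall/F1/FPR per class plus aggregates."""
    m = cm.counts.astype(float)
    total = m.sum()
    flags: list[tuple[str, str]] = []
    rows = {}
    for i, cls in enumerate(cm.class_order):
        tp = m[i, i]
        fn = m[i].sum() - tp
        fp = m[:, i].sum() - tp
        tn = total - tp - fn - fp
        p = _safe_div(tp, tp + fp, cls, "precision", flags)
        r = _safe_div(tp, tp + fn, cls, "recall", flags)
        f1 = _safe_div(2 * p * r, p + r, cls, "f1", flags)
        fpr = _safe_div(fp, fp + tn, cls, "fpr", flags)
        rows[cls] = {"precision": p, "recall": r, "f1": f1, "fpr": fpr}
    per_class = pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]
    acc = float(np.trace(m) / total) if total > 0 else 0.0
    return ClassMetrics(
        per_class=per_class,
        accuracy=acc,
        macro_precision=float(per_class["precision"].mean()),
        macro_recall=float(per_class["recall"].mean()),
        macro_f1=float(per_class["f1"].mean()),
        micro_accuracy=acc,
        flags=flags,
    )


def round_half_away(x: float, decimals: int = 3) -> float:
    """Round half away from zero (the convention of the reference tables)."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def compare_to_reference(metrics: ClassMetrics, reference: pd.DataFrame,
                         tolerance: float = 5e-4) -> pd.DataFrame:
    """Cell-by-cell comparison of computed metrics against a reference
    table (same class index, columns from METRIC_NAMES). Computed values
    are rounded half-away-from-zero to 3 decimals before the |diff| <=
    tolerance check. Returns a long-form report with a ``passed`` column.
    """
    if set(reference.index) != set(metrics.per_class.index):
        raise ValueError("reference and computed metrics cover different classes")
    records = []
    for cls in metrics.per_class.index:
        for metric in reference.columns:
            computed = float(metrics.per_class.loc[cls, metric])
            rounded = round_half_away(computed, 3)
            ref = float(reference.loc[cls, metric])
            records.append({
                "class": cls, "metric": metric, "computed": computed,
                "rounded": rounded, "reference": ref,
                "passed": abs(rounded - ref) <= tolerance,
            })
    return pd.DataFrame.from_records(records)
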