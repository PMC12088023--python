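"""Confusion matrix and binary-classification metrics, malignant positive.

The five reported metrics are

    Accuracy  = (TP + TN) / (TP + TN + FP + FN)
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    F1        = 2 · Precision · Recall / (Precision + Recall)
    MCC       = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

computed in exact rational/integer arithmetic and only then rounded, and
reported as percentages to two decimals. Malignant is the positive class
throughout; evaluation is image-level (each fused whole-image prediction is
one unit).

Degenerate denominators follow standard conventions (precision with
TP+FP = 0 → 0, recall with TP+FN = 0 → 0, F1 with both undefined → 0, MCC
with any zero factor under the root → 0) and log a warning when triggered.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd

from .types import Label

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts with malignant as the positive class."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    """The five headline metrics, as percentages rounded to 2 decimals."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    n: int
    magnification: Optional[str] = None
    strategy: str = ""


def _as_label(x) -> Label:
    return x if isinstance(x, Label) else Label(str(x))


def confusion(true_labels: Sequence, predicted_labels: Sequence) -> ConfusionMatrix:
    """Exact confusion counts; malignant is positive."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"label list lengths differ: {len(true_labels)} vs "
            f"{len(predicted_labels)}"
        )
    tp = fp = tn = fn = 0
    for t, p in zip(true_labels, predicted_labels):
        t, p = _as_label(t), _as_label(p)
        if t is Label.MALIGNANT:
            if p is Label.MALIGNANT:
                tp += 1
            else:
                fn += 1
        else:
            if p is Label.MALIGNANT:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(TP=tp, FP=fp, TN=tn, FN=fn)


def _round2_percent(x: Fraction) -> float:
    """Round an exact fraction (on the 0–1 scale) to a 2-decimal percent,
    half away from zero."""
    scaled = x * 10000  # percent with 2 decimals
    if scaled >= 0:
        q = (scaled + Fraction(1, 2)).__floor__()
    else:
        q = -((-scaled + Fraction(1, 2)).__floor__())
    return q / 100.0


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP+TN)/(TP+TN+FP+FN) as a percent."""
    if cm.total == 0:
        logger.warning("accuracy of an empty confusion matrix → 0 by convention")
        return 0.0
    return _round2_percent(Fraction(cm.TP + cm.TN, cm.total))


def precision(cm: ConfusionMatrix) -> float:
    """TP/(TP+FP) as a percent; 0 when no positive predictions exist."""
    if cm.TP + cm.FP == 0:
        logger.warning("precision with TP+FP=0 → 0 by convention")
        return 0.0
    return _round2_percent(Fraction(cm.TP, cm.TP + cm.FP))


def recall(cm: ConfusionMatrix) -> float:
    """TP/(TP+FN) as a percent; 0 when no positives exist."""
    if cm.TP + cm.FN == 0:
        logger.warning("recall with TP+FN=0 → 0 by convention")
        return 0.0
    return _round2_percent(Fraction(cm.TP, cm.TP + cm.FN))


def f1(cm: ConfusionMatrix) -> float:
    """Harmonic mean of precision and recall as a percent.

    Simplifies to 2·TP / (2·TP + FP + FN), which stays exact-rational.
    """
    denom = 2 * cm.TP + cm.FP + cm.FN
    if denom == 0:
        logger.warning("F1 with TP=FP=FN=0 → 0 by convention")
        return 0.0
    return _round2_percent(Fraction(2 * cm.TP, denom))


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient as a percent in [−100, 100].

    The numerator TP·TN − FP·FN and the product under the root are exact
    integers; the square root is the only irrational step, taken at float
    precision on the exact product.
    """
    prod = (
        (cm.TP + cm.FP) * (cm.TP + cm.FN) * (cm.TN + cm.FP) * (cm.TN + cm.FN)
    )
    if prod == 0:
        logger.warning("MCC with a zero factor under the root → 0 by convention")
        return 0.0
    num = cm.TP * cm.TN - cm.FP * cm.FN
    value = num / math.sqrt(prod)  # in [-1, 1]
    return round(value * 100.0, 2)


def evaluate(
    predictions: Sequence,
    magnification: Optional[str] = None,
    strategy: str = "",
) -> MetricsReport:
    """Compose the confusion matrix and the five metrics over fused
    image-level predictions."""
    cm = confusion(
        [p.true_label for p in predictions],
        [p.predicted_label for p in predictions],
    )
    return report_from_confusion(cm, magnification=magnification, strategy=strategy)


def report_from_confusion(
    cm: ConfusionMatrix,
    magnification: Optional[str] = None,
    strategy: str = "",
) -> MetricsReport:
    """All five metrics from explicit counts."""
    return MetricsReport(
        accuracy=accuracy(cm),
        precision=precision(cm),
        recall=recall(cm),
        f1=f1(cm),
        mcc=mcc(cm),
        n=cm.total,
        magnification=magnification,
        strategy=strategy,
    )


INDICATORS = ("accuracy", "precision", "recall", "f1", "mcc")


def reports_frame(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Long-form DataFrame of an indicator × magnification × strategy grid."""
    rows = []
    for r in reports:
        for ind in INDICATORS:
            rows.append(
                {
                    "indicator": ind,
                    "strategy": r.strategy,
                    "magnification": r.magnification or "all",
                    "value": getattr(r, ind),
                    "n": r.n,
                }
            )
    return pd.DataFrame(rows)


def render_report(reports: Sequence[MetricsReport], path, fmt: str = "csv") -> Path:
    """Emit an indicator × magnification grid as CSV or Markdown."""
    path = Path(path)
    df = reports_frame(reports)
    grid = df.pivot_table(
        index=["indicator", "strategy"],
        columns="magnification",
        values="value",
        sort=False,
    )
    if fmt == "csv":
        grid.to_csv(path)
    elif fmt == "markdown":
        path.write_text(grid.to_markdown())
    else:
        raise ValueError(f"unknown report format: {fmt!r}")
    return path
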