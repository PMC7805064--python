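"""Confusion-matrix bookkeeping and the six reported metrics.

Positive class is DILI throughout. Any metric whose denominator is zero is
reported as 0 and flagged rather than NaN, so reports stay numeric on
degenerate inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "f1", "mcc")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, sensitivity, specificity, F1 and MCC.

    Zero-denominator cases yield 0.0 with the metric name recorded under
    the "zero_denominator" key.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total == 0:
        raise ValueError("empty confusion table")
    flagged = []

    def ratio(num, den, name):
        if den == 0:
            flagged.append(name)
            return 0.0
        return num / den

    out = {
        "accuracy": (tp + tn) / counts.total,
        "precision": ratio(tp, tp + fp, "precision"),
        "sensitivity": ratio(tp, tp + fn, "sensitivity"),
        "specificity": ratio(tn, tn + fp, "specificity"),
    }
    out["f1"] = ratio(2 * tp, 2 * tp + fp + fn, "f1")
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    out["mcc"] = ratio(tp * tn - fp * fn, mcc_den, "mcc")
    out["zero_denominator"] = flagged
    return out


def evaluate_model(
    probabilities: dict[str, float], labels: dict[str, bool], threshold: float = 0.5
) -> tuple[ConfusionCounts, dict[str, float]]:
    """Confusion counts and metrics from per-drug DILI probabilities."""
    unknown = [d for d in probabilities if d not in labels]
    if unknown:
        raise KeyError(f"predictions for unlabelled drugs: {unknown}")
    tp = fp = tn = fn = 0
    for drug_id, p in probabilities.items():
        call = p >= threshold
        truth = labels[drug_id]
        if call and truth:
            tp += 1
        elif call and not truth:
            fp += 1
        elif not call and not truth:
            tn += 1
        else:
            fn += 1
    counts = ConfusionCounts(tp, fp, tn, fn)
    return counts, metrics(counts)


@dataclass
class EvaluationReport:
    """Per-base-model metric rows, their mean, and the stacked-model row."""

    base_rows: list[dict[str, float]] = field(default_factory=list)
    stacked_row: dict[str, float] | None = None

    def mean_row(self) -> dict[str, float]:
        if not self.base_rows:
            raise ValueError("no base-model rows")
        return {
            m: sum(r[m] for r in self.base_rows) / len(self.base_rows)
            for m in METRIC_NAMES
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.base_rows, 1):
            rows.append({"model": f"base_{i:02d}", **{m: r[m] for m in METRIC_NAMES}})
        rows.append({"model": "mean", **self.mean_row()})
        if self.stacked_row is not None:
            rows.append(
                {"model": "stacked", **{m: self.stacked_row[m] for m in METRIC_NAMES}}
            )
        return pd.DataFrame(rows)
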