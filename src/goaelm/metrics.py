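"""Confusion-matrix evaluation metrics for binary classification.

Eight scalar indicators derive from the four confusion counts: accuracy,
sensitivity (recall / true-positive rate), specificity (true-negative
rate), precision (identical to PPV), F1 score, Matthews correlation
coefficient (MCC), PPV and NPV.  A metric whose denominator is zero is
reported as NaN ("undefined") rather than silently coerced to 0; the
remaining metrics of the report are unaffected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts", "metric_report"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{f.name} must be a nonnegative integer, got {v!r}")
        if self.total < 1:
            raise ValueError("confusion counts must cover at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """All values on [0,1] (MCC on [-1,1]); undefined metrics are NaN."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float
    ppv: float
    npv: float

    def to_dict(self, percent: bool = False) -> dict[str, Optional[float]]:
        out: dict[str, Optional[float]] = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if math.isnan(v):
                out[f.name] = None
            else:
                out[f.name] = 100.0 * v if percent else v
        return out

    def to_json(self, path: Union[str, Path], percent: bool = False) -> None:
        Path(path).write_text(json.dumps(self.to_dict(percent), indent=2) + "\n")

    def to_csv(self, path: Union[str, Path], percent: bool = False) -> None:
        pd.DataFrame([self.to_dict(percent)]).to_csv(path, index=False)


def confusion_counts(
    true_labels: Sequence[int],
    predicted_labels: Sequence[int],
    positive_label: int = 1,
) -> ConfusionCounts:
    """Exact TP/TN/FP/FN counts for binary label vectors."""
    y = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if y.shape != p.shape or y.ndim != 1 or y.size < 1:
        raise ValueError("label vectors must be 1-D, non-empty, and equal length")
    values = set(np.unique(y)) | set(np.unique(p))
    if len(values) > 2:
        raise ValueError(f"labels must be binary, saw values {sorted(values)}")
    pos_t = y == positive_label
    pos_p = p == positive_label
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metric_report(c: ConfusionCounts) -> MetricsReport:
    """Compute the eight indicators from confusion counts.

    MCC uses the standard Matthews form
    (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), the only form
    bounded in [−1, 1].
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    sensitivity = _ratio(tp, tp + fn)
    precision = _ratio(tp, tp + fp)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else float("nan")
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(
        accuracy=_ratio(tp + tn, c.total),
        sensitivity=sensitivity,
        specificity=_ratio(tn, tn + fp),
        precision=precision,
        f1=f1,
        mcc=mcc,
        ppv=precision,
        npv=_ratio(tn, tn + fn),
    )
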