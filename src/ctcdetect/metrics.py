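"""Confusion-matrix evaluation of CTC calls.

Evaluation is per cell: predicted candidates are paired with
ground-truth cells of the same field of view by mutual box-center
containment, and the paired labels are tallied into TP/FP/TN/FN with
"CTC" as the positive class.  Five metrics are derived:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    Se/recall = TP / (TP + FN)
    Sp        = TN / (TN + FP)
    precision = TP / (TP + FP)
    F1        = 2 TP / (2 TP + FP + FN)

A metric whose denominator is zero is reported as undefined (None),
never silently 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .geometry import BoundingBox
from .params import CTC, NON_CTC

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "build_confusion",
    "compute_metrics",
    "match_boxes",
    "evaluate_detections",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = ["source_id", "row0", "col0", "row1", "col1", "label"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN tally; positive = CTC."""

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


@dataclass(frozen=True)
class MetricsReport:
    """The five performance metrics, as fractions; None = undefined."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None

    def as_percent(self, digits: int = 1) -> dict[str, float | None]:
        """Metrics as percentages rounded to ``digits`` decimals."""
        return {
            name: None if value is None else round(100.0 * value, digits)
            for name, value in vars(self).items()
        }

    def format_text(self) -> str:
        lines = []
        for name, value in self.as_percent().items():
            shown = "undefined" if value is None else f"{value:.1f}%"
            lines.append(f"{name:<12s} {shown}")
        return "\n".join(lines)


def build_confusion(
    pred: Sequence[str], truth: Sequence[str], positive: str = CTC
) -> ConfusionMatrix:
    """Tally matched prediction/truth label pairs."""
    if len(pred) != len(truth):
        raise ValueError(
            f"prediction/truth length mismatch: {len(pred)} vs {len(truth)}"
        )
    tp = fp = tn = fn = 0
    for p, t in zip(pred, truth):
        if p == positive:
            if t == positive:
                tp += 1
            else:
                fp += 1
        else:
            if t == positive:
                fn += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Derive the five metrics from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return MetricsReport(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        precision=_ratio(cm.tp, cm.tp + cm.fp),
        f1=_ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn),
    )


def _boxes(df: pd.DataFrame) -> list[BoundingBox]:
    return [
        BoundingBox(int(r.row0), int(r.col0), int(r.row1), int(r.col1))
        for r in df.itertuples()
    ]


def match_boxes(
    pred: Sequence[BoundingBox], truth: Sequence[BoundingBox]
) -> list[tuple[int, int]]:
    """One-to-one pairing by mutual center containment.

    A predicted box matches a truth box when each box contains the
    other's center; among competitors the pair with the smallest
    center distance wins.  Returns (pred_index, truth_index) pairs.
    """
    candidates = []
    for ti, tb in enumerate(truth):
        tc = tb.center
        for pi, pb in enumerate(pred):
            pc = pb.center
            if tb.contains_point(*pc) and pb.contains_point(*tc):
                d2 = (tc[0] - pc[0]) ** 2 + (tc[1] - pc[1]) ** 2
                candidates.append((d2, pi, ti))
    candidates.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for _, pi, ti in candidates:
        if pi in used_p or ti in used_t:
            continue
        pairs.append((pi, ti))
        used_p.add(pi)
        used_t.add(ti)
    return pairs


def evaluate_detections(
    pred_df: pd.DataFrame, truth_df: pd.DataFrame
) -> ConfusionMatrix:
    """Pair detections with truth cells per field of view and tally.

    An unmatched truth cell counts as predicted non-CTC (FN when it is
    a CTC, TN otherwise); an unmatched predicted CTC is an FP against
    background; an unmatched predicted non-CTC carries no information
    and is ignored.
    """
    for name, df in (("pred", pred_df), ("truth", truth_df)):
        missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{name} table missing column(s): {', '.join(missing)}")
    pred_labels: list[str] = []
    truth_labels: list[str] = []
    sources = sorted(
        set(pred_df["source_id"].astype(str)) | set(truth_df["source_id"].astype(str))
    )
    for sid in sources:
        p = pred_df[pred_df["source_id"].astype(str) == sid].reset_index(drop=True)
        t = truth_df[truth_df["source_id"].astype(str) == sid].reset_index(drop=True)
        pairs = match_boxes(_boxes(p), _boxes(t))
        matched_p = {pi for pi, _ in pairs}
        matched_t = {ti for _, ti in pairs}
        for pi, ti in pairs:
            pred_labels.append(str(p.loc[pi, "label"]))
            truth_labels.append(str(t.loc[ti, "label"]))
        for ti in range(len(t)):
            if ti not in matched_t:
                pred_labels.append(NON_CTC)
                truth_labels.append(str(t.loc[ti, "label"]))
        for pi in range(len(p)):
            if pi not in matched_p and str(p.loc[pi, "label"]) == CTC:
                pred_labels.append(CTC)
                truth_labels.append(NON_CTC)
    return build_confusion(pred_labels, truth_labels)
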