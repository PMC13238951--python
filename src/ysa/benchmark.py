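"""Sample-wise benchmarking of detector output against ground-truth events.

Detected and annotated event intervals are rasterized to per-sample boolean
masks (event present / absent — labels collapse to binary), compared
element-wise, and pooled across channels before scoring, so the five
summary metrics describe the whole recording set:

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 · precision · recall / (precision + recall)

A metric whose denominator is zero is reported as ``None`` (undefined),
never coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass
class BenchmarkScores:
    accuracy: float | None
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
        }


def events_to_mask(intervals, fs: float, length: int) -> np.ndarray:
    """Rasterize ``(onset_s, offset_s)`` intervals to a boolean sample mask.

    Half-open sample intervals; overlaps union without double counting.
    Intervals extending beyond the record are rejected.
    """
    mask = np.zeros(int(length), dtype=bool)
    duration = length / fs
    for onset, offset in intervals:
        if onset < 0 or offset > duration + 0.5 / fs:
            raise ValueError(f"interval [{onset}, {offset}] s lies outside the {duration} s record")
        if offset < onset:
            raise ValueError("interval offset precedes onset")
        i0 = int(np.floor(onset * fs))
        i1 = min(length, int(np.ceil(offset * fs)))
        mask[i0:i1] = True
    return mask


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Element-wise confusion counts between two equal-length masks."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth masks must have equal length")
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & truth)),
        tn=int(np.count_nonzero(~pred & ~truth)),
        fp=int(np.count_nonzero(pred & ~truth)),
        fn=int(np.count_nonzero(~pred & truth)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def scores(c: ConfusionCounts) -> BenchmarkScores:
    """The five summary metrics from pooled confusion counts."""
    if c.total == 0:
        raise ValueError("cannot score empty confusion counts")
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return BenchmarkScores(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=precision,
        recall=recall,
        specificity=_ratio(c.tn, c.tn + c.fp),
        f1=f1,
    )


def benchmark_events(
    pred_df: pd.DataFrame,
    truth_df: pd.DataFrame,
    fs: float,
    length: int,
    channel_ids=None,
) -> tuple[ConfusionCounts, BenchmarkScores]:
    """Score predicted events against ground truth, pooled across channels.

    Both frames follow the events CSV schema (channel_id, onset_s, offset_s;
    a ``label`` column, if present, is ignored beyond being non-discarded —
    callers should pre-filter). Masks are built per channel over the union
    of channels (or an explicit ``channel_ids`` list, so event-free channels
    still contribute true negatives), confusion counts are pooled, and the
    pooled counts are scored.
    """
    if channel_ids is None:
        channel_ids = sorted(
            set(pred_df["channel_id"].tolist()) | set(truth_df["channel_id"].tolist())
        )
    pooled = ConfusionCounts()
    for cid in channel_ids:
        p = pred_df[pred_df["channel_id"] == cid]
        t = truth_df[truth_df["channel_id"] == cid]
        pm = events_to_mask(zip(p["onset_s"], p["offset_s"]), fs, length)
        tm = events_to_mask(zip(t["onset_s"], t["offset_s"]), fs, length)
        pooled = pooled + confusion(pm, tm)
    return pooled, scores(pooled)
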