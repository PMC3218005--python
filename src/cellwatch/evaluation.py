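"""Pixel-level comparison of computer masks against reference tracings.

A computer-generated confluency mask is scored against a human (or
synthetic ground-truth) mask pixel by pixel: pixels labeled cell in both
are true positives, computer-only pixels false positives, reference-only
pixels false negatives, and the rest true negatives. Precision and
recall follow the usual definitions TP/(TP+FP) and TP/(TP+FN).

Two aggregations over an image set are provided: per-image mean +/- SEM
(the convention for small evaluation panels) and pooled-pixel metrics
computed on summed confusion counts.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .frames import ConfluencyMask


class UndefinedMetricError(ValueError):
    """Raised when a ratio metric has an empty denominator."""


@dataclass(frozen=True)
class SegConfusion:
    """Pixel confusion counts between a predicted and a reference mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "SegConfusion") -> "SegConfusion":
        return SegConfusion(self.tp + other.tp, self.fp + other.fp,
                            self.fn + other.fn, self.tn + other.tn)


def confusion_pixels(pred: ConfluencyMask, ref: ConfluencyMask) -> SegConfusion:
    if pred.labels.shape != ref.labels.shape:
        raise ValueError("predicted and reference masks must have identical shapes")
    p, r = pred.labels, ref.labels
    return SegConfusion(
        tp=int(np.count_nonzero(p & r)),
        fp=int(np.count_nonzero(p & ~r)),
        fn=int(np.count_nonzero(~p & r)),
        tn=int(np.count_nonzero(~p & ~r)),
    )


def precision(c: SegConfusion) -> float:
    """TP / (TP + FP); undefined when the prediction is empty."""
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: no predicted-positive pixels")
    return c.tp / (c.tp + c.fp)


def recall(c: SegConfusion) -> float:
    """TP / (TP + FN); undefined when the reference is empty."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: no reference-positive pixels")
    return c.tp / (c.tp + c.fn)


def pooled_metrics(confusions: Sequence[SegConfusion]) -> dict:
    """Precision/recall on pixel counts summed across images."""
    if not confusions:
        raise ValueError("need at least one confusion")
    total = confusions[0]
    for c in confusions[1:]:
        total = total + c
    return {"precision": precision(total), "recall": recall(total), "confusion": total}


def per_image_metrics(confusions: Sequence[SegConfusion]) -> dict:
    """Mean +/- SEM of per-image precision and recall (SEM is 0 for n=1)."""
    if not confusions:
        raise ValueError("need at least one confusion")
    precs = np.array([precision(c) for c in confusions])
    recs = np.array([recall(c) for c in confusions])
    sem = lambda a: float(stats.sem(a)) if a.size > 1 else 0.0
    return {
        "precision_mean": float(precs.mean()), "precision_sem": sem(precs),
        "recall_mean": float(recs.mean()), "recall_sem": sem(recs),
        "n_images": len(confusions),
    }


#: RGB colors of the evaluation map: overlap yellow, computer-only green,
#: reference-only red, background black.
EVAL_COLORS = {
    "tp": (255, 255, 0),
    "fp": (0, 255, 0),
    "fn": (255, 0, 0),
    "tn": (0, 0, 0),
}


def evaluation_overlay(pred: ConfluencyMask, ref: ConfluencyMask) -> np.ndarray:
    """Color-coded agreement map (RGB uint8): TP yellow, FP green, FN red, TN black."""
    if pred.labels.shape != ref.labels.shape:
        raise ValueError("predicted and reference masks must have identical shapes")
    p, r = pred.labels, ref.labels
    rgb = np.zeros(p.shape + (3,), dtype=np.uint8)
    rgb[p & r] = EVAL_COLORS["tp"]
    rgb[p & ~r] = EVAL_COLORS["fp"]
    rgb[~p & r] = EVAL_COLORS["fn"]
    return rgb
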