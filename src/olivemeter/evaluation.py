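"""Pixel-level scoring of predicted masks against ground truth.

Counts are defined over foreground (fruit) pixels only; true negatives
are never computed.  Precision PC = TP/(TP+FP), recall RC = TP/(TP+FN),
and the F-score is their harmonic mean.  Scores over an image set are by
default pooled — counts are summed across images before the ratios — so
each image contributes in proportion to its pixel count; a per-image-mean
weighting is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster_io import ensure_mask

__all__ = [
    "ConfusionCounts",
    "SegScores",
    "UndefinedScoreError",
    "confusion_counts",
    "seg_scores",
    "downscale_truth",
    "evaluate_set",
]


class UndefinedScoreError(ValueError):
    """Precision, recall or F-score is undefined for these counts."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class SegScores:
    precision: float
    recall: float
    f_score: float


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """TP/FP/FN pixel counts of a predicted mask against its ground truth."""
    pred = ensure_mask(pred)
    truth = ensure_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: prediction {pred.shape} vs truth {truth.shape}")
    p = pred > 0
    t = truth > 0
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def seg_scores(counts: ConfusionCounts) -> SegScores:
    """Precision, recall, F-score; raises rather than silently reporting 0."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fp == 0:
        raise UndefinedScoreError("precision undefined: no predicted foreground (TP+FP=0)")
    if tp + fn == 0:
        raise UndefinedScoreError("recall undefined: no true foreground (TP+FN=0)")
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    if precision + recall == 0:
        raise UndefinedScoreError("F-score undefined: precision and recall are both 0")
    f_score = 2.0 * precision * recall / (precision + recall)
    return SegScores(precision=precision, recall=recall, f_score=f_score)


def downscale_truth(truth: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour downscale of a ground-truth mask to *shape*.

    Nearest-neighbour preserves binarity, so full-resolution hand-painted
    truths can be compared against working-resolution predictions.
    """
    truth = ensure_mask(truth)
    if truth.shape == tuple(shape):
        return truth
    rows = (np.arange(shape[0]) + 0.5) * truth.shape[0] / shape[0]
    cols = (np.arange(shape[1]) + 0.5) * truth.shape[1] / shape[1]
    rr = np.clip(rows.astype(int), 0, truth.shape[0] - 1)
    cc = np.clip(cols.astype(int), 0, truth.shape[1] - 1)
    return truth[np.ix_(rr, cc)]


def evaluate_set(
    pairs,
    weighting: str = "pooled",
    image_ids=None,
) -> tuple[pd.DataFrame, SegScores]:
    """Score a list of (prediction, truth) mask pairs.

    Truths whose shape differs from their prediction are downscaled with
    nearest-neighbour first.  Returns a per-image table and an overall
    score: with ``weighting="pooled"`` the counts are summed before the
    ratios (default); with ``"per-image-mean"`` the per-image scores are
    averaged unweighted.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one (prediction, truth) pair")
    if weighting not in ("pooled", "per-image-mean"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if image_ids is None:
        image_ids = [f"image_{i:03d}" for i in range(len(pairs))]
    rows = []
    pooled = ConfusionCounts(0, 0, 0)
    for image_id, (pred, truth) in zip(image_ids, pairs):
        try:
            if truth.shape != pred.shape:
                if (
                    truth.shape[0] >= pred.shape[0]
                    and truth.shape[1] >= pred.shape[1]
                ):
                    truth = downscale_truth(truth, pred.shape)
                else:
                    raise ValueError(
                        f"shape mismatch: prediction {pred.shape} vs smaller "
                        f"truth {truth.shape}"
                    )
            counts = confusion_counts(pred, truth)
        except ValueError as exc:
            raise ValueError(f"pair {image_id!r}: {exc}") from exc
        pooled = pooled + counts
        scores = seg_scores(counts)
        rows.append(
            {
                "image_id": image_id,
                "tp": counts.tp,
                "fp": counts.fp,
                "fn": counts.fn,
                "precision": scores.precision,
                "recall": scores.recall,
                "f_score": scores.f_score,
            }
        )
    per_image = pd.DataFrame(rows)
    if weighting == "pooled":
        overall = seg_scores(pooled)
    else:
        overall = SegScores(
            precision=float(per_image["precision"].mean()),
            recall=float(per_image["recall"].mean()),
            f_score=float(per_image["f_score"].mean()),
        )
    return per_image, overall
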