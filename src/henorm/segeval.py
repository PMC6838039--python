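"""Pixel-level segmentation overlap metrics.

Given a binary ground-truth nuclei mask L and a binary prediction P, the
usual confusion tallies give

* Dice similarity coefficient  DSC = 2TP / (2TP + FP + FN)
* extra fraction               EF  = FP / (TP + FN)   (over-segmentation)
* Jaccard index                JAC = |L n P| / |L u P|
* precision                    TP / (TP + FP)
* recall                       TP / (TP + FN)

Evaluation is pixel-level throughout; object-matched scores (AJI etc.) are
out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UndefinedAggregateError, UndefinedScoreError

__all__ = ["ConfusionCounts", "SegScore", "confusion_counts", "score", "aggregate"]

logger = logging.getLogger(__name__)

_METRICS = ("dsc", "jac", "ef", "precision", "recall")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SegScore:
    """Overlap scores for one (label, prediction) pair.

    ``empty_prediction`` flags the convention that precision is reported as 0
    when the prediction has no foreground (TP + FP = 0).
    """

    dsc: float
    jac: float
    ef: float
    precision: float
    recall: float
    empty_prediction: bool = False

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in _METRICS}


def _as_bool_pair(label, pred):
    label = np.asarray(label).astype(bool)
    pred = np.asarray(pred).astype(bool)
    if label.shape != pred.shape:
        raise InvalidInputError(
            f"label shape {label.shape} != prediction shape {pred.shape}"
        )
    return label, pred


def confusion_counts(label, pred) -> ConfusionCounts:
    """Exact pixel tallies of TP/FP/FN/TN between two equally-shaped masks."""
    label, pred = _as_bool_pair(label, pred)
    tp = int(np.sum(label & pred))
    fp = int(np.sum(~label & pred))
    fn = int(np.sum(label & ~pred))
    tn = int(np.sum(~label & ~pred))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def score(label, pred) -> SegScore:
    """Compute DSC, JAC, EF, precision and recall for one mask pair.

    Raises :class:`UndefinedScoreError` when the ground truth is empty (every
    ratio's denominator vanishes); an empty *prediction* instead yields
    precision 0 with the ``empty_prediction`` flag set.
    """
    c = confusion_counts(label, pred)
    if c.tp + c.fn == 0:
        raise UndefinedScoreError("ground-truth mask has no foreground pixels")
    union = c.tp + c.fp + c.fn
    empty_pred = (c.tp + c.fp) == 0
    return SegScore(
        dsc=2 * c.tp / (2 * c.tp + c.fp + c.fn),
        jac=c.tp / union,
        ef=c.fp / (c.tp + c.fn),
        precision=0.0 if empty_pred else c.tp / (c.tp + c.fp),
        recall=c.tp / (c.tp + c.fn),
        empty_prediction=empty_pred,
    )


def aggregate(scores) -> pd.DataFrame:
    """Sample mean and standard deviation per metric over a list of scores.

    ``None`` entries (images whose score was undefined) are excluded with a
    logged count; a single defined value reports std 0 with ``n`` = 1.
    """
    scores = list(scores)
    defined = [s for s in scores if s is not None]
    if not defined:
        raise UndefinedAggregateError("no defined scores to aggregate")
    n_missing = len(scores) - len(defined)
    if n_missing:
        logger.warning("%d undefined score(s) excluded from aggregation", n_missing)
    table = pd.DataFrame([s.as_dict() for s in defined])
    out = pd.DataFrame(index=["mean", "std", "n"], columns=list(_METRICS), dtype=float)
    for m in _METRICS:
        vals = table[m].to_numpy(dtype=float)
        out.loc["mean", m] = vals.mean()
        out.loc["std", m] = vals.std(ddof=1) if vals.size > 1 else 0.0
        out.loc["n", m] = vals.size
    return out
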