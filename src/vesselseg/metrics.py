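"""Pixel-wise segmentation metrics over the field of view.

Sensitivity, specificity and accuracy follow the usual confusion-count
definitions; the Matthews correlation coefficient is computed in its
marginal form MCC = (TP/N - S*P) / sqrt(P*S*(1-S)*(1-P)) with
N = TP+FP+TN+FN, S = (TP+FN)/N, P = (TP+FP)/N, which is algebraically equal
to the familiar four-product form but numerically stabler for large N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, UndefinedMetricError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ContractError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    se: float
    sp: float
    acc: float
    mcc: float | None
    counts: ConfusionCounts


def confusion_counts(pred: np.ndarray, gold: np.ndarray, fov: np.ndarray) -> ConfusionCounts:
    """Tally TP/FP/TN/FN over FOV pixels only."""
    pred = np.asarray(pred, dtype=bool)
    gold = np.asarray(gold, dtype=bool)
    fov = np.asarray(fov, dtype=bool)
    if not (pred.shape == gold.shape == fov.shape):
        raise ContractError(
            f"shape mismatch: pred {pred.shape}, gold {gold.shape}, fov {fov.shape}"
        )
    if not fov.any():
        raise ContractError("empty FOV")
    p, g = pred[fov], gold[fov]
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp, fp, tn, fn)


def basic_metrics(c: ConfusionCounts) -> MetricsReport:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/N."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive gold pixels")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative gold pixels")
    se = c.tp / (c.tp + c.fn)
    sp = c.tn / (c.tn + c.fp)
    acc = (c.tp + c.tn) / c.n
    return MetricsReport(se=se, sp=sp, acc=acc, mcc=None, counts=c)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient from the marginal form."""
    n = c.n
    if n == 0:
        raise UndefinedMetricError("MCC undefined: no pixels")
    s = (c.tp + c.fn) / n
    p = (c.tp + c.fp) / n
    denom = p * s * (1.0 - s) * (1.0 - p)
    if denom <= 0:
        raise UndefinedMetricError("MCC undefined: degenerate margins")
    return (c.tp / n - s * p) / math.sqrt(denom)


def evaluate(pred: np.ndarray, gold: np.ndarray, fov: np.ndarray) -> MetricsReport:
    """Confusion counts plus all four metrics in one call."""
    c = confusion_counts(pred, gold, fov)
    base = basic_metrics(c)
    try:
        m = mcc(c)
    except UndefinedMetricError:
        m = None
    return MetricsReport(se=base.se, sp=base.sp, acc=base.acc, mcc=m, counts=c)
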