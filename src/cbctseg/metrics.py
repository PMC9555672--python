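"""Voxel-overlap evaluation of binary segmentations.

Segmentation quality is scored against a clinician's mask with the Dice
coefficient 2|A∩M|/(|A|+|M|), the F2 score (recall weighted twice as
heavily as precision — clinically, over-segmentation beats
under-segmentation), accuracy, recall, precision, and the area under the
precision-recall curve.  Because bone typically occupies only ~1-10% of
a head scan, AUPRC is reported next to its chance baseline, the
foreground prevalence; accuracy alone is uninformative at that
imbalance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .io_geometry import LabelMap, VolumeImage

__all__ = [
    "ConfusionCounts",
    "PRCurve",
    "EvalReport",
    "UndefinedMetricError",
    "confusion",
    "dice_coefficient",
    "f2_score",
    "accuracy",
    "recall",
    "precision",
    "pr_curve",
    "auprc",
    "auprc_baseline",
    "evaluate",
]


class UndefinedMetricError(ValueError):
    """The metric's denominator is empty for these inputs."""


def _as_bool(x) -> np.ndarray:
    arr = x.voxels if isinstance(x, VolumeImage) else np.asarray(x)
    return arr != 0


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel tallies of a binary prediction against ground truth."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PRCurve:
    """Precision/recall at decreasing score thresholds.

    ``thresholds[0]`` is +inf (the R = 0 anchor, with precision extended
    horizontally from the strictest real threshold); recall is
    non-decreasing along the curve and reaches 1 at the loosest
    threshold.
    """

    thresholds: np.ndarray
    recall: np.ndarray
    precision: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.recall)


@dataclass(frozen=True)
class EvalReport:
    """The full metric suite for one scan."""

    auprc: float
    auprc_baseline: float
    dice: float
    f2: float
    accuracy: float
    recall: float
    precision: float

    def to_dict(self) -> dict:
        return asdict(self)


def confusion(pred, gt) -> ConfusionCounts:
    """Exhaustive TP/TN/FP/FN voxel tally of two aligned binary grids."""
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def dice_coefficient(m, a) -> float:
    """Dice coefficient ``2|A∩M| / (|A| + |M|)``; symmetric in arguments."""
    mb, ab = _as_bool(m), _as_bool(a)
    if mb.shape != ab.shape:
        raise ValueError(f"shape mismatch: {mb.shape} vs {ab.shape}")
    denom = int(np.count_nonzero(mb)) + int(np.count_nonzero(ab))
    if denom == 0:
        raise UndefinedMetricError("Dice undefined: both masks are empty")
    return 2.0 * int(np.count_nonzero(mb & ab)) / denom


def f2_score(c: ConfusionCounts) -> float:
    """F2 = TP / (TP + 0.2 FP + 0.8 FN): recall twice as important."""
    denom = c.tp + 0.2 * c.fp + 0.8 * c.fn
    if denom == 0:
        raise UndefinedMetricError("F2 undefined: no foreground in prediction or truth")
    return c.tp / denom


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined on empty grids")
    return (c.tp + c.tn) / c.total


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: ground truth is empty")
    return c.tp / (c.tp + c.fn)


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP)."""
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: prediction is empty")
    return c.tp / (c.tp + c.fp)


def pr_curve(probs, gt, n_thresholds: int = 1024) -> PRCurve:
    """Precision-recall curve of a foreground-probability grid.

    All unique scores serve as thresholds when there are at most
    ``n_thresholds`` of them, otherwise that many uniform quantiles are
    used (always including the extremes).  Each threshold t binarizes
    ``probs >= t``.  The curve is anchored at R = 0 (precision extended
    horizontally) and reaches R = 1 at the loosest threshold.
    """
    g = _as_bool(gt).ravel()
    s = (probs.voxels if isinstance(probs, VolumeImage) else np.asarray(probs)).ravel()
    if s.shape != g.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {g.shape}")
    n_fg = int(np.count_nonzero(g))
    if n_fg == 0 or n_fg == g.size:
        raise UndefinedMetricError(
            "PR curve undefined: ground truth needs both foreground and background"
        )
    uniq = np.unique(s)
    if uniq.size <= n_thresholds:
        thr = uniq[::-1]
    else:
        qs = np.quantile(s, np.linspace(0.0, 1.0, n_thresholds))
        thr = np.unique(np.concatenate([qs, [s.min(), s.max()]]))[::-1]
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    tp_cum = np.cumsum(g[order])
    # number of voxels predicted positive at each threshold
    k = np.searchsorted(-s_sorted, -thr, side="right")
    tp = np.where(k > 0, tp_cum[np.maximum(k - 1, 0)], 0)
    with np.errstate(invalid="ignore"):
        prec = np.where(k > 0, tp / np.maximum(k, 1), 1.0)
    rec = tp / n_fg
    thresholds = np.concatenate([[np.inf], thr])
    rec = np.concatenate([[0.0], rec])
    prec = np.concatenate([[prec[0]], prec])
    return PRCurve(thresholds=thresholds, recall=rec, precision=prec)


def auprc(curve: PRCurve, variant: str = "trapezoid") -> float:
    """Area under the precision-recall curve.

    ``variant="trapezoid"`` (default) integrates
    Σ (R[n] − R[n−1]) · (P[n] + P[n−1]) / 2 over the recall-sorted curve.
    ``variant="midpoint_delta"`` instead multiplies by the *difference*
    of successive precisions — kept selectable for auditing, but it is
    not an area (it telescopes toward 0 for flat curves) and is never
    used by :func:`evaluate`.
    """
    r, p = np.asarray(curve.recall, float), np.asarray(curve.precision, float)
    if r.size < 2:
        raise ValueError("need at least two curve points")
    if np.any(np.isnan(r)) or np.any(np.isnan(p)) or np.any(np.diff(r) < -1e-12):
        raise ValueError("curve must be recall-sorted and free of NaNs")
    dr = np.diff(r)
    if variant == "trapezoid":
        return float(np.sum(dr * (p[1:] + p[:-1]) / 2.0))
    if variant == "midpoint_delta":
        return float(np.sum(dr * (p[1:] - p[:-1]) / 2.0))
    raise ValueError(f"unknown variant {variant!r}")


def auprc_baseline(gt) -> float:
    """Chance-level AUPRC: the foreground prevalence of the ground truth."""
    g = _as_bool(gt)
    if g.size == 0:
        raise UndefinedMetricError("baseline undefined on an empty grid")
    return float(np.count_nonzero(g)) / g.size


def evaluate(pred_probs, pred_label, gt, n_thresholds: int = 1024) -> EvalReport:
    """Compute the full metric suite.

    Overlap metrics use the binarized post-processed prediction; AUPRC
    consumes the pre-argmax foreground-probability grid.
    """
    c = confusion(pred_label, gt)
    return EvalReport(
        auprc=auprc(pr_curve(pred_probs, gt, n_thresholds)),
        auprc_baseline=auprc_baseline(gt),
        dice=dice_coefficient(gt, pred_label),
        f2=f2_score(c),
        accuracy=accuracy(c),
        recall=recall(c),
        precision=precision(c),
    )
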