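"""Training objective (cross-entropy + soft Dice) and evaluation metrics.

The training loss is ``CE + (1 - softDice)``: pixel-mean categorical
cross-entropy plus one minus the smoothed soft Dice ratio averaged over the
foreground classes.  Evaluation uses the standard confusion-count metrics —
accuracy, Dice score, sensitivity, specificity — computed per binarized
tumor region (whole tumor WT = labels {1,2,3}, tumor core TC = {2,3},
enhancing tumor ET = {3}) and macro-averaged over cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

REGIONS = ("WT", "TC", "ET")
_REGION_LABELS = {"WT": (1, 2, 3), "TC": (2, 3), "ET": (3,)}
METRICS = ("accuracy", "dice", "sensitivity", "specificity")

_CLIP = 1e-7


@dataclass
class ConfusionCounts:
    """Pixel-level 2x2 tabulation for one binarized region."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("invalid counts: negative entry")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class LossValue:
    total: float
    cross_entropy_term: float
    dice_term: float


@dataclass
class MetricsReport:
    """Per-region mean metrics plus the per-case values behind them."""

    means: dict  # {region: {metric: float}}
    per_case: dict  # {region: {metric: list[float]}}

    def to_dict(self) -> dict:
        return self.means


# ---------------------------------------------------------------------------
# losses


def cross_entropy_loss(probabilities: np.ndarray, target: np.ndarray) -> float:
    """Mean over pixels of -log p(true class), p clipped to [1e-7, 1].

    ``probabilities`` is (C, H, W) or (N, C, H, W); ``target`` the matching
    integer mask.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    t = np.asarray(target)
    if p.ndim != t.ndim + 1:
        raise ValueError("probabilities and target shapes are incongruent")
    if t.ndim == 2:  # implicit batch of one
        p = p[None]
        t = t[None]
    ncls = p.shape[1]
    if t.min() < 0 or t.max() >= ncls:
        raise ValueError("invalid target: label outside class range")
    p_true = np.take_along_axis(p, t[:, None], axis=1)[:, 0]
    return float(-np.log(np.clip(p_true, _CLIP, 1.0)).mean())


def dice_loss(
    probabilities: np.ndarray,
    target: np.ndarray,
    epsilon: float = 1e-6,
    foreground_classes: tuple[int, ...] = (1, 2, 3),
) -> float:
    """Soft Dice loss: 1 - mean_c (2 sum(y_c p_c) + eps)/(sum y_c + sum p_c + eps).

    Accepts either a class-channel probability array with an integer mask,
    or a plain foreground-probability array with a binary mask of the same
    shape (single-class form).
    """
    if epsilon <= 0:
        raise ValueError("invalid smoothing: epsilon must be > 0")
    p = np.asarray(probabilities, dtype=np.float64)
    t = np.asarray(target)
    if p.shape == t.shape:  # binary single-class form
        num = 2.0 * float((t * p).sum()) + epsilon
        den = float(t.sum() + p.sum()) + epsilon
        return 1.0 - num / den
    if p.ndim != t.ndim + 1:
        raise ValueError("probabilities and target shapes are incongruent")
    class_axis = 0 if t.ndim == 2 else 1  # (C,H,W) vs (N,C,H,W)
    ratios = []
    for c in foreground_classes:
        yc = (t == c).astype(np.float64)
        pc = np.take(p, c, axis=class_axis)
        num = 2.0 * float((yc * pc).sum()) + epsilon
        den = float(yc.sum() + pc.sum()) + epsilon
        ratios.append(num / den)
    return 1.0 - float(np.mean(ratios))


def combined_loss(
    probabilities: np.ndarray,
    target: np.ndarray,
    epsilon: float = 1e-6,
    foreground_classes: tuple[int, ...] = (1, 2, 3),
) -> LossValue:
    """Cross-entropy plus soft-Dice loss; vanishes at a perfect prediction."""
    ce = cross_entropy_loss(probabilities, target)
    dc = dice_loss(probabilities, target, epsilon, foreground_classes)
    return LossValue(total=ce + dc, cross_entropy_term=ce, dice_term=dc)


# ---------------------------------------------------------------------------
# metrics


def region_binarize(mask: np.ndarray, region: str) -> np.ndarray:
    """Binarize a label mask to one nested tumor region (WT / TC / ET)."""
    if region not in _REGION_LABELS:
        raise ValueError(f"invalid region {region!r}")
    m = np.asarray(mask)
    return np.isin(m, _REGION_LABELS[region]).astype(np.uint8)


def confusion_counts(predicted: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tabulate TP/TN/FP/FN between two congruent binary masks."""
    p = np.asarray(predicted).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError("unaligned masks")
    tp = int(np.count_nonzero(p & t))
    tn = int(np.count_nonzero(~p & ~t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def segmentation_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, Dice, sensitivity, specificity from confusion counts.

    Empty-denominator convention: a region empty in the ground truth and
    predicted empty scores 1.0 for the affected metric, otherwise 0.0.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn

    def safe(num, den, empty_ok):
        if den == 0:
            return 1.0 if empty_ok else 0.0
        return num / den

    return {
        "accuracy": safe(tp + tn, counts.total, True),
        "dice": safe(2 * tp, 2 * tp + fp + fn, True),
        "sensitivity": safe(tp, tp + fn, fp == 0),
        "specificity": safe(tn, tn + fp, fn == 0),
    }


def evaluate_dataset(predictions, truths) -> MetricsReport:
    """Per-region metrics for paired label masks, macro-averaged over cases.

    ``predictions`` and ``truths`` are equal-length sequences of integer
    label masks with values in {0,1,2,3}.
    """
    predictions = list(predictions)
    truths = list(truths)
    if not predictions or len(predictions) != len(truths):
        raise ValueError("nothing to evaluate: need equal-length nonempty lists")
    per_case = {r: {m: [] for m in METRICS} for r in REGIONS}
    for pred, truth in zip(predictions, truths):
        for region in REGIONS:
            counts = confusion_counts(
                region_binarize(pred, region), region_binarize(truth, region)
            )
            vals = segmentation_metrics(counts)
            for m in METRICS:
                per_case[region][m].append(vals[m])
    means = {
        r: {m: float(np.mean(per_case[r][m])) for m in METRICS} for r in REGIONS
    }
    return MetricsReport(means=means, per_case=per_case)
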