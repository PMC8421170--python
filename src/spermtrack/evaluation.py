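"""Detection scoring against ground truth and cross-sample summaries.

Detections in one frame are matched greedily (nearest first, within a
pixel gate) to the ground-truth objects present in that frame. Motile
objects are the positives: a detection on a motile object is a true
positive, a motile object left undetected a false negative. Immotile
cells and debris are the negatives: one with a detection on it, or a
detection on nothing at all, counts as a false positive; one left alone
is a true negative. From the pooled tallies:

    accuracy    = 100 * (TP + TN) / (TP + TN + FP + FN)
    sensitivity = 100 * TP / (TP + FN)
    specificity = 100 * TN / (TN + FP)

Per-sample metrics are summarized as mean +/- population standard
deviation (divisor n), rounded only for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import SpermDetection
from .synthetic import GroundTruth

__all__ = [
    "ConfusionCounts",
    "PerformanceSummary",
    "DEFAULT_MATCH_GATE_PX",
    "match_to_ground_truth",
    "accuracy",
    "sensitivity",
    "specificity",
    "summarize_performance",
]

#: Default detection-to-truth matching radius, pixels (about one head length).
DEFAULT_MATCH_GATE_PX = 20.0


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class PerformanceSummary:
    """Mean and spread of each metric across samples, in percent."""

    accuracy_mean: float
    accuracy_std: float
    sensitivity_mean: float
    sensitivity_std: float
    specificity_mean: float
    specificity_std: float

    def rounded(self) -> dict[str, float]:
        """Presentation precision: 1 decimal for means, 2 for stds."""
        return {
            "accuracy_mean": round(self.accuracy_mean, 1),
            "accuracy_std": round(self.accuracy_std, 2),
            "sensitivity_mean": round(self.sensitivity_mean, 1),
            "sensitivity_std": round(self.sensitivity_std, 2),
            "specificity_mean": round(self.specificity_mean, 1),
            "specificity_std": round(self.specificity_std, 2),
        }


def match_to_ground_truth(
    detections: list[SpermDetection],
    gt: GroundTruth,
    frame_index: int,
    gate_px: float = DEFAULT_MATCH_GATE_PX,
) -> ConfusionCounts:
    """Score one frame's detections against the ground truth.

    Greedy nearest-first matching within ``gate_px`` (ties broken by
    detection then object order). A detection matched to a motile object
    is a TP; any other detection is an FP. Unmatched motile objects are
    FNs; untouched immotile/debris objects are TNs.
    """
    objects = []  # (class, x, y)
    covered = False
    for track in gt.tracks:
        for obs in track.frames:
            if obs.frame == frame_index:
                objects.append((track.object_class, obs.x, obs.y))
        covered = covered or any(o.frame == frame_index for o in track.frames)
    if gt.tracks and not covered:
        raise ValueError(f"frame {frame_index} not covered by ground truth")

    pairs = []
    for di, det in enumerate(detections):
        for oi, (_cls, x, y) in enumerate(objects):
            d = np.hypot(det.centroid[0] - x, det.centroid[1] - y)
            if d <= gate_px:
                pairs.append((d, di, oi))
    pairs.sort()
    det_match: dict[int, int] = {}
    obj_match: dict[int, int] = {}
    for _d, di, oi in pairs:
        if di in det_match or oi in obj_match:
            continue
        det_match[di] = oi
        obj_match[oi] = di

    tp = fn = tn = fp = 0
    for oi, (cls, _x, _y) in enumerate(objects):
        if cls == "motile":
            if oi in obj_match:
                tp += 1
            else:
                fn += 1
        else:
            if oi not in obj_match:
                tn += 1
    # detections on non-motile objects or on nothing are false positives
    for di in range(len(detections)):
        oi = det_match.get(di)
        if oi is None or objects[oi][0] != "motile":
            fp += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(c: ConfusionCounts) -> float:
    """Percent of all decisions that are correct."""
    denom = c.tp + c.tn + c.fp + c.fn
    if denom == 0:
        raise ZeroDivisionError("accuracy undefined: no counts")
    return 100.0 * (c.tp + c.tn) / denom


def sensitivity(c: ConfusionCounts) -> float:
    """Percent of motile objects recovered."""
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no positives")
    return 100.0 * c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """Percent of non-motile objects left alone."""
    if c.tn + c.fp == 0:
        raise ZeroDivisionError("specificity undefined: no negatives")
    return 100.0 * c.tn / (c.tn + c.fp)


def summarize_performance(
    per_sample: list[tuple[float, float, float]],
    ddof: int = 0,
) -> PerformanceSummary:
    """Mean +/- std of (accuracy, sensitivity, specificity) across samples.

    The population standard deviation (``ddof=0``) is the default
    reporting convention; pass ``ddof=1`` for the sample estimate.
    """
    if not per_sample:
        raise ValueError("need at least one sample")
    arr = np.asarray(per_sample, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("per_sample must be rows of (accuracy, sensitivity, specificity)")
    means = arr.mean(axis=0)
    stds = arr.std(axis=0, ddof=ddof) if arr.shape[0] > ddof else np.zeros(3)
    return PerformanceSummary(
        accuracy_mean=float(means[0]),
        accuracy_std=float(stds[0]),
        sensitivity_mean=float(means[1]),
        sensitivity_std=float(stds[1]),
        specificity_mean=float(means[2]),
        specificity_std=float(stds[2]),
    )
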