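"""Velocity estimation and WHO motility classification.

Each track's per-step speed is its centroid displacement between sampled
frames, converted to micrometres and divided by the elapsed time
``stride / fps``; the track speed is the arithmetic mean over its steps.
WHO classes: fast progressive (FP) at >= 25 um/s, slow progressive (SP)
below that, immotile at (effectively) zero. The detector only sees movers,
so the immotile count of a sample is the total sperm count minus the
motile tracks; the total comes from ground truth, a manual count, or a
static count of the first frame.

A sample is called normal when the motile fraction (FP+SP over all sperm)
reaches 40%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .tracking import Track
from .video_io import DEFAULT_PIXEL_SCALE_UM

__all__ = [
    "WHOClass",
    "MotilityRecord",
    "SampleResult",
    "V_FAST_UM_S",
    "step_velocity",
    "track_mean_velocity",
    "classify_who",
    "classify_sample",
    "summarize_sample",
]

#: WHO fast-progressive velocity cut-off, um/s.
V_FAST_UM_S = 25.0

#: Below this mean speed (um/s) a track is treated as immotile jitter.
V_IMMOTILE_EPS_UM_S = 1.0

#: Minimum motile fraction for a normal sample (boundary inclusive).
NORMAL_MOTILE_FRACTION = 0.40


class WHOClass(str, Enum):
    FAST_PROGRESSIVE = "fast_progressive"
    SLOW_PROGRESSIVE = "slow_progressive"
    IMMOTILE = "immotile"


@dataclass(frozen=True)
class MotilityRecord:
    track_id: int
    mean_velocity_um_s: float
    velocity_std_um_s: float
    who_class: WHOClass


@dataclass(frozen=True)
class SampleResult:
    """Per-sample motility summary and the normal/abnormal call."""

    n_immotile: int
    n_fast: int
    n_slow: int
    mean_velocity_fast: float  # nan when no FP track
    std_velocity_fast: float
    mean_velocity_slow: float
    std_velocity_slow: float
    motile_fraction: float
    classification: str  # normal | abnormal


def step_velocity(
    prev: tuple[float, float],
    curr: tuple[float, float],
    stride: int,
    fps: float,
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
    literal_frame_rate_divisor: bool = False,
) -> float:
    """Speed over one sampled step, in um/s.

    Displacement (px) is converted to micrometres and divided by the
    elapsed time ``stride / fps`` seconds. The
    ``literal_frame_rate_divisor`` variant instead divides the raw pixel
    displacement by the frame rate; its unit (px·s/frame) is not a
    physical speed and it exists only for comparison.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if fps <= 0:
        raise ValueError("fps must be positive")
    displacement_px = math.hypot(curr[0] - prev[0], curr[1] - prev[1])
    if literal_frame_rate_divisor:
        return displacement_px / fps
    return displacement_px * pixel_scale_um / (stride / fps)


def track_mean_velocity(
    track: Track,
    fps: float,
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
    stride: int = 10,
) -> float:
    """Arithmetic mean of a track's step speeds; 0 for a single observation."""
    if len(track) < 2:
        return 0.0
    speeds = [
        step_velocity(track.centroids[i], track.centroids[i + 1], stride, fps, pixel_scale_um)
        for i in range(len(track) - 1)
    ]
    return float(np.mean(speeds))


def classify_who(
    mean_velocity_um_s: float,
    v_fast: float = V_FAST_UM_S,
    v_immotile_eps: float = V_IMMOTILE_EPS_UM_S,
) -> WHOClass:
    """WHO class of one track: FP at >= ``v_fast``, immotile below
    ``v_immotile_eps``, SP in between."""
    if mean_velocity_um_s < 0:
        raise ValueError("velocity cannot be negative")
    if mean_velocity_um_s < v_immotile_eps:
        return WHOClass.IMMOTILE
    if mean_velocity_um_s >= v_fast:
        return WHOClass.FAST_PROGRESSIVE
    return WHOClass.SLOW_PROGRESSIVE


def classify_sample(
    n_immotile: int,
    n_fast: int,
    n_slow: int,
    normal_fraction: float = NORMAL_MOTILE_FRACTION,
) -> SampleResult:
    """Normal/abnormal call from class counts alone.

    Normal when (FP+SP)/(immotile+FP+SP) >= ``normal_fraction``; the
    boundary is inclusive.
    """
    if min(n_immotile, n_fast, n_slow) < 0:
        raise ValueError("counts must be non-negative")
    total = n_immotile + n_fast + n_slow
    if total == 0:
        raise ValueError("sample contains no sperm; classification undefined")
    motile_fraction = (n_fast + n_slow) / total
    return SampleResult(
        n_immotile=n_immotile,
        n_fast=n_fast,
        n_slow=n_slow,
        mean_velocity_fast=float("nan"),
        std_velocity_fast=float("nan"),
        mean_velocity_slow=float("nan"),
        std_velocity_slow=float("nan"),
        motile_fraction=motile_fraction,
        classification="normal" if motile_fraction >= normal_fraction else "abnormal",
    )


def motility_records(
    tracks: list[Track],
    fps: float,
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
    stride: int = 10,
    v_fast: float = V_FAST_UM_S,
    v_immotile_eps: float = V_IMMOTILE_EPS_UM_S,
) -> list[MotilityRecord]:
    """Per-track velocity summary and WHO class."""
    records = []
    for track in tracks:
        mean_v = track_mean_velocity(track, fps, pixel_scale_um, stride)
        if len(track) < 2:
            std_v = 0.0
        else:
            speeds = [
                step_velocity(track.centroids[i], track.centroids[i + 1], stride, fps, pixel_scale_um)
                for i in range(len(track) - 1)
            ]
            std_v = float(np.std(speeds))
        records.append(
            MotilityRecord(
                track_id=track.track_id,
                mean_velocity_um_s=mean_v,
                velocity_std_um_s=std_v,
                who_class=classify_who(mean_v, v_fast, v_immotile_eps),
            )
        )
    return records


def summarize_sample(
    tracks: list[Track],
    total_sperm_count: int,
    fps: float,
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
    stride: int = 10,
    v_fast: float = V_FAST_UM_S,
    v_immotile_eps: float = V_IMMOTILE_EPS_UM_S,
    normal_fraction: float = NORMAL_MOTILE_FRACTION,
) -> SampleResult:
    """Sample-level motility summary from tracked movers.

    ``total_sperm_count`` supplies the sperms the background model never
    sees (immotile ones); the immotile count is that total minus the
    motile tracks, plus any track whose mean speed falls below the
    immotile epsilon.
    """
    records = motility_records(tracks, fps, pixel_scale_um, stride, v_fast, v_immotile_eps)
    fast = [r.mean_velocity_um_s for r in records if r.who_class is WHOClass.FAST_PROGRESSIVE]
    slow = [r.mean_velocity_um_s for r in records if r.who_class is WHOClass.SLOW_PROGRESSIVE]
    n_motile = len(fast) + len(slow)
    if total_sperm_count < n_motile:
        raise ValueError(
            f"total_sperm_count={total_sperm_count} is below the number of "
            f"motile tracks ({n_motile})"
        )
    n_immotile = total_sperm_count - n_motile
    base = classify_sample(n_immotile, len(fast), len(slow), normal_fraction)
    return SampleResult(
        n_immotile=n_immotile,
        n_fast=len(fast),
        n_slow=len(slow),
        mean_velocity_fast=float(np.mean(fast)) if fast else float("nan"),
        std_velocity_fast=float(np.std(fast)) if fast else float("nan"),
        mean_velocity_slow=float(np.mean(slow)) if slow else float("nan"),
        std_velocity_slow=float(np.std(slow)) if slow else float("nan"),
        motile_fraction=base.motile_fraction,
        classification=base.classification,
    )
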