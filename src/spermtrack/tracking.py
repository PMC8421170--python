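"""Frame-to-frame association of sperm-head detections into tracks.

Detections are linked across sampled frames (every ``frame_stride``-th
frame, default 10) under two gates: the centroid displacement must not
exceed ``t_dis`` pixels (default 125), and the head areas must agree
within the size ratio ``t_size`` (default 1.2) — a head's apparent size
should barely change between consecutive samples. Matching is greedy
nearest-first with deterministic tie-breaks: the closest admissible pair
is linked first, then the next among the remainder, so no global
assignment problem is solved, mirroring a per-sperm
closest-and-most-similar search.

A track that finds no admissible detection is marked lost and never
revived; a sperm that re-enters the field of view starts a new identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .background import (
    BackgroundParams,
    init_mixture,
    optimize_background_threshold,
    update_and_classify,
)
from .detection import (
    DEFAULT_MIN_AREA,
    MorphologyParams,
    SpermDetection,
    detect_in_mask,
)
from .video_io import TRACK_COLUMNS, FrameSequence

__all__ = [
    "TrackingParams",
    "Track",
    "euclidean_distance",
    "size_similarity",
    "associate",
    "step_tracks",
    "track_video",
]


@dataclass(frozen=True)
class TrackingParams:
    """Association gates and the sampling stride."""

    t_dis: float = 125.0
    t_size: float = 1.2
    frame_stride: int = 10
    #: If set, t_dis is scaled by frame_stride/10 when the stride changes;
    #: by default the gate is the fixed pixel value above.
    scale_gate_with_stride: bool = False

    def __post_init__(self) -> None:
        if self.t_dis <= 0:
            raise ValueError("t_dis must be positive")
        if self.t_size < 1:
            raise ValueError("t_size must be >= 1")
        if self.frame_stride < 1:
            raise ValueError("frame_stride must be >= 1")

    @property
    def effective_t_dis(self) -> float:
        if self.scale_gate_with_stride:
            return self.t_dis * self.frame_stride / 10.0
        return self.t_dis


@dataclass
class Track:
    """One sperm identity across sampled frames."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)
    areas: list[float] = field(default_factory=list)
    status: str = "active"  # active | lost
    step_velocities_um_s: list[float] = field(default_factory=list)

    def last_centroid(self) -> tuple[float, float]:
        return self.centroids[-1]

    def last_area(self) -> float:
        return self.areas[-1]

    def append(self, detection: SpermDetection) -> None:
        self.frames.append(detection.frame_index)
        self.centroids.append(detection.centroid)
        self.areas.append(detection.elliptical_area)

    def __len__(self) -> int:
        return len(self.frames)


def euclidean_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Plain Euclidean distance between two centroids, in pixels."""
    return math.hypot(a[0] - b[0], a[1] - b[1])


def size_similarity(area_prev: float, area_curr: float, t_size: float = 1.2) -> int:
    """1 if the two head areas agree within the ratio ``t_size``, else 0.

    Symmetric in its area arguments: the larger is divided by the smaller.
    """
    if area_prev <= 0 or area_curr <= 0:
        raise ValueError("areas must be positive")
    big, small = max(area_prev, area_curr), min(area_prev, area_curr)
    return int(big / small <= t_size)


def associate(
    active_tracks: list[Track],
    detections: list[SpermDetection],
    params: TrackingParams | None = None,
) -> tuple[list[tuple[Track, SpermDetection]], list[Track], list[SpermDetection]]:
    """Greedy one-to-one matching of active tracks to new detections.

    Candidate pairs passing both the distance and the size gate are sorted
    by distance (ties: smaller size ratio, lower track id, detection
    order) and consumed greedily. Returns (matches, unmatched tracks,
    unmatched detections).
    """
    if params is None:
        params = TrackingParams()
    gate = params.effective_t_dis
    candidates = []
    for ti, track in enumerate(active_tracks):
        for di, det in enumerate(detections):
            d = euclidean_distance(track.last_centroid(), det.centroid)
            if d > gate:
                continue
            big = max(track.last_area(), det.elliptical_area)
            small = min(track.last_area(), det.elliptical_area)
            ratio = big / small
            if ratio > params.t_size:
                continue
            candidates.append((d, ratio, track.track_id, di, ti))
    candidates.sort()
    used_tracks: set[int] = set()
    used_dets: set[int] = set()
    matches = []
    for d, ratio, _tid, di, ti in candidates:
        if ti in used_tracks or di in used_dets:
            continue
        used_tracks.add(ti)
        used_dets.add(di)
        matches.append((active_tracks[ti], detections[di]))
    unmatched_tracks = [t for i, t in enumerate(active_tracks) if i not in used_tracks]
    unmatched_dets = [d for i, d in enumerate(detections) if i not in used_dets]
    return matches, unmatched_tracks, unmatched_dets


def step_tracks(
    tracks: list[Track],
    detections: list[SpermDetection],
    params: TrackingParams | None = None,
) -> list[Track]:
    """Advance all tracks by one sampled frame.

    Matched tracks are extended; unmatched active tracks become lost (and
    stay lost — a re-entering sperm is a new identity); unmatched
    detections open new tracks with fresh, monotonically increasing ids.
    The input list is updated in place and returned.
    """
    active = [t for t in tracks if t.status == "active"]
    matches, unmatched_tracks, unmatched_dets = associate(active, detections, params)
    for track, det in matches:
        track.append(det)
    for track in unmatched_tracks:
        track.status = "lost"
    next_id = max((t.track_id for t in tracks), default=-1) + 1
    for det in unmatched_dets:
        t = Track(track_id=next_id)
        t.append(det)
        tracks.append(t)
        next_id += 1
    return tracks


def track_video(
    frames: FrameSequence,
    bg_params: BackgroundParams | None = None,
    morph_params: MorphologyParams | None = None,
    min_area: float = DEFAULT_MIN_AREA,
    track_params: TrackingParams | None = None,
) -> tuple[list[Track], pd.DataFrame]:
    """Run the full two-stage pipeline over a video.

    The background mixture is updated on every frame; detection and
    association run on every ``frame_stride``-th frame once the burn-in
    period has passed. If ``bg_params.bg_t`` is unset, the automatic
    background-ratio optimization runs first. Per-step velocities (um/s)
    are attached to each track using the sequence's frame rate and pixel
    scale. Returns the track list and a flat track table.
    """
    from .motility import step_velocity  # circular at module level

    if bg_params is None:
        bg_params = BackgroundParams()
    if morph_params is None:
        morph_params = MorphologyParams()
    if track_params is None:
        track_params = TrackingParams()
    if bg_params.bg_t is None:
        bg_params = optimize_background_threshold(
            frames, bg_params, morph_params, min_area
        )

    stride = track_params.frame_stride
    burn_in = bg_params.burn_in_frames
    state = init_mixture(frames[0], bg_params)
    tracks: list[Track] = []
    for idx in range(len(frames)):
        state, mask = update_and_classify(state, frames[idx], bg_params)
        if idx >= burn_in and (idx - burn_in) % stride == 0:
            detections = detect_in_mask(mask, idx, morph_params, min_area)
            step_tracks(tracks, detections, track_params)

    for track in tracks:
        track.step_velocities_um_s = [
            step_velocity(
                track.centroids[i],
                track.centroids[i + 1],
                stride,
                frames.fps,
                frames.pixel_scale_um,
            )
            for i in range(len(track) - 1)
        ]

    rows = []
    for track in sorted(tracks, key=lambda t: t.track_id):
        for i, (f, (x, y), area) in enumerate(
            zip(track.frames, track.centroids, track.areas)
        ):
            vel = track.step_velocities_um_s[i - 1] if i > 0 else np.nan
            rows.append((track.track_id, f, x, y, area, vel))
    table = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return tracks, table
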