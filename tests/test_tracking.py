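"""Gated greedy association, track lifecycle and the full pipeline."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spermtrack import (
    SpermDetection,
    Track,
    TrackingParams,
    associate,
    euclidean_distance,
    size_similarity,
    step_tracks,
)


def _track(tid, x, y, area=200.0, frame=0):
    t = Track(track_id=tid)
    t.append(SpermDetection(frame, (x, y), area, area))
    return t


def _det(x, y, area=200.0, frame=10):
    return SpermDetection(frame, (x, y), area, area)


def test_euclidean_examples():
    assert euclidean_distance((0, 0), (3, 4)) == 5.0
    assert euclidean_distance((2, 7), (2, 7)) == 0.0


def test_distance_gate_is_inclusive_at_threshold():
    """A displacement of exactly t_dis still matches."""
    matches, _, _ = associate([_track(0, 0, 0)], [_det(125, 0)], TrackingParams())
    assert len(matches) == 1


def test_size_similarity_boundary_and_examples():
    assert size_similarity(120.0, 100.0) == 1  # ratio exactly 1.2
    assert size_similarity(100.0, 100.0) == 1
    assert size_similarity(200.0, 100.0) == 0
    with pytest.raises(ValueError):
        size_similarity(0.0, 10.0)


@settings(derandomize=True, max_examples=50)
@given(
    a=st.floats(1.0, 1e4),
    b=st.floats(1.0, 1e4),
    t=st.floats(1.0, 3.0),
)
def test_size_similarity_symmetric(a, b, t):
    assert size_similarity(a, b, t) == size_similarity(b, a, t)


def test_simple_match_within_gates():
    matches, ut, ud = associate([_track(0, 0, 0)], [_det(3, 4)])
    assert len(matches) == 1 and not ut and not ud


def test_far_detection_stays_unmatched():
    matches, ut, ud = associate([_track(0, 0, 0)], [_det(200, 0)])
    assert not matches and len(ut) == 1 and len(ud) == 1


def test_mutual_nearest_pairs_resolve_correctly():
    tracks = [_track(0, 0, 0), _track(1, 10, 0)]
    dets = [_det(1, 0), _det(9, 0)]
    matches, _, _ = associate(tracks, dets)
    got = {(t.track_id, d.centroid) for t, d in matches}
    assert got == {(0, (1, 0)), (1, (9, 0))}


def test_size_gate_blocks_close_but_dissimilar():
    matches, _, _ = associate([_track(0, 0, 0, area=100)], [_det(1, 0, area=140)])
    assert not matches


def _exhaustive_best(tracks, dets, params):
    """Oracle: enumerate all one-to-one assignments, keep the one with the
    most admissible pairs (ties: least total distance)."""
    gate = params.t_dis
    best = (0, 0.0, frozenset())
    n = min(len(tracks), len(dets))
    for k in range(n, -1, -1):
        for tsub in itertools.permutations(range(len(tracks)), k):
            for dsub in itertools.combinations(range(len(dets)), k):
                pairs = list(zip(tsub, dsub))
                dists = []
                ok = True
                for ti, di in pairs:
                    d = euclidean_distance(tracks[ti].last_centroid(), dets[di].centroid)
                    if d > gate or not size_similarity(
                        tracks[ti].last_area(), dets[di].elliptical_area, params.t_size
                    ):
                        ok = False
                        break
                    dists.append(d)
                if ok:
                    cand = (k, -sum(dists), frozenset(pairs))
                    if cand[:2] > best[:2]:
                        best = cand
        if best[0] == k and best[0] > 0:
            break
    return best[2]


def test_greedy_equals_exhaustive_when_separated(rng):
    """With objects more than twice the gate apart, greedy matching must
    coincide with the exhaustive optimum."""
    params = TrackingParams(t_dis=30.0)
    for _ in range(25):
        n = rng.integers(1, 5)
        # grid positions separated by > 2 * gate
        cells = rng.permutation(25)[:n]
        tracks, dets = [], []
        for i, cell in enumerate(cells):
            x = 40.0 + 70.0 * (cell % 5)
            y = 40.0 + 70.0 * (cell // 5)
            tracks.append(_track(i, x, y))
            if rng.random() < 0.8:  # some objects vanish
                dx, dy = rng.uniform(-10, 10, 2)
                dets.append(_det(x + dx, y + dy))
        matches, _, _ = associate(tracks, dets, params)
        got = frozenset(
            (tracks.index(t), dets.index(d)) for t, d in matches
        )
        assert got == _exhaustive_best(tracks, dets, params)


def test_lost_track_is_never_revived():
    tracks = [_track(0, 0, 0)]
    step_tracks(tracks, [], TrackingParams())
    assert tracks[0].status == "lost"
    step_tracks(tracks, [_det(0, 0)], TrackingParams())
    assert tracks[0].status == "lost"
    assert len(tracks) == 2  # re-entry spawns a fresh identity
    assert tracks[1].track_id == 1


def test_new_detections_open_new_tracks():
    tracks = [_track(0, 0, 0)]
    step_tracks(tracks, [_det(1, 0), _det(300, 300), _det(500, 100)], TrackingParams())
    assert len(tracks) == 3
    assert [t.track_id for t in tracks] == [0, 1, 2]
    assert len(tracks[0]) == 2  # the close one extended track 0


def test_departed_object_keeps_total_track_count():
    tracks = [_track(0, 0, 0), _track(1, 400, 0)]
    step_tracks(tracks, [_det(2, 0)], TrackingParams())  # object 1 left the view
    assert len(tracks) == 2
    assert tracks[1].status == "lost"


def test_matched_pairs_satisfy_both_gates_by_construction(rng):
    params = TrackingParams(t_dis=50.0)
    tracks = [_track(i, *rng.uniform(0, 300, 2), area=rng.uniform(150, 400)) for i in range(6)]
    dets = [_det(*rng.uniform(0, 300, 2), area=rng.uniform(150, 400)) for _ in range(6)]
    matches, _, _ = associate(tracks, dets, params)
    for t, d in matches:
        assert euclidean_distance(t.last_centroid(), d.centroid) <= params.t_dis
        assert size_similarity(t.last_area(), d.elliptical_area, params.t_size) == 1


def test_one_to_one_assignment(rng):
    params = TrackingParams(t_dis=500.0, t_size=10.0)  # everything admissible
    tracks = [_track(i, *rng.uniform(0, 100, 2)) for i in range(5)]
    dets = [_det(*rng.uniform(0, 100, 2)) for _ in range(3)]
    matches, ut, ud = associate(tracks, dets, params)
    assert len(matches) == 3 and len(ut) == 2 and not ud
    assert len({id(t) for t, _ in matches}) == 3
    assert len({id(d) for _, d in matches}) == 3


def test_tracking_params_validation():
    with pytest.raises(ValueError):
        TrackingParams(t_dis=0.0)
    with pytest.raises(ValueError):
        TrackingParams(t_size=0.9)
    assert TrackingParams(frame_stride=20, scale_gate_with_stride=True).effective_t_dis == 250.0
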