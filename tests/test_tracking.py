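import itertools

import numpy as np
import pytest

from trocartrack.config import NOT_VISIBLE, SceneConfig, TrackerParams
from trocartrack.detection import Detection, detect
from trocartrack.synthetic_scene import (
    override_states,
    render_frame_pair,
    simulate_timeline,
)
from trocartrack.tracking import (
    FrameSlots,
    TrackedTrocar,
    assign,
    id_switch_count,
    match_cost,
    track_sequence,
)


def make_track(tid, centroid, area):
    side = np.sqrt(area)
    box = (centroid[0] - side / 2, centroid[1] - side / 2,
           centroid[0] + side / 2, centroid[1] + side / 2)
    return TrackedTrocar(id=tid, last_centroid=centroid, last_area=area, last_box=box)


def make_det(centroid, area):
    side = np.sqrt(area)
    return Detection(
        box=(centroid[0] - side / 2, centroid[1] - side / 2,
             centroid[0] + side / 2, centroid[1] + side / 2),
        score=1.0,
    )


def brute_force_assignment(tracks, dets, params, gate):
    """Oracle: enumerate every injective partial matching; maximize matched
    count, then minimize total cost."""
    n, m = len(tracks), len(dets)
    best = (0, 0.0, {})
    for size in range(min(n, m), -1, -1):
        found = None
        for track_idx in itertools.combinations(range(n), size):
            for det_perm in itertools.permutations(range(m), size):
                cost = 0.0
                ok = True
                for i, j in zip(track_idx, det_perm):
                    c = match_cost(tracks[i], dets[j], params, gate=gate)
                    if np.isinf(c):
                        ok = False
                        break
                    cost += c
                if ok and (found is None or cost < found[0]):
                    found = (cost, dict(zip(track_idx, det_perm)))
        if found is not None:
            return size, found[0], found[1]
    return best


class TestMatchCost:
    def test_exact_overlap_costs_zero(self):
        tr = make_track(1, (50.0, 50.0), 100.0)
        assert match_cost(tr, make_det((50.0, 50.0), 100.0),
                          TrackerParams(), gate=100.0) == 0.0

    def test_zero_area_weight_reduces_to_euclidean(self):
        tr = make_track(1, (0.0, 0.0), 400.0)
        d = make_det((3.0, 4.0), 300.0)
        c = match_cost(tr, d, TrackerParams(w_area=0.0), gate=100.0)
        assert c == pytest.approx(5.0)

    def test_area_term_formula(self):
        # dist 5 + w_area * |300-400|/400 * gate 100 = 5 + 25 = 30
        tr = make_track(1, (0.0, 0.0), 400.0)
        d = make_det((3.0, 4.0), 300.0)
        c = match_cost(tr, d, TrackerParams(w_area=1.0), gate=100.0)
        assert c == pytest.approx(30.0)

    def test_beyond_gate_is_unmatchable(self):
        tr = make_track(1, (0.0, 0.0), 100.0)
        assert np.isinf(match_cost(tr, make_det((200.0, 0.0), 100.0),
                                   TrackerParams(), gate=50.0))


class TestAssign:
    def test_nearest_neighbour_keeps_ids(self):
        tracks = [make_track(1, (100.0, 100.0), 100.0),
                  make_track(2, (200.0, 200.0), 100.0)]
        dets = [make_det((102.0, 101.0), 100.0), make_det((198.0, 203.0), 100.0)]
        matches, _, _ = assign(tracks, dets, TrackerParams(), gate=50.0)
        assert matches == {0: 0, 1: 1}

    def test_five_detections_four_matched_one_discarded(self):
        tracks = [make_track(i + 1, (50.0 * i, 50.0), 100.0) for i in range(4)]
        dets = [make_det((50.0 * i + 1.0, 50.0), 100.0) for i in range(4)]
        dets.append(make_det((26.0, 50.0), 100.0))  # extra, between tracks
        matches, unmatched_tracks, unmatched_dets = assign(
            tracks, dets, TrackerParams(), gate=40.0
        )
        assert len(matches) == 4 and unmatched_tracks == []
        assert unmatched_dets == [4]

    def test_area_consistency_overrides_pure_distance(self):
        # with a heavy area weight, each detection goes to the track of
        # matching size even though track B is nearer the large detection
        params = TrackerParams(w_area=10.0)
        tracks = [make_track(1, (150.0, 150.0), 400.0),
                  make_track(2, (160.0, 150.0), 100.0)]
        dets = [make_det((155.0, 150.0), 400.0), make_det((156.0, 150.0), 100.0)]
        matches, _, _ = assign(tracks, dets, params, gate=100.0)
        assert matches == {0: 0, 1: 1}
        size, cost, oracle = brute_force_assignment(tracks, dets, params, 100.0)
        assert matches == oracle

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        params = TrackerParams(w_area=0.5)
        for _ in range(150):
            n, m = rng.integers(0, 5), rng.integers(0, 7)
            tracks = [make_track(i + 1, tuple(rng.uniform(0, 200, 2)),
                                 float(rng.uniform(50, 500))) for i in range(n)]
            dets = [make_det(tuple(rng.uniform(0, 200, 2)),
                             float(rng.uniform(50, 500))) for _ in range(m)]
            matches, _, _ = assign(tracks, dets, params, gate=150.0)
            size, cost, _ = brute_force_assignment(tracks, dets, params, 150.0)
            got = sum(match_cost(tracks[i], dets[j], params, gate=150.0)
                      for i, j in matches.items())
            assert len(matches) == size
            assert got == pytest.approx(cost)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        params = TrackerParams()
        tracks = [make_track(i + 1, tuple(rng.uniform(0, 100, 2)), 100.0)
                  for i in range(3)]
        dets = [make_det(tuple(rng.uniform(0, 100, 2)), 100.0) for _ in range(4)]
        ref, _, _ = assign(tracks, dets, params, gate=200.0)
        perm = [2, 0, 3, 1]
        shuffled = [dets[j] for j in perm]
        got, _, _ = assign(tracks, shuffled, params, gate=200.0)
        assert {i: perm[j] for i, j in got.items()} == ref


class TestTrackSequence:
    def test_single_stationary_detection_one_stable_track(self):
        dets = [[make_det((100.0, 100.0), 100.0)] for _ in range(100)]
        slots, tracks = track_sequence(dets, TrackerParams())
        assert len(tracks) == 1 and tracks[0].id == 1
        assert all(fs.slots[1][3] for fs in slots)

    def test_identity_survives_occlusion_episode(self, encoder):
        cfg = SceneConfig(duration_s=15, seed=33)
        truth = simulate_timeline(cfg)
        # trocar 2 disappears under the occluder for 5 frames mid-scene
        truth = override_states(truth, cfg, 2, 40, 45, NOT_VISIBLE)
        det_frames = []
        for t in range(truth.n_frames):
            c1, _ = render_frame_pair(truth, cfg, t)
            det_frames.append(detect(c1))
        slots, _ = track_sequence(
            det_frames, TrackerParams(id_mode="position"),
            frame_size=cfg.frame_size_c1,
        )
        switches = id_switch_count(slots, truth)
        assert switches.events == 0
        assert not slots[42].slots[3][3]  # invisible during the episode
        assert slots[50].slots[3][3]  # same ID visible again after it

    def test_global_translation_does_not_switch_ids(self):
        base = np.array([[50.0, 50.0], [150.0, 50.0], [50.0, 120.0], [150.0, 120.0]])
        det_frames = []
        for t in range(30):
            shift = np.array([3.0 * t, 0.0])
            det_frames.append([make_det(tuple(p + shift), 144.0) for p in base])
        slots, tracks = track_sequence(det_frames, TrackerParams(),
                                       frame_size=(320, 180))
        assert len(tracks) == 4
        for fs in slots:  # slot centroids stay in the same relative order
            xs = [fs.slots[i][0][0] for i in (1, 2, 3, 4)]
            assert xs[0] < xs[1] and xs[2] < xs[3]

    def test_never_more_than_max_tracks_identities(self):
        rng = np.random.default_rng(8)
        det_frames = []
        for _ in range(60):
            k = rng.integers(0, 8)
            det_frames.append(
                [make_det(tuple(rng.uniform(0, 300, 2)), float(rng.uniform(50, 400)))
                 for _ in range(k)]
            )
        slots, tracks = track_sequence(det_frames, TrackerParams(max_tracks=4))
        assert len(tracks) <= 4
        assert len({tr.id for tr in tracks}) == len(tracks)


class TestIdSwitchCount:
    def _truth_two_boxes(self, n_frames):
        from types import SimpleNamespace

        boxes = np.empty((n_frames, 2, 4))
        boxes[:, 0] = (10.0, 10.0, 30.0, 30.0)
        boxes[:, 1] = (100.0, 10.0, 120.0, 30.0)
        return SimpleNamespace(boxes=boxes, n_trocars=2)

    def test_perfect_tracking_counts_zero(self):
        truth = self._truth_two_boxes(20)
        slots = [
            FrameSlots(frame=t, slots={
                1: ((20.0, 20.0), 400.0, (10.0, 10.0, 30.0, 30.0), True),
                2: ((110.0, 20.0), 400.0, (100.0, 10.0, 120.0, 30.0), True),
            })
            for t in range(20)
        ]
        sw = id_switch_count(slots, truth)
        assert (sw.frames, sw.events) == (0, 0)

    def test_permanent_switch_counts_tail_frames_one_event(self):
        n, k = 30, 20
        truth = self._truth_two_boxes(n)
        a = (10.0, 10.0, 30.0, 30.0)
        b = (100.0, 10.0, 120.0, 30.0)
        slots = []
        for t in range(n):  # one track follows truth 0, then jumps to truth 1
            box = a if t < k else b
            slots.append(FrameSlots(frame=t, slots={
                1: (((box[0] + box[2]) / 2, 20.0), 400.0, box, True)
            }))
        sw = id_switch_count(slots, truth)
        assert sw.frames == n - k
        assert sw.events == 1

    def test_empty_scene_counts_zero(self):
        sw = id_switch_count([], self._truth_two_boxes(0))
        assert (sw.frames, sw.events) == (0, 0)
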