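"""Capped-identity centroid tracking.

Identity assignment uses the prior knowledge that a laparoscopic scene
contains at most four trocars: at most ``max_tracks`` persistent IDs are ever
created, tracks are frozen (never deleted) when lost, and a frozen track can
be revived inside a larger re-acquisition gate. Frame-to-frame matching
minimizes a cost combining centroid Euclidean distance with a bounding-box
area-consistency term, which stabilizes identities under camera shifts:

    cost = ||c_track - c_det||
         + w_area * |A_det - A_track| / max(A_det, A_track) * gate

pairs farther apart than the gate are unmatchable. The assignment is the
optimal (minimum total cost, maximum cardinality) one-to-one matching —
with at most four tracks this equals the exhaustive-enumeration optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import TrackerParams
from .detection import Detection, box_iou

__all__ = [
    "TrackedTrocar",
    "match_cost",
    "assign",
    "track_sequence",
    "id_switch_count",
    "IdSwitches",
]

logger = logging.getLogger(__name__)

_BIG = 1e12  # stands in for an unmatchable (gated-out) pair


@dataclass
class TrackedTrocar:
    """A persistent trocar identity with its state history."""

    id: int
    last_centroid: tuple[float, float]
    last_area: float
    last_box: tuple[float, float, float, float]
    frames_missing: int = 0
    visible: bool = True
    #: per processed frame: (centroid | None, area | None, visible)
    history: list = field(default_factory=list)

    @property
    def frozen(self) -> bool:
        return self.frames_missing > 0


def match_cost(track: TrackedTrocar, det: Detection, params: TrackerParams,
               gate: float | None = None) -> float:
    """Matching cost between a track and a detection; ``inf`` when gated out.

    The area term is the relative area difference scaled to distance units by
    the gate, weighted by ``params.w_area`` (0 ablates it to plain Euclidean
    distance).
    """
    if gate is None:
        gate = params.max_match_dist
        if gate is None:
            raise ValueError("explicit gate required when params.max_match_dist is None")
    (tx, ty), (dx, dy) = track.last_centroid, det.centroid
    dist = float(np.hypot(tx - dx, ty - dy))
    if dist > gate:
        return float("inf")
    area_rel = abs(det.area - track.last_area) / max(det.area, track.last_area)
    return dist + params.w_area * area_rel * gate


def assign(
    tracks: list[TrackedTrocar],
    dets: list[Detection],
    params: TrackerParams,
    gate: float | None = None,
    reacquire_gate: float | None = None,
) -> tuple[dict[int, int], list[int], list[int]]:
    """Optimal one-to-one matching of active tracks to detections.

    Returns ``(matches, unmatched_tracks, unmatched_dets)`` where ``matches``
    maps track index -> detection index. The matching maximizes the number of
    within-gate pairs and, among those, minimizes total cost (Hungarian
    algorithm on the gated cost matrix). Tracks frozen longer than
    ``params.max_frames_missing`` use the larger re-acquisition gate.
    """
    if not tracks or not dets:
        return {}, list(range(len(tracks))), list(range(len(dets)))
    if gate is None:
        gate = params.max_match_dist
    if reacquire_gate is None:
        reacquire_gate = params.reacquire_factor * gate
    cost = np.empty((len(tracks), len(dets)))
    for i, tr in enumerate(tracks):
        g = reacquire_gate if tr.frames_missing > params.max_frames_missing else gate
        for j, d in enumerate(dets):
            c = match_cost(tr, d, params, gate=g)
            cost[i, j] = _BIG if np.isinf(c) else c
    rows, cols = linear_sum_assignment(cost)
    matches = {int(i): int(j) for i, j in zip(rows, cols) if cost[i, j] < _BIG}
    unmatched_tracks = [i for i in range(len(tracks)) if i not in matches]
    unmatched_dets = [j for j in range(len(dets)) if j not in matches.values()]
    return matches, unmatched_tracks, unmatched_dets


def _position_id(centroid: tuple[float, float], frame_size: tuple[int, int],
                 taken: set[int]) -> int:
    """Quadrant-based functional ID (1 TL, 2 TR, 3 BL, 4 BR), falling back to
    the lowest free ID when the quadrant's ID is taken."""
    w, h = frame_size
    qid = 1 + (centroid[0] >= w / 2) + 2 * (centroid[1] >= h / 2)
    if qid not in taken:
        return int(qid)
    return min(i for i in range(1, 5) if i not in taken)


@dataclass
class FrameSlots:
    """Tracker output for one frame: one slot per identity 1..max_tracks."""

    frame: int
    #: id -> (centroid, area, box, visible); missing ids have never been born
    slots: dict


def track_sequence(
    detections_per_frame: list[list[Detection]],
    params: TrackerParams | None = None,
    frame_size: tuple[int, int] = (320, 180),
) -> tuple[list[FrameSlots], list[TrackedTrocar]]:
    """Run the capped-identity tracker over a scene.

    IDs are stable for the scene's lifetime: a track unmatched for a while is
    frozen, never deleted, and can be revived by a detection inside the
    re-acquisition gate. A detection that cannot be matched once all
    ``max_tracks`` identities exist is discarded (logged as a warning).
    Returns per-frame slot states and the final track objects.
    """
    params = params or TrackerParams()
    gate = params.gate_for(frame_size)
    tracks: list[TrackedTrocar] = []
    out: list[FrameSlots] = []
    for t, dets in enumerate(detections_per_frame):
        matches, unmatched_tracks, unmatched_dets = assign(tracks, dets, params, gate=gate)
        for i, j in matches.items():
            tr, d = tracks[i], dets[j]
            tr.last_centroid = d.centroid
            tr.last_area = d.area
            tr.last_box = d.box
            tr.frames_missing = 0
            tr.visible = True
        for i in unmatched_tracks:
            tracks[i].frames_missing += 1
            tracks[i].visible = False
        for j in unmatched_dets:
            if len(tracks) < params.max_tracks:
                d = dets[j]
                taken = {tr.id for tr in tracks}
                if params.id_mode == "position":
                    new_id = _position_id(d.centroid, frame_size, taken)
                else:
                    new_id = min(i for i in range(1, params.max_tracks + 1) if i not in taken)
                tracks.append(
                    TrackedTrocar(
                        id=new_id,
                        last_centroid=d.centroid,
                        last_area=d.area,
                        last_box=d.box,
                    )
                )
            else:
                logger.warning(
                    "frame %d: detection at %s discarded — all %d identities "
                    "exist and none is within its gate",
                    t, dets[j].centroid, params.max_tracks,
                )
        for tr in tracks:
            tr.history.append(
                (tr.last_centroid if tr.visible else None,
                 tr.last_area if tr.visible else None,
                 tr.visible)
            )
        out.append(
            FrameSlots(
                frame=t,
                slots={
                    tr.id: (tr.last_centroid, tr.last_area, tr.last_box, tr.visible)
                    for tr in tracks
                },
            )
        )
    return out, tracks


@dataclass(frozen=True)
class IdSwitches:
    """ID-switch counts against ground truth.

    ``frames``: frames where a track's matched ground-truth identity differs
    from that track's majority identity. ``events``: number of identity
    transitions (consecutive observed matches that differ) — a permanent swap
    counts once.
    """

    frames: int
    events: int


def id_switch_count(frame_slots: list[FrameSlots], truth) -> IdSwitches:
    """Count identity switches of tracker output against ``SceneTruth``.

    Each visible slot in each frame is matched to the ground-truth trocar
    whose box overlaps it most (IoU > 0). A track's reference identity is its
    majority matched identity over the scene.
    """
    per_track: dict[int, list[int]] = {}
    for fs in frame_slots:
        t = fs.frame
        true_boxes = truth.boxes[t]
        for tid, (_, _, box, visible) in fs.slots.items():
            if not visible:
                continue
            best_iou, best_i = 0.0, -1
            for i in range(truth.n_trocars):
                tb = true_boxes[i]
                if np.any(np.isnan(tb)):
                    continue
                iou = box_iou(box, tb)
                if iou > best_iou:
                    best_iou, best_i = iou, i
            if best_i >= 0:
                per_track.setdefault(tid, []).append(best_i)
    frames = 0
    events = 0
    for seq in per_track.values():
        vals, counts = np.unique(seq, return_counts=True)
        majority = int(vals[np.argmax(counts)])
        frames += int(sum(1 for s in seq if s != majority))
        events += int(sum(1 for a, b in zip(seq, seq[1:]) if a != b))
    return IdSwitches(frames=frames, events=events)
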