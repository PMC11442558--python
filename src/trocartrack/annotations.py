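"""JSON-lines annotation schema for scene ground truth.

One file = one scene. The first line is a header carrying the schema version,
frame geometry and the simulator layout; every following line is one
:class:`AnnotationRecord`:

* per-trocar records (``camera="c1"``, ``trocar_id`` 1-4) carry the bounding
  box and occupancy state of one trocar in one frame — ``box`` is ``null``
  exactly when the state is ``not_visible``;
* camera-level records (``trocar_id=null``) carry the C1 camera pose and
  illumination factor, and the C2 correlate-cue flag.

Frames are 0-based; boxes are half-open ``[x_min, y_min, x_max, y_max)`` in
pixels. JSON floats round-trip exactly, so write -> read is lossless.
"""

from __future__ import annotations

import json
from typing import Iterable

import numpy as np

from .config import NOT_VISIBLE, STATE_CODES, STATE_NAMES

SCHEMA_NAME = "trocartrack-annotations"
SCHEMA_VERSION = "1.0"


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation file; names the offending line."""


def _check_version(version: str) -> None:
    major = str(version).split(".")[0]
    if major != SCHEMA_VERSION.split(".")[0]:
        raise AnnotationError(
            f"unsupported schema version {version!r} (reader supports major "
            f"{SCHEMA_VERSION.split('.')[0]})"
        )


def write_truth(truth, path) -> None:
    """Serialize a :class:`~trocartrack.synthetic_scene.SceneTruth`."""
    header = {
        "schema": SCHEMA_NAME,
        "version": SCHEMA_VERSION,
        "fps": truth.fps,
        "frame_size_c1": list(truth.frame_size_c1),
        "frame_size_c2": list(truth.frame_size_c2),
        "n_frames": truth.n_frames,
        "n_trocars": truth.n_trocars,
        "layout": {
            "base_centers": truth.base_centers.tolist(),
            "radii": truth.radii.tolist(),
            "occluder": list(truth.occluder),
        },
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        for t in range(truth.n_frames):
            dx, dy, dth = truth.camera_pose[t]
            fh.write(
                json.dumps(
                    {
                        "frame": t,
                        "camera": "c1",
                        "trocar_id": None,
                        "box": None,
                        "state": None,
                        "pose": [float(dx), float(dy), float(dth)],
                        "illum": float(truth.illum[t]),
                    }
                )
                + "\n"
            )
            fh.write(
                json.dumps(
                    {
                        "frame": t,
                        "camera": "c2",
                        "trocar_id": None,
                        "box": None,
                        "state": None,
                        "cue": bool(truth.c2_cue[t]),
                    }
                )
                + "\n"
            )
            for i in range(truth.n_trocars):
                state = int(truth.states[t, i])
                box = truth.boxes[t, i]
                fh.write(
                    json.dumps(
                        {
                            "frame": t,
                            "camera": "c1",
                            "trocar_id": i + 1,
                            "box": None if state == NOT_VISIBLE else [float(v) for v in box],
                            "state": STATE_NAMES[state],
                        }
                    )
                    + "\n"
                )


def read_annotations(path):
    """Parse and validate an annotation file into a ``SceneTruth``.

    Raises :class:`AnnotationError` (with 1-based line numbers) on schema
    mismatch, malformed lines, duplicate ``(frame, trocar_id)`` records,
    out-of-bounds boxes, or a box/state inconsistency.
    """
    from .synthetic_scene import SceneTruth

    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise AnnotationError("empty file: missing header line")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as e:
        raise AnnotationError(f"line 1: invalid JSON header: {e}") from e
    if header.get("schema") != SCHEMA_NAME:
        raise AnnotationError(f"line 1: unexpected schema {header.get('schema')!r}")
    _check_version(header.get("version", "?"))

    n_frames = int(header["n_frames"])
    n_trocars = int(header["n_trocars"])
    w1, h1 = header["frame_size_c1"]
    layout = header.get("layout", {})

    states = np.full((n_frames, n_trocars), -1, dtype=np.int8)
    boxes = np.full((n_frames, n_trocars, 4), np.nan)
    pose = np.zeros((n_frames, 3))
    illum = np.ones(n_frames)
    cue = np.zeros(n_frames, dtype=bool)
    seen: set[tuple[int, int]] = set()

    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as e:
            raise AnnotationError(f"line {lineno}: invalid JSON: {e}") from e
        try:
            t = int(rec["frame"])
            camera = rec["camera"]
        except (KeyError, TypeError, ValueError) as e:
            raise AnnotationError(f"line {lineno}: missing frame/camera: {e}") from e
        if not 0 <= t < n_frames:
            raise AnnotationError(f"line {lineno}: frame {t} out of range [0, {n_frames})")
        tid = rec.get("trocar_id")
        if tid is None:
            if camera == "c1":
                pose[t] = rec.get("pose", [0, 0, 0])
                illum[t] = rec.get("illum", 1.0)
            elif camera == "c2":
                cue[t] = bool(rec.get("cue", False))
            else:
                raise AnnotationError(f"line {lineno}: unknown camera {camera!r}")
            continue
        if not 1 <= int(tid) <= n_trocars:
            raise AnnotationError(f"line {lineno}: trocar_id {tid} out of range 1-{n_trocars}")
        i = int(tid) - 1
        if (t, i) in seen:
            raise AnnotationError(f"line {lineno}: duplicate record for (frame={t}, trocar_id={tid})")
        seen.add((t, i))
        state_name = rec.get("state")
        if state_name not in STATE_CODES:
            raise AnnotationError(f"line {lineno}: unknown state {state_name!r}")
        state = STATE_CODES[state_name]
        box = rec.get("box")
        if (box is None) != (state == NOT_VISIBLE):
            raise AnnotationError(
                f"line {lineno}: box must be null exactly when state is not_visible"
            )
        states[t, i] = state
        if box is not None:
            x0, y0, x1, y1 = (float(v) for v in box)
            if not (0 <= x0 < x1 <= w1 and 0 <= y0 < y1 <= h1):
                raise AnnotationError(
                    f"line {lineno}: box {box} outside frame bounds {w1}x{h1}"
                )
            boxes[t, i] = (x0, y0, x1, y1)

    missing = [(t, i) for t in range(n_frames) for i in range(n_trocars) if states[t, i] < 0]
    if missing:
        t, i = missing[0]
        raise AnnotationError(
            f"missing state record for (frame={t}, trocar_id={i + 1}) "
            f"(+{len(missing) - 1} more)"
        )

    return SceneTruth(
        n_trocars=n_trocars,
        fps=float(header["fps"]),
        frame_size_c1=(int(w1), int(h1)),
        frame_size_c2=tuple(int(v) for v in header["frame_size_c2"]),
        states=states,
        boxes=boxes,
        camera_pose=pose,
        illum=illum,
        c2_cue=cue,
        base_centers=np.asarray(layout.get("base_centers", np.zeros((n_trocars, 2)))),
        radii=np.asarray(layout.get("radii", np.zeros(n_trocars))),
        occluder=tuple(layout.get("occluder", (0, 0, 0, 0))),
    )


def write_jsonl(path, header: dict, records: Iterable[dict]) -> None:
    """Write a generic header + records JSON-lines artifact."""
    with open(path, "w") as fh:
        fh.write(json.dumps({"schema_version": SCHEMA_VERSION, **header}) + "\n")
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_jsonl(path) -> tuple[dict, list[dict]]:
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise AnnotationError("empty file: missing header line")
    header = json.loads(lines[0])
    _check_version(header.get("schema_version", header.get("version", "?")))
    return header, [json.loads(ln) for ln in lines[1:]]
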