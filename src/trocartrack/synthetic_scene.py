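"""Synthetic dual-view surgical scenes with ground-truth trocar annotations.

The simulator emulates the structure of extra-abdominal cholecystectomy
recordings: a close-up camera (C1) sees up to four trocar-like discs on a
body-surface background, each in one of three occupancy states (``empty``,
``occupied``, ``not_visible``) following a semi-Markov timeline with a
configurable stationary distribution; a distant camera (C2) renders a coarse
correlate cue. The camera jitters (bounded random-walk translation and
rotation) and global illumination drifts multiplicatively.

Geometry and identity semantics follow the standard port layout: trocars 1-2
are 10 mm working/camera ports and render with a larger radius than the 5 mm
ports 3-4. A trocar becomes ``not_visible`` by moving under a rendered
occluder bar at the top of the frame (an instrument cable / lamp edge stand-
in), not by deletion, so downstream trackers must survive reappearance.

Coordinates are pixels, origin top-left, boxes half-open
``[x_min, y_min, x_max, y_max)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import NOT_VISIBLE, OCCUPIED, SceneConfig

__all__ = [
    "SceneTruth",
    "simulate_timeline",
    "render_frame_pair",
    "render_frames",
    "override_states",
    "write_truth",
]

_BG_C1 = 40.0
_DISC_VALUE = 220.0
_SHAFT_VALUE = 15.0
_OCCLUDER_VALUE = 10.0
_BG_C2 = 60.0
_CUE_VALUE = 230.0


@dataclass
class SceneTruth:
    """Ground truth for one simulated scene.

    ``boxes[t, i]`` is NaN-filled exactly when ``states[t, i]`` is
    ``not_visible`` — the disc is rendered under the occluder and absent from
    the visible C1 frame. Identifiers (array index i = trocar ID i+1) are
    constant over the scene's lifetime.
    """

    n_trocars: int
    fps: float
    frame_size_c1: tuple[int, int]
    frame_size_c2: tuple[int, int]
    states: np.ndarray        # (T, n) int8, codes from config.STATE_NAMES
    boxes: np.ndarray         # (T, n, 4) float, NaN when not visible
    camera_pose: np.ndarray   # (T, 3): dx, dy, dtheta_deg
    illum: np.ndarray         # (T,) multiplicative illumination factor
    c2_cue: np.ndarray        # (T,) bool
    base_centers: np.ndarray  # (n, 2) home position of each trocar (px)
    radii: np.ndarray         # (n,) disc radius (px)
    occluder: tuple[float, float, float, float] = field(default=(0, 0, 0, 0))

    @property
    def n_frames(self) -> int:
        return int(self.states.shape[0])

    def centers_at(self, t: int) -> np.ndarray:
        """Posed disc centers at frame t (n, 2), ignoring visibility."""
        dx, dy, dtheta = self.camera_pose[t]
        w, h = self.frame_size_c1
        c = np.array([w / 2.0, h / 2.0])
        th = np.deg2rad(dtheta)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return (self.base_centers - c) @ rot.T + c + np.array([dx, dy])

    def __eq__(self, other: object) -> bool:  # NaN-aware structural equality
        if not isinstance(other, SceneTruth):
            return NotImplemented
        scalar = (
            self.n_trocars == other.n_trocars
            and self.fps == other.fps
            and tuple(self.frame_size_c1) == tuple(other.frame_size_c1)
            and tuple(self.frame_size_c2) == tuple(other.frame_size_c2)
            and tuple(self.occluder) == tuple(other.occluder)
        )
        return scalar and all(
            np.array_equal(getattr(self, k), getattr(other, k), equal_nan=(k == "boxes"))
            for k in ("states", "boxes", "camera_pose", "illum", "c2_cue",
                      "base_centers", "radii")
        )


def _layout(config: SceneConfig) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Home positions, radii and occluder bar for the port layout."""
    w, h = config.frame_size_c1
    scale = w / 320.0
    homes = np.array(
        [[0.25 * w, 0.35 * h], [0.75 * w, 0.35 * h],
         [0.25 * w, 0.80 * h], [0.75 * w, 0.80 * h]]
    )[: config.n_trocars]
    # IDs 1-2 are 10 mm ports, IDs 3-4 are 5 mm ports.
    radii = (np.array([12.0, 12.0, 8.0, 8.0]) * scale)[: config.n_trocars]
    bar_h = 2 * 12.0 * scale + 2
    occluder = (0.0, 0.0, float(w), float(bar_h))
    return homes, radii, occluder


def _sample_state_sequence(
    rng: np.random.Generator, n_frames: int, pi: np.ndarray, dwell: np.ndarray
) -> np.ndarray:
    """Renewal sequence of states: each segment's state is drawn with
    probability proportional to pi_j / dwell_j and lasts a geometric dwell
    with mean dwell_j, so the long-run time fraction in state j is pi_j."""
    rates = np.where(pi > 0, pi / dwell, 0.0)
    rates = rates / rates.sum()
    out = np.empty(n_frames, dtype=np.int8)
    t = 0
    while t < n_frames:
        s = int(rng.choice(3, p=rates))
        d = int(rng.geometric(min(1.0, 1.0 / dwell[s])))
        out[t : t + d] = s
        t += d
    return out


def _compute_cue(states: np.ndarray, mode: str) -> np.ndarray:
    n_frames = states.shape[0]
    if mode == "occupancy":
        return states[:, 0] == OCCUPIED
    change = np.zeros(n_frames, dtype=bool)
    if n_frames > 1:
        change[1:] = np.any(states[1:] != states[:-1], axis=1)
    cue = np.zeros(n_frames, dtype=bool)
    for off in range(-2, 3):
        shifted = np.roll(change, -off)
        if off > 0:
            shifted[-off:] = False
        elif off < 0:
            shifted[:-off] = False
        cue |= shifted
    return cue


def _boxes_from_states(
    states: np.ndarray,
    camera_pose: np.ndarray,
    base_centers: np.ndarray,
    radii: np.ndarray,
    frame_size: tuple[int, int],
) -> np.ndarray:
    n_frames, n = states.shape
    w, h = frame_size
    boxes = np.full((n_frames, n, 4), np.nan)
    c = np.array([w / 2.0, h / 2.0])
    for t in range(n_frames):
        dx, dy, dtheta = camera_pose[t]
        th = np.deg2rad(dtheta)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        centers = (base_centers - c) @ rot.T + c + np.array([dx, dy])
        for i in range(n):
            if states[t, i] == NOT_VISIBLE:
                continue
            cx, cy = centers[i]
            r = radii[i]
            boxes[t, i] = (
                max(cx - r, 0.0), max(cy - r, 0.0),
                min(cx + r, float(w)), min(cy + r, float(h)),
            )
    return boxes


def simulate_timeline(config: SceneConfig) -> SceneTruth:
    """Draw the ground-truth timeline of a scene (no pixels yet).

    Per trocar, the occupancy sequence is a renewal/semi-Markov chain whose
    empirical state frequencies converge to ``config.state_stationary`` as
    the duration grows; the camera pose is a bounded random walk; the
    illumination factor drifts inside ``brightness_range``. Reproducible
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_frames = config.n_frames
    n = config.n_trocars
    pi = np.asarray(config.state_stationary, dtype=float)
    dwell = np.asarray(config.dwell_means, dtype=float)

    states = np.empty((n_frames, n), dtype=np.int8)
    for i in range(n):
        states[:, i] = _sample_state_sequence(rng, n_frames, pi, dwell)

    jt, jr = config.jitter
    pose = np.zeros((n_frames, 3))
    if n_frames:
        steps = np.column_stack(
            [
                rng.uniform(-jt, jt, size=(n_frames, 2)) if jt > 0 else np.zeros((n_frames, 2)),
                rng.uniform(-jr, jr, size=n_frames) if jr > 0 else np.zeros(n_frames),
            ]
        )
        steps[0] = 0.0
        bound = np.array([4 * jt, 4 * jt, 4 * jr])
        cur = np.zeros(3)
        for t in range(n_frames):
            cur = np.clip(cur + steps[t], -bound, bound)
            pose[t] = cur

    lo, hi = config.brightness_range
    illum = np.empty(n_frames)
    if n_frames:
        b = 0.5 * (lo + hi)
        step = (hi - lo) / 20.0
        for t in range(n_frames):
            b = float(np.clip(b + rng.uniform(-step, step), lo, hi)) if hi > lo else b
            illum[t] = b

    base_centers, radii, occluder = _layout(config)
    boxes = _boxes_from_states(states, pose, base_centers, radii, config.frame_size_c1)
    cue = _compute_cue(states, config.c2_cue)
    return SceneTruth(
        n_trocars=n,
        fps=config.fps,
        frame_size_c1=config.frame_size_c1,
        frame_size_c2=config.frame_size_c2,
        states=states,
        boxes=boxes,
        camera_pose=pose,
        illum=illum,
        c2_cue=cue,
        base_centers=base_centers,
        radii=radii,
        occluder=occluder,
    )


def override_states(
    truth: SceneTruth,
    config: SceneConfig,
    trocar: int,
    t0: int,
    t1: int,
    state: int,
) -> SceneTruth:
    """Return a copy of ``truth`` with trocar ``trocar`` forced to ``state``
    on frames ``[t0, t1)``, with boxes and the C2 cue kept consistent.

    Used to script deterministic episodes (e.g. a guaranteed occlusion) on
    top of a sampled timeline.
    """
    states = truth.states.copy()
    states[t0:t1, trocar] = state
    boxes = _boxes_from_states(
        states, truth.camera_pose, truth.base_centers, truth.radii, truth.frame_size_c1
    )
    return SceneTruth(
        n_trocars=truth.n_trocars,
        fps=truth.fps,
        frame_size_c1=truth.frame_size_c1,
        frame_size_c2=truth.frame_size_c2,
        states=states,
        boxes=boxes,
        camera_pose=truth.camera_pose.copy(),
        illum=truth.illum.copy(),
        c2_cue=_compute_cue(states, config.c2_cue),
        base_centers=truth.base_centers.copy(),
        radii=truth.radii.copy(),
        occluder=truth.occluder,
    )


def _draw_disc(img: np.ndarray, cx: float, cy: float, r: float, value: float) -> None:
    h, w = img.shape
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= r * r
    img[y0:y1, x0:x1][mask] = value


def _draw_shaft(img: np.ndarray, cx: float, cy: float, r: float, contrast: float) -> None:
    if contrast <= 0:
        return
    h, w = img.shape
    half_w = 1.5
    y0 = max(int(cy - 2.2 * r), 0)
    y1 = min(int(np.ceil(cy)) + 1, h)
    x0 = max(int(cx - half_w), 0)
    x1 = min(int(np.ceil(cx + half_w)), w)
    if y0 >= y1 or x0 >= x1:
        return
    region = img[y0:y1, x0:x1]
    img[y0:y1, x0:x1] = (1.0 - contrast) * region + contrast * _SHAFT_VALUE


def render_frame_pair(
    truth: SceneTruth, config: SceneConfig, t: int
) -> tuple[np.ndarray, np.ndarray]:
    """Render the (C1, C2) uint8 grayscale frame pair for frame ``t``.

    Deterministic given ``truth``: all randomness lives in the timeline.
    Visible trocars are filled discs; ``occupied`` ones additionally carry a
    dark instrument-shaft segment entering the disc from above; not-visible
    ones sit under the occluder bar. Global brightness is scaled by the
    frame's illumination factor.
    """
    w, h = truth.frame_size_c1
    img = np.full((h, w), _BG_C1)
    centers = truth.centers_at(t)
    ox0, oy0, ox1, oy1 = truth.occluder
    bar_cy = 0.5 * (oy0 + oy1)
    for i in range(truth.n_trocars):
        state = truth.states[t, i]
        r = truth.radii[i]
        if state == NOT_VISIBLE:
            # moved under the occluder bar: drawn, then covered.
            cx, cy = truth.base_centers[i, 0], bar_cy
        else:
            cx, cy = centers[i]
        _draw_disc(img, cx, cy, r, _DISC_VALUE)
        if state == OCCUPIED:
            _draw_shaft(img, cx, cy, r, config.shaft_contrast)
    img[int(oy0) : int(oy1), int(ox0) : int(ox1)] = _OCCLUDER_VALUE
    c1 = np.clip(img * truth.illum[t], 0, 255).astype(np.uint8)

    w2, h2 = truth.frame_size_c2
    c2f = np.full((h2, w2), _BG_C2)
    c2f += np.linspace(0.0, 20.0, w2)[None, :]  # fixed coarse scene gradient
    if truth.c2_cue[t]:
        s = max(4, h2 // 4)
        c2f[4 : 4 + s, 4 : 4 + s] = _CUE_VALUE
    c2 = np.clip(c2f, 0, 255).astype(np.uint8)
    return c1, c2


def render_frames(truth: SceneTruth, config: SceneConfig):
    """Yield (t, c1_frame, c2_frame) for every frame of the scene."""
    for t in range(truth.n_frames):
        c1, c2 = render_frame_pair(truth, config, t)
        yield t, c1, c2


def write_truth(truth: SceneTruth, path) -> None:
    """Serialize ``truth`` in the JSON-lines annotation schema (round-trips
    losslessly through :func:`trocartrack.annotations.read_annotations`)."""
    from . import annotations

    annotations.write_truth(truth, path)
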