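"""Configuration dataclasses shared across the pipeline stages.

All coordinates are pixels with the origin at the top-left corner, x to the
right, y down. Bounding boxes are axis-aligned ``[x_min, y_min, x_max, y_max)``
half-open intervals. Frame indices are 0-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Occupancy-state codes, in label order.
EMPTY, OCCUPIED, NOT_VISIBLE = 0, 1, 2
STATE_NAMES = ("empty", "occupied", "not_visible")
STATE_CODES = {name: code for code, name in enumerate(STATE_NAMES)}

#: Class distribution of the occupancy states in recorded cholecystectomies
#: (empty / occupied / not visible); used as the default stationary
#: distribution of the simulator and for the default focal-loss class weights.
DEFAULT_STATE_FREQS = (0.1072, 0.6535, 0.2393)


class ConfigurationError(ValueError):
    """An invalid configuration value."""


@dataclass
class SceneConfig:
    """Parameters of one synthetic dual-camera surgical scene.

    The defaults give a desk-scale scene: 320x180 close-up (C1) frames at
    6 fps — the rate at which real recordings are annotated — with up to four
    trocar-like discs, the recorded occupancy-state imbalance as the
    stationary distribution, bounded camera jitter and mild illumination
    drift. The full recording geometry (1920x1080 @ 30 fps) is available by
    overriding ``frame_size_c1`` and ``fps``.
    """

    n_trocars: int = 4
    frame_size_c1: tuple[int, int] = (320, 180)  # (width, height)
    frame_size_c2: tuple[int, int] = (160, 90)
    fps: float = 6.0
    duration_s: float = 30.0
    state_stationary: tuple[float, float, float] = DEFAULT_STATE_FREQS
    #: Mean dwell time per state, in frames (empty, occupied, not_visible).
    #: Desk-scale dwells, scaled down from clinical instrument-exchange
    #: timescales in proportion to the scene length, keeping the chain's
    #: mixing time far below the 10^4-frame calibration horizon.
    dwell_means: tuple[float, float, float] = (2.0, 4.0, 3.0)
    #: Max per-frame camera translation step (px) and rotation step (deg).
    jitter: tuple[float, float] = (2.0, 0.5)
    #: Multiplicative illumination factor interval.
    brightness_range: tuple[float, float] = (0.9, 1.1)
    #: Contrast of the instrument shaft drawn on occupied trocars, in [0, 1].
    #: 0 renders `occupied` identically to `empty` (used for constructed-
    #: signal experiments where only the C2 cue separates the two states).
    shaft_contrast: float = 1.0
    #: What the distant-view (C2) cue encodes: "transition" — cue present iff
    #: any trocar changes state within +-2 frames; "occupancy" — cue present
    #: iff trocar 1 is occupied.
    c2_cue: str = "transition"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trocars not in (1, 2, 3, 4):
            raise ConfigurationError(f"n_trocars must be 1-4, got {self.n_trocars}")
        p = np.asarray(self.state_stationary, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"state_stationary must be 3 non-negative numbers summing to 1, got {self.state_stationary}"
            )
        if any(d <= 0 for d in self.dwell_means):
            raise ConfigurationError("all dwell means must be > 0")
        if self.fps <= 0:
            raise ConfigurationError("fps must be > 0")
        if self.duration_s < 0:
            raise ConfigurationError("duration_s must be >= 0")
        if not 0.0 <= self.shaft_contrast <= 1.0:
            raise ConfigurationError("shaft_contrast must be in [0, 1]")
        if self.c2_cue not in ("transition", "occupancy"):
            raise ConfigurationError(f"unknown c2_cue mode {self.c2_cue!r}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        for key in ("frame_size_c1", "frame_size_c2", "state_stationary",
                    "dwell_means", "jitter", "brightness_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class DetectorParams:
    """Reference classical detector: contrast threshold + connected components.

    The threshold sits halfway between the background level (frame median) and
    the frame maximum, so a uniform brightness gain does not move the decision
    boundary. Components smaller than ``min_area`` are discarded; the score of
    a component is its fill ratio (component area / bounding-box area).
    """

    min_area: int = 20
    #: A frame whose maximum is below ``min_contrast`` times the background
    #: level is treated as containing no trocars.
    min_contrast: float = 1.35
    gain: float = 1.0


@dataclass
class TrackerParams:
    """Capped-identity centroid tracker parameters.

    At most ``max_tracks`` persistent identities ever exist; tracks are frozen
    when unmatched for more than ``max_frames_missing`` frames, never deleted,
    and a frozen track can be revived by a detection inside the larger
    re-acquisition gate ``reacquire_factor * max_match_dist``.
    """

    max_tracks: int = 4
    w_area: float = 0.5
    #: Matching gate in pixels. If None, defaults to 10% of the frame
    #: diagonal at track time.
    max_match_dist: Optional[float] = None
    max_frames_missing: int = 10
    reacquire_factor: float = 2.0
    #: "birth" — IDs in order of first appearance; "position" — IDs by frame
    #: quadrant (1 top-left, 2 top-right, 3 bottom-left, 4 bottom-right),
    #: mirroring the anatomical port layout.
    id_mode: str = "birth"

    def __post_init__(self) -> None:
        if not 1 <= self.max_tracks <= 4:
            raise ConfigurationError("max_tracks must be in [1, 4]")
        if self.w_area < 0:
            raise ConfigurationError("w_area must be >= 0")
        if self.max_match_dist is not None and self.max_match_dist <= 0:
            raise ConfigurationError("max_match_dist must be > 0")
        if self.id_mode not in ("birth", "position"):
            raise ConfigurationError(f"unknown id_mode {self.id_mode!r}")

    def gate_for(self, frame_size: tuple[int, int]) -> float:
        if self.max_match_dist is not None:
            return float(self.max_match_dist)
        w, h = frame_size
        return 0.1 * float(np.hypot(w, h))


@dataclass
class FocalLossParams:
    """Multiclass focal loss FL = -alpha_y (1 - p_y)^gamma log p_y.

    ``alpha`` defaults to the normalized inverse of the recorded occupancy
    class frequencies, down-weighting the dominant `occupied` class.
    """

    gamma: float = 2.0
    alpha: tuple[float, float, float] = None  # type: ignore[assignment]
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ConfigurationError("gamma must be >= 0")
        if self.alpha is None:
            inv = 1.0 / np.asarray(DEFAULT_STATE_FREQS)
            self.alpha = tuple(inv / inv.sum())
        a = np.asarray(self.alpha, dtype=float)
        if a.shape != (3,) or np.any(a <= 0):
            raise ConfigurationError("alpha must be 3 positive weights")


@dataclass
class TemporalModelConfig:
    """Architecture and training hyperparameters of the temporal classifier."""

    kind: str = "mstcn"  # lstm | gru | mstcn
    input_dim: int = 384  # 6 * D for the default reference encoder (D = 64)
    hidden: int = 128
    seq_len: int = 12
    batch: int = 32
    # MS-TCN structure: n_stages stages of layers_per_stage dilated residual
    # layers, kernel 3, dilations doubling 1, 2, 4, ... within a stage.
    n_stages: int = 2
    layers_per_stage: int = 4
    kernel_size: int = 3
    n_trocars: int = 4
    n_states: int = 3
    lr: float = 1e-3
    max_epochs: int = 50
    patience: int = 5
    focal: FocalLossParams = field(default_factory=FocalLossParams)

    def __post_init__(self) -> None:
        if self.kind not in ("lstm", "gru", "mstcn"):
            raise ConfigurationError(f"unknown temporal model kind {self.kind!r}")
        for name in ("input_dim", "hidden", "seq_len", "batch", "n_stages",
                     "layers_per_stage", "kernel_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if isinstance(self.focal, dict):
            self.focal = FocalLossParams(**self.focal)
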