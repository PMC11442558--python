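"""Frame preprocessing and per-frame trocar detection.

The production detector in this problem setting is a learned object detector
(the intended configuration for a plugged-in model is documented in
``docs/methods.md``); here it is a pluggable contract: anything that maps a
frame to a list of :class:`Detection` can drive the tracker. The bundled
reference detector is classical — background-relative contrast threshold,
connected components, minimum-area filter — and is exact on the synthetic
scenes this package simulates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .config import DetectorParams

__all__ = ["Detection", "brighten", "detect", "detector_metrics", "box_iou"]


@dataclass(frozen=True)
class Detection:
    """One detector output: half-open pixel box, confidence, centroid, area."""

    box: tuple[float, float, float, float]
    score: float

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def centroid(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.box
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.box
        return (x1 - x0) * (y1 - y0)


def brighten(frame: np.ndarray, gain: float) -> np.ndarray:
    """Uniformly scale pixel intensities by ``gain``, clipping to the valid
    range (mirrors the brightness preprocessing applied to dim close-up
    recordings before annotation)."""
    if gain <= 0:
        raise ValueError(f"gain must be > 0, got {gain}")
    if np.issubdtype(frame.dtype, np.integer):
        info = np.iinfo(frame.dtype)
        out = np.clip(frame.astype(np.float64) * gain, info.min, info.max)
        return out.astype(frame.dtype)
    # float frames use the [0, 1] convention
    return np.clip(frame * gain, 0.0, 1.0)


def detect(frame: np.ndarray, params: DetectorParams | None = None) -> list[Detection]:
    """Reference classical detector: threshold relative to the background
    level, label connected components, emit one Detection per component.

    The threshold is the midpoint of the frame median (background) and frame
    maximum, so a uniform brightness gain leaves the decision unchanged. A
    frame with no sufficiently bright structure yields an empty list. Scores
    are component fill ratios (area / bounding-box area), so round discs
    score ~pi/4; output is sorted by descending score.
    """
    params = params or DetectorParams()
    f = frame.astype(np.float64)
    if params.gain != 1.0:
        f = f * params.gain
    bg = float(np.median(f))
    mx = float(f.max())
    if mx < params.min_contrast * bg + 5.0:
        return []
    thresh = 0.5 * (bg + mx)
    labels = measure.label(f > thresh, connectivity=2)
    dets: list[Detection] = []
    for region in measure.regionprops(labels):
        if region.area < params.min_area:
            continue
        y0, x0, y1, x1 = region.bbox  # skimage bbox is half-open
        fill = float(region.area) / float((y1 - y0) * (x1 - x0))
        dets.append(Detection(box=(float(x0), float(y0), float(x1), float(y1)),
                              score=min(fill, 1.0)))
    dets.sort(key=lambda d: -d.score)
    return dets


def box_iou(a, b) -> float:
    """Intersection-over-union of two half-open boxes."""
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union if union > 0 else 0.0


def _match_frame(pred_boxes, true_boxes, iou_threshold: float) -> tuple[int, int, int]:
    """Greedy one-to-one matching by descending IoU; returns (TP, FP, FN)."""
    pairs = []
    for i, pb in enumerate(pred_boxes):
        for j, tb in enumerate(true_boxes):
            iou = box_iou(pb, tb)
            if iou >= iou_threshold:
                pairs.append((iou, i, j))
    pairs.sort(key=lambda x: -x[0])
    used_p: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        tp += 1
    return tp, len(pred_boxes) - tp, len(true_boxes) - tp


def prf_from_counts(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


def detector_metrics(
    predictions: list[list[Detection]],
    truth,
    iou_threshold: float = 0.5,
) -> tuple[float, float, float]:
    """Precision / recall / F1 of per-frame detections against scene truth.

    ``predictions[t]`` are the detections of frame ``t``; ground-truth boxes
    are the visible trocar boxes of ``truth`` (a ``SceneTruth``). Matching is
    greedy one-to-one by descending IoU at ``iou_threshold``; counts are
    pooled over frames (micro-averaged).
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError("iou_threshold must be in (0, 1]")
    tp = fp = fn = 0
    for t, dets in enumerate(predictions):
        true_boxes = [b for b in truth.boxes[t] if not np.any(np.isnan(b))]
        dtp, dfp, dfn = _match_frame([d.box for d in dets], true_boxes, iou_threshold)
        tp, fp, fn = tp + dtp, fp + dfp, fn + dfn
    return prf_from_counts(tp, fp, fn)
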