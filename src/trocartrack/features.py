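"""Fused per-timestep features: [X1, X2, X3, X4, XC1, XC2].

Each tracked trocar slot contributes the encoding of its adaptively padded
crop (an invisible slot contributes a zero vector); the two full camera
frames contribute one encoding each. The six blocks are concatenated in a
fixed order, so ablations (dropping XC1 or XC2) are pure block slices.

The encoder is a contract — any deterministic map from an
``input_size x input_size`` patch to a fixed-dimension vector works; a deep
backbone plug-in may use its native dimension. The bundled
:class:`ReferenceEncoder` is a small fixed-weight convolutional network
suited to CPU pipelines: its weights are seeded and never trained, and each
patch is normalized by its mean intensity so that global illumination
changes cancel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize as _resize

BLOCK_NAMES = ("x1", "x2", "x3", "x4", "xc1", "xc2")
N_BLOCKS = len(BLOCK_NAMES)

__all__ = [
    "BLOCK_NAMES",
    "N_BLOCKS",
    "FusedFeature",
    "ReferenceEncoder",
    "crop_adaptive_pad",
    "fuse",
    "extract_features",
    "drop_blocks",
    "make_sequences",
    "SequenceDataset",
]


def crop_adaptive_pad(frame: np.ndarray, box, target: int) -> np.ndarray:
    """Crop ``box`` from ``frame`` with adaptive padding to a square patch.

    The box is expanded symmetrically along its shorter side to a square,
    preferring real frame content as padding and zero-filling beyond the
    frame borders, then resampled (bilinear) to ``target x target``. The box
    content therefore ends up centered and unstretched. Raises ``ValueError``
    if the box does not intersect the frame.
    """
    h, w = frame.shape[:2]
    x0, y0, x1, y1 = box
    if x1 <= 0 or y1 <= 0 or x0 >= w or y0 >= h or x0 >= x1 or y0 >= y1:
        raise ValueError(f"box {box} does not intersect frame {w}x{h}")
    ix0, iy0 = int(np.floor(x0)), int(np.floor(y0))
    ix1, iy1 = int(np.ceil(x1)), int(np.ceil(y1))
    bw, bh = ix1 - ix0, iy1 - iy0
    side = max(bw, bh)
    pad_x, pad_y = side - bw, side - bh
    sx0, sy0 = ix0 - pad_x // 2, iy0 - pad_y // 2
    sx1, sy1 = sx0 + side, sy0 + side

    patch = np.zeros((side, side), dtype=np.float64)
    fx0, fy0 = max(sx0, 0), max(sy0, 0)
    fx1, fy1 = min(sx1, w), min(sy1, h)
    if fx1 > fx0 and fy1 > fy0:
        patch[fy0 - sy0 : fy1 - sy0, fx0 - sx0 : fx1 - sx0] = frame[fy0:fy1, fx0:fx1]
    if side == target:
        return patch
    return _resize(patch, (target, target), order=1, preserve_range=True,
                   anti_aliasing=False)


class ReferenceEncoder:
    """Fixed-weight two-layer CNN encoder (contract: patch -> R^dim).

    Architecture: mean-normalize -> conv3x3/stride2 (8 ch) -> ReLU ->
    conv3x3/stride2 (16 ch) -> ReLU -> adaptive average pool 2x2 -> flatten
    (64) -> optional fixed linear projection to ``dim``. Weights are drawn
    once from a seeded generator and never trained, so the encoder is
    deterministic: identical patches map to identical vectors.
    """

    def __init__(self, dim: int = 64, input_size: int = 32, seed: int = 12345):
        self.dim = int(dim)
        self.input_size = int(input_size)
        rng = np.random.default_rng(seed)
        self._w1 = rng.normal(0.0, np.sqrt(2.0 / 9.0), size=(8, 1, 3, 3))
        self._w2 = rng.normal(0.0, np.sqrt(2.0 / (9.0 * 8)), size=(16, 8, 3, 3))
        self._proj = None
        if self.dim != 64:
            self._proj = rng.normal(0.0, np.sqrt(1.0 / 64.0), size=(64, self.dim))

    @staticmethod
    def _conv_s2(x: np.ndarray, w: np.ndarray) -> np.ndarray:
        win = sliding_window_view(x, (3, 3), axis=(2, 3))[:, :, ::2, ::2]
        out = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))
        return np.moveaxis(out, -1, 1)

    @staticmethod
    def _adaptive_pool_2x2(x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        hs, ws = (h + 1) // 2, (w + 1) // 2
        quads = [
            x[:, :, :hs, :ws], x[:, :, :hs, ws:],
            x[:, :, hs:, :ws], x[:, :, hs:, ws:],
        ]
        return np.stack([q.mean(axis=(2, 3)) for q in quads], axis=2)  # (n, c, 4)

    def encode_batch(self, patches: np.ndarray) -> np.ndarray:
        """Encode (N, s, s) patches to (N, dim); s must equal input_size."""
        if patches.ndim != 3 or patches.shape[1:] != (self.input_size,) * 2:
            raise ValueError(
                f"expected (N, {self.input_size}, {self.input_size}) patches, "
                f"got {patches.shape}"
            )
        x = patches.astype(np.float64)
        means = x.mean(axis=(1, 2), keepdims=True)
        x = x / np.maximum(means, 1e-6) - 1.0  # illumination-invariant
        x = x[:, None]
        x = np.maximum(self._conv_s2(x, self._w1), 0.0)
        x = np.maximum(self._conv_s2(x, self._w2), 0.0)
        feat = self._adaptive_pool_2x2(x).reshape(len(x), -1)  # (N, 64)
        if self._proj is not None:
            feat = feat @ self._proj
        return feat

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        return self.encode_batch(patch[None])[0]


@dataclass(frozen=True)
class FusedFeature:
    """The six feature blocks of one timestep, in fixed order."""

    t: int
    blocks: np.ndarray  # (6, D)

    @property
    def concat(self) -> np.ndarray:
        return self.blocks.reshape(-1)

    def block(self, name: str) -> np.ndarray:
        return self.blocks[BLOCK_NAMES.index(name)]


def _resize_frame(frame: np.ndarray, size: int) -> np.ndarray:
    return _resize(frame.astype(np.float64), (size, size), order=1,
                   preserve_range=True, anti_aliasing=False)


def fuse(frame_c1: np.ndarray, frame_c2: np.ndarray, slots: dict,
         encoder) -> FusedFeature:
    """Build one timestep's fused feature from the tracker's four ID slots
    and the two full frames. Invisible / never-born slots are zero vectors."""
    size = encoder.input_size
    blocks = np.zeros((N_BLOCKS, encoder.dim))
    patches, where = [], []
    for sid in (1, 2, 3, 4):
        entry = slots.get(sid)
        if entry is None or not entry[3]:
            continue
        patches.append(crop_adaptive_pad(frame_c1, entry[2], size))
        where.append(sid - 1)
    patches.append(_resize_frame(frame_c1, size))
    where.append(4)
    patches.append(_resize_frame(frame_c2, size))
    where.append(5)
    encoded = encoder.encode_batch(np.stack(patches))
    if encoded.shape[1] != encoder.dim:
        raise ValueError(
            f"encoder produced dimension {encoded.shape[1]}, declared {encoder.dim}"
        )
    for row, b in zip(encoded, where):
        blocks[b] = row
    return FusedFeature(t=-1, blocks=blocks)


def extract_features(frames_c1, frames_c2, frame_slots, encoder,
                     batch: int = 256) -> np.ndarray:
    """Encode a whole scene to a (T, 6, D) float32 feature array.

    ``frames_c1`` / ``frames_c2`` are sequences of frames aligned with the
    tracker's per-frame ``frame_slots``. Crops and frame resizes are batched
    through the encoder for throughput.
    """
    size = encoder.input_size
    T = len(frame_slots)
    out = np.zeros((T, N_BLOCKS, encoder.dim), dtype=np.float32)
    patches: list[np.ndarray] = []
    targets: list[tuple[int, int]] = []

    def flush() -> None:
        if not patches:
            return
        enc = encoder.encode_batch(np.stack(patches))
        for row, (t, b) in zip(enc, targets):
            out[t, b] = row
        patches.clear()
        targets.clear()

    for t, (f1, f2, fs) in enumerate(zip(frames_c1, frames_c2, frame_slots)):
        for sid in (1, 2, 3, 4):
            entry = fs.slots.get(sid)
            if entry is None or not entry[3]:
                continue
            patches.append(crop_adaptive_pad(f1, entry[2], size))
            targets.append((t, sid - 1))
        patches.append(_resize_frame(f1, size))
        targets.append((t, 4))
        patches.append(_resize_frame(f2, size))
        targets.append((t, 5))
        if len(patches) >= batch:
            flush()
    flush()
    return out


def drop_blocks(features: np.ndarray, blocks: tuple[str, ...]) -> np.ndarray:
    """Remove named blocks from a (T, 6, D) feature array (ablation)."""
    unknown = set(blocks) - set(BLOCK_NAMES)
    if unknown:
        raise ValueError(f"unknown feature blocks {sorted(unknown)}")
    keep = [i for i, name in enumerate(BLOCK_NAMES) if name not in blocks]
    if not keep:
        raise ValueError("cannot drop all feature blocks")
    return features[:, keep, :]


def make_sequences(features: np.ndarray, labels: np.ndarray, seq_len: int,
                   stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Sliding length-L windows over one scene's feature stream.

    Returns ``(X, Y)`` with X of shape (N, L, F) — feature blocks flattened —
    and Y of shape (N, L, n_trocar_slots). Windows never span scene
    boundaries (call per scene). A stream shorter than ``seq_len`` yields
    empty output with a warning.
    """
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    T = features.shape[0]
    flat = features.reshape(T, -1)
    if T < seq_len:
        warnings.warn(
            f"stream of length {T} shorter than sequence length {seq_len}; "
            "no windows produced",
            stacklevel=2,
        )
        return (np.empty((0, seq_len, flat.shape[1]), dtype=flat.dtype),
                np.empty((0, seq_len) + labels.shape[1:], dtype=labels.dtype))
    starts = np.arange(0, T - seq_len + 1, stride)
    X = np.stack([flat[s : s + seq_len] for s in starts])
    Y = np.stack([labels[s : s + seq_len] for s in starts])
    return X, Y


class SequenceDataset:
    """Lazy window dataset over multiple scenes (windows never cross scenes).

    Stores per-scene feature/label arrays and a global window index;
    materializes only one batch at a time.
    """

    def __init__(self, scenes: list[tuple[np.ndarray, np.ndarray]],
                 seq_len: int, stride: int = 1):
        self.seq_len = int(seq_len)
        self.stride = int(stride)
        self._feats = [f.reshape(f.shape[0], -1).astype(np.float32) for f, _ in scenes]
        self._labels = [l for _, l in scenes]
        self.index: list[tuple[int, int]] = []
        for si, f in enumerate(self._feats):
            for s in range(0, f.shape[0] - self.seq_len + 1, self.stride):
                self.index.append((si, s))

    def __len__(self) -> int:
        return len(self.index)

    @property
    def feature_dim(self) -> int:
        return self._feats[0].shape[1] if self._feats else 0

    def gather(self, idx) -> tuple[np.ndarray, np.ndarray]:
        X = np.stack([self._feats[si][s : s + self.seq_len] for si, s in (self.index[i] for i in idx)])
        Y = np.stack([self._labels[si][s : s + self.seq_len] for si, s in (self.index[i] for i in idx)])
        return X, Y

    def batches(self, batch_size: int, rng: np.random.Generator | None = None):
        order = np.arange(len(self.index))
        if rng is not None:
            rng.shuffle(order)
        for k in range(0, len(order), batch_size):
            yield self.gather(order[k : k + batch_size])
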