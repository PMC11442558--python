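"""Temporal occupancy-state classifiers: LSTM, GRU and MS-TCN.

All three consume windows of fused feature vectors (sequence length L,
input dimension 6*D by default) and emit, for every timestep, a probability
triple over {empty, occupied, not_visible} for each of the four trocar ID
slots — a single trunk with one joint 4x3 head, so all trocars share
temporal context. Training uses the multiclass focal loss
``FL = -alpha_y (1 - p_y)^gamma log p_y`` to counter the heavy class
imbalance of occupancy states, with not-a-label padding cells (label < 0)
excluded from the average.

The MS-TCN follows the multi-stage design: each stage is a stack of dilated
residual 1-D convolutions (kernel 3, dilations doubling per layer) and every
stage after the first refines the previous stage's probability output. The
training loss averages over stages (deep supervision); prediction uses the
final stage.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import f1_score

from .autodiff import Adam, Tensor, concat
from .config import FocalLossParams, TemporalModelConfig

__all__ = [
    "focal_loss",
    "TemporalClassifier",
    "LSTMClassifier",
    "GRUClassifier",
    "MSTCN",
    "build_model",
    "fit",
    "predict",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# focal loss
# ---------------------------------------------------------------------------

def focal_loss(probs: np.ndarray, y, params: FocalLossParams | None = None):
    """Multiclass focal loss of predicted probabilities against true classes.

    ``probs`` is one probability vector (C,) with scalar ``y``, or a batch
    (N, C) with ``y`` of shape (N,). With ``gamma=0`` and unit ``alpha`` this
    is exactly cross-entropy. ``p_y = 0`` is clamped by ``params.eps`` inside
    the log, so the loss is finite; ``p_y = 1`` gives exactly 0.
    """
    params = params or FocalLossParams()
    probs = np.asarray(probs, dtype=np.float64)
    y = np.asarray(y)
    alpha = np.asarray(params.alpha)
    if probs.ndim == 1:
        p_y = probs[int(y)]
        return float(-alpha[int(y)] * (1.0 - p_y) ** params.gamma
                     * np.log(max(p_y, params.eps)))
    p_y = np.take_along_axis(probs, y[..., None], axis=-1)[..., 0]
    return -alpha[y] * (1.0 - p_y) ** params.gamma * np.log(np.maximum(p_y, params.eps))


def _focal_loss_tensor(probs: Tensor, y: np.ndarray, fp: FocalLossParams) -> Tensor:
    """Mean focal loss over all labeled (trocar, timestep) cells.

    ``probs``: Tensor (..., 3); ``y``: int array matching ``probs`` without
    the class axis; cells with ``y < 0`` are padding and excluded.
    """
    mask = y >= 0
    y_safe = np.where(mask, y, 0)
    onehot = np.eye(3)[y_safe] * mask[..., None]
    alpha = np.asarray(fp.alpha)[y_safe] * mask
    p_y = (probs * Tensor(onehot)).sum(axis=-1)
    per_cell = Tensor(-alpha) * (Tensor(1.0) - p_y).pow(fp.gamma) * p_y.clip_min(fp.eps).log()
    n = max(int(mask.sum()), 1)
    return per_cell.sum() * (1.0 / n)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class TemporalClassifier:
    """Base: holds config, parameter list, and the shared classification head."""

    def __init__(self, config: TemporalModelConfig, seed: int = 0):
        self.config = config
        self.rng = np.random.default_rng(seed)
        self.params: list[Tensor] = []

    def _param(self, *shape, scale: float | None = None) -> Tensor:
        fan_in = shape[0] if len(shape) > 1 else max(shape[0], 1)
        s = scale if scale is not None else 1.0 / np.sqrt(fan_in)
        t = Tensor(self.rng.normal(0.0, s, size=shape), requires_grad=True)
        self.params.append(t)
        return t

    def _zeros(self, *shape) -> Tensor:
        t = Tensor(np.zeros(shape), requires_grad=True)
        self.params.append(t)
        return t

    @property
    def out_cells(self) -> int:
        return self.config.n_trocars * self.config.n_states

    def forward_stages(self, x: Tensor) -> list[Tensor]:
        """All supervision outputs, each (B, L, n_trocars, n_states)."""
        raise NotImplementedError

    def forward(self, x) -> Tensor:
        """Final per-timestep state probabilities (B, L, n_trocars, n_states)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        return self.forward_stages(x)[-1]

    def _check_input(self, x: Tensor) -> None:
        if x.shape[-1] != self.config.input_dim:
            raise ValueError(
                f"input dimension {x.shape[-1]} != configured {self.config.input_dim}"
            )


class _RecurrentBase(TemporalClassifier):
    n_gates = 4

    def __init__(self, config: TemporalModelConfig, seed: int = 0):
        super().__init__(config, seed)
        F, H = config.input_dim, config.hidden
        self.wx = self._param(F, self.n_gates * H)
        self.wh = self._param(H, self.n_gates * H)
        self.b = self._zeros(self.n_gates * H)
        self.w_head = self._param(H, self.out_cells, scale=0.01)
        self.b_head = self._zeros(self.out_cells)

    def _recur(self, xp: Tensor, B: int, L: int) -> list[Tensor]:
        raise NotImplementedError

    def forward_stages(self, x: Tensor) -> list[Tensor]:
        self._check_input(x)
        B, L, F = x.shape
        H = self.config.hidden
        xp = (x.reshape(B * L, F) @ self.wx).reshape(B, L, self.n_gates * H)
        hs = self._recur(xp, B, L)
        h_all = concat([h.reshape(B, 1, H) for h in hs], axis=1)  # (B, L, H)
        logits = h_all.reshape(B * L, H) @ self.w_head + self.b_head
        probs = logits.reshape(B, L, self.config.n_trocars, self.config.n_states).softmax(-1)
        return [probs]


class LSTMClassifier(_RecurrentBase):
    """Single-layer LSTM trunk with a joint 4x3 softmax head."""

    n_gates = 4

    def _recur(self, xp: Tensor, B: int, L: int) -> list[Tensor]:
        H = self.config.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        hs = []
        for t in range(L):
            z = xp[:, t] + h @ self.wh + self.b
            i = z[:, 0 * H : 1 * H].sigmoid()
            f = z[:, 1 * H : 2 * H].sigmoid()
            g = z[:, 2 * H : 3 * H].tanh()
            o = z[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            hs.append(h)
        return hs


class GRUClassifier(_RecurrentBase):
    """Single-layer GRU trunk with a joint 4x3 softmax head."""

    n_gates = 3

    def _recur(self, xp: Tensor, B: int, L: int) -> list[Tensor]:
        H = self.config.hidden
        h = Tensor(np.zeros((B, H)))
        hs = []
        for t in range(L):
            hp = h @ self.wh + self.b
            xt = xp[:, t]
            r = (xt[:, 0 * H : 1 * H] + hp[:, 0 * H : 1 * H]).sigmoid()
            z = (xt[:, 1 * H : 2 * H] + hp[:, 1 * H : 2 * H]).sigmoid()
            n = (xt[:, 2 * H : 3 * H] + r * hp[:, 2 * H : 3 * H]).tanh()
            h = (Tensor(1.0) - z) * n + z * h
            hs.append(h)
        return hs


class MSTCN(TemporalClassifier):
    """Multi-stage temporal convolutional network.

    Stage 1 maps features to per-timestep probabilities; each later stage
    takes the previous stage's probabilities as input and refines them. Each
    stage: 1x1 input projection -> ``layers_per_stage`` dilated residual
    layers (kernel ``kernel_size``, dilation 2^l, symmetric zero padding) ->
    1x1 output head. Receptive field of one stage with kernel 3 and
    dilations 1..2^(L-1) is 1 + 2 (2^L - 1) frames.
    """

    def __init__(self, config: TemporalModelConfig, seed: int = 0):
        super().__init__(config, seed)
        self.stages = []
        for s in range(config.n_stages):
            in_dim = config.input_dim if s == 0 else self.out_cells
            stage = {
                "w_in": self._param(in_dim, config.hidden),
                "b_in": self._zeros(config.hidden),
                "layers": [],
                "w_out": self._param(config.hidden, self.out_cells, scale=0.01),
                "b_out": self._zeros(self.out_cells),
            }
            for l in range(config.layers_per_stage):
                k = config.kernel_size
                H = config.hidden
                stage["layers"].append(
                    {
                        "dilation": 2**l,
                        "w_conv": [self._param(H, H, scale=np.sqrt(2.0 / (k * H)))
                                   for _ in range(k)],
                        "b_conv": self._zeros(H),
                        "w_1x1": self._param(H, H),
                        "b_1x1": self._zeros(H),
                    }
                )
            self.stages.append(stage)

    @staticmethod
    def _dilated_conv(x: Tensor, taps: list[Tensor], bias: Tensor, dilation: int) -> Tensor:
        """Symmetric same-padded dilated 1-D convolution along axis 1."""
        B, L, H = x.shape
        k = len(taps)
        half = (k - 1) // 2
        pad = half * dilation
        zeros = Tensor(np.zeros((B, pad, H)))
        xp = concat([zeros, x, zeros], axis=1)
        out = None
        for j, w in enumerate(taps):
            shifted = xp[:, j * dilation : j * dilation + L]
            term = shifted @ w
            out = term if out is None else out + term
        return out + bias

    def _run_stage(self, stage: dict, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        h = x @ stage["w_in"] + stage["b_in"]
        for layer in stage["layers"]:
            z = self._dilated_conv(h, layer["w_conv"], layer["b_conv"],
                                   layer["dilation"]).relu()
            z = z @ layer["w_1x1"] + layer["b_1x1"]
            h = h + z
        return h @ stage["w_out"] + stage["b_out"]

    def forward_stages(self, x: Tensor) -> list[Tensor]:
        self._check_input(x)
        B, L, _ = x.shape
        outs = []
        inp = x
        for stage in self.stages:
            logits = self._run_stage(stage, inp)
            probs = logits.reshape(B, L, self.config.n_trocars,
                                   self.config.n_states).softmax(-1)
            outs.append(probs)
            inp = probs.reshape(B, L, self.out_cells)
        return outs


_KINDS = {"lstm": LSTMClassifier, "gru": GRUClassifier, "mstcn": MSTCN}


def build_model(config: TemporalModelConfig, seed: int = 0) -> TemporalClassifier:
    return _KINDS[config.kind](config, seed)


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------

def _val_macro_f1(model: TemporalClassifier, val_ds, batch: int) -> float:
    ys, ps = [], []
    for X, Y in val_ds.batches(batch):
        probs = model.forward(X).data  # (B, L, 4, 3)
        pred = probs.argmax(-1)
        mask = Y >= 0
        ys.append(Y[mask])
        ps.append(pred[mask])
    y = np.concatenate(ys) if ys else np.array([])
    p = np.concatenate(ps) if ps else np.array([])
    if y.size == 0:
        return 0.0
    return float(f1_score(y, p, average="macro", zero_division=0))


def fit(model: TemporalClassifier, train_ds, val_ds, seed: int = 0,
        verbose: bool = False) -> list[dict]:
    """Train with Adam + focal loss; early stop on validation macro-F1.

    Deterministic given ``seed`` (the only randomness is batch shuffling).
    Restores the best-validation weights before returning. Returns the
    per-epoch history (train loss, validation macro-F1).
    """
    if len(train_ds) == 0:
        raise ValueError("empty training set")
    cfg = model.config
    rng = np.random.default_rng(seed)
    opt = Adam(model.params, lr=cfg.lr)
    best_f1, best_state, since_best = -1.0, None, 0
    history: list[dict] = []
    for epoch in range(cfg.max_epochs):
        losses = []
        for X, Y in train_ds.batches(cfg.batch, rng):
            x = Tensor(np.asarray(X, dtype=np.float64))
            stage_probs = model.forward_stages(x)
            loss = None
            for probs in stage_probs:
                term = _focal_loss_tensor(probs, Y, cfg.focal)
                loss = term if loss is None else loss + term
            loss = loss * (1.0 / len(stage_probs))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_f1 = _val_macro_f1(model, val_ds, cfg.batch) if val_ds is not None and len(val_ds) else float("nan")
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_macro_f1": val_f1})
        if verbose:
            print(f"epoch {epoch:3d}  loss {np.mean(losses):.4f}  val macro-F1 {val_f1:.4f}")
        if val_ds is not None and len(val_ds):
            if val_f1 > best_f1 + 1e-6:
                best_f1 = val_f1
                best_state = [p.data.copy() for p in model.params]
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
    if best_state is not None:
        for p, d in zip(model.params, best_state):
            p.data = d
    return history


def predict(model: TemporalClassifier, features: np.ndarray, stride: int = 1,
            batch: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame occupancy states for one scene's feature stream.

    ``features``: (T, n_blocks, D) or (T, F). Sliding windows of the model's
    sequence length are classified and the probabilities of all windows
    overlapping a frame are averaged before the argmax. Streams shorter than
    one window are right-padded by repeating the last frame.

    Returns ``(states (T, n_trocars) int, probs (T, n_trocars, n_states))``.
    """
    cfg = model.config
    T = features.shape[0]
    flat = features.reshape(T, -1).astype(np.float64)
    L = cfg.seq_len
    padded_T = max(T, L)
    if padded_T > T:
        flat = np.concatenate([flat, np.repeat(flat[-1:], padded_T - T, axis=0)])
    starts = np.arange(0, padded_T - L + 1, stride)
    if starts[-1] != padded_T - L:  # always cover the tail
        starts = np.append(starts, padded_T - L)
    prob_sum = np.zeros((padded_T, cfg.n_trocars, cfg.n_states))
    counts = np.zeros(padded_T)
    for k in range(0, len(starts), batch):
        chunk = starts[k : k + batch]
        X = np.stack([flat[s : s + L] for s in chunk])
        probs = model.forward(X).data
        for row, s in enumerate(chunk):
            prob_sum[s : s + L] += probs[row]
            counts[s : s + L] += 1
    probs = prob_sum / counts[:, None, None]
    return probs[:T].argmax(-1), probs[:T]


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------

def save_model(model: TemporalClassifier, path) -> None:
    import dataclasses
    import json

    from ._npz import savez_deterministic

    cfg = dataclasses.asdict(model.config)
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.params)}
    savez_deterministic(path, config=np.array(json.dumps(cfg)), **arrays)


def load_model(path) -> TemporalClassifier:
    import json

    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["config"]))
        focal = cfg_dict.pop("focal")
        focal["alpha"] = tuple(focal["alpha"])
        cfg = TemporalModelConfig(focal=FocalLossParams(**focal), **cfg_dict)
        model = build_model(cfg, seed=0)
        for i, p in enumerate(model.params):
            p.data = data[f"param_{i}"]
    return model
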