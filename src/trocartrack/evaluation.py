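"""Per-trocar occupancy metrics, scene-level k-fold CV, and feature ablation.

Metrics convention: for each trocar the three occupancy states are scored
one-vs-rest and macro-averaged (micro available by option); classes absent
from both truth and predictions are excluded from the macro average, and
``F1 := 0`` where ``P + R = 0``. Folds partition whole scenes (surgeries) so
no scene contributes to both train and test; reported spreads are sample
standard deviations over folds (n-1 denominator). The reported mean F1 is
the mean of per-fold F1 — deliberately not the harmonic mean of mean-P and
mean-R.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

from .config import TemporalModelConfig
from .features import BLOCK_NAMES, SequenceDataset, drop_blocks
from .temporal import build_model, fit, predict

__all__ = [
    "TrocarMetrics",
    "StateMetrics",
    "occupancy_metrics",
    "state_change_events",
    "train_and_eval",
    "kfold",
    "KFoldResult",
    "ablate",
    "AblationResult",
]


@dataclass(frozen=True)
class TrocarMetrics:
    precision: float
    recall: float
    f1: float


@dataclass
class StateMetrics:
    """One fold's metrics: per trocar ID and averaged over trocars."""

    per_trocar: dict[int, TrocarMetrics]

    @property
    def overall(self) -> TrocarMetrics:
        ms = list(self.per_trocar.values())
        return TrocarMetrics(
            precision=float(np.mean([m.precision for m in ms])),
            recall=float(np.mean([m.recall for m in ms])),
            f1=float(np.mean([m.f1 for m in ms])),
        )


def occupancy_metrics(pred: np.ndarray, true: np.ndarray,
                      average: str = "macro") -> StateMetrics:
    """Precision/recall/F1 of predicted occupancy states for one fold.

    ``pred`` and ``true`` are (T, n_trocars) state-code arrays with equal
    frame coverage; cells with ``true < 0`` are unlabeled padding and
    ignored. Per trocar, states are scored one-vs-rest and averaged per
    ``average`` ("macro" or "micro") over the states present in truth or
    predictions.
    """
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs true {true.shape}")
    per_trocar: dict[int, TrocarMetrics] = {}
    for i in range(true.shape[1]):
        mask = true[:, i] >= 0
        if not mask.any():
            continue
        t, p = true[mask, i], pred[mask, i]
        labels = sorted(set(t.tolist()) | set(p.tolist()))
        prec, rec, f1, _ = precision_recall_fscore_support(
            t, p, labels=labels, average=average, zero_division=0
        )
        per_trocar[i + 1] = TrocarMetrics(float(prec), float(rec), float(f1))
    return StateMetrics(per_trocar=per_trocar)


def state_change_events(states: np.ndarray) -> int:
    """Number of frame-to-frame state transitions summed over trocars."""
    states = np.asarray(states)
    if states.shape[0] < 2:
        return 0
    return int(np.sum(states[1:] != states[:-1]))


# ---------------------------------------------------------------------------
# training harness
# ---------------------------------------------------------------------------

def _make_datasets(train_scenes, cfg: TemporalModelConfig, stride: int,
                   seed: int) -> tuple[SequenceDataset, SequenceDataset]:
    """Split train scenes into train/early-stopping-validation at scene level
    (window level when only one scene is available)."""
    rng = np.random.default_rng(seed)
    if len(train_scenes) > 1:
        order = rng.permutation(len(train_scenes))
        val_idx = {int(order[0])}
        tr = [s for i, s in enumerate(train_scenes) if i not in val_idx]
        va = [s for i, s in enumerate(train_scenes) if i in val_idx]
        return (SequenceDataset(tr, cfg.seq_len, stride),
                SequenceDataset(va, cfg.seq_len, stride))
    ds = SequenceDataset(list(train_scenes), cfg.seq_len, stride)
    order = rng.permutation(len(ds))
    cut = max(1, int(0.85 * len(ds)))
    tr = SequenceDataset([], cfg.seq_len, stride)
    va = SequenceDataset([], cfg.seq_len, stride)
    tr._feats, tr._labels = ds._feats, ds._labels
    va._feats, va._labels = ds._feats, ds._labels
    tr.index = [ds.index[i] for i in order[:cut]]
    va.index = [ds.index[i] for i in order[cut:]]
    return tr, va


def train_and_eval(train_scenes, test_scenes, cfg: TemporalModelConfig,
                   seed: int = 0, stride: int = 1, verbose: bool = False):
    """Train one temporal model and score it on held-out scenes.

    Scenes are ``(features (T, n_blocks, D), labels (T, n_trocars))`` pairs.
    One train scene is held out for early stopping. Returns
    ``(StateMetrics, model, history, predictions per test scene)``.
    """
    train_ds, val_ds = _make_datasets(train_scenes, cfg, stride, seed)
    model = build_model(cfg, seed=seed)
    history = fit(model, train_ds, val_ds, seed=seed, verbose=verbose)
    preds, trues = [], []
    for feats, labels in test_scenes:
        states, _ = predict(model, feats)
        preds.append(states)
        trues.append(labels)
    metrics = occupancy_metrics(np.concatenate(preds), np.concatenate(trues))
    return metrics, model, history, preds


@dataclass
class KFoldResult:
    """Mean +- sd of per-trocar and overall metrics over folds."""

    per_fold: list[StateMetrics]
    fold_assignment: list[list[int]] = field(default_factory=list)

    def _gather(self, metric: str) -> dict[str, tuple[float, float]]:
        out: dict[str, tuple[float, float]] = {}
        ids = sorted({tid for f in self.per_fold for tid in f.per_trocar})
        for tid in ids:
            vals = [getattr(f.per_trocar[tid], metric)
                    for f in self.per_fold if tid in f.per_trocar]
            out[f"trocar_{tid}"] = (float(np.mean(vals)),
                                    float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
        vals = [getattr(f.overall, metric) for f in self.per_fold]
        out["mean"] = (float(np.mean(vals)),
                       float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
        return out

    def table(self) -> pd.DataFrame:
        rows = {}
        for metric in ("precision", "recall", "f1"):
            for row, (m, s) in self._gather(metric).items():
                rows.setdefault(row, {})[f"{metric}_mean"] = m
                rows.setdefault(row, {})[f"{metric}_sd"] = s
        return pd.DataFrame.from_dict(rows, orient="index")

    @property
    def mean_f1(self) -> float:
        return self._gather("f1")["mean"][0]


def kfold(scenes, k: int, cfg: TemporalModelConfig, seed: int = 0,
          stride: int = 1) -> KFoldResult:
    """Scene-level k-fold cross-validation.

    Scenes (never frames) are partitioned into k folds of sizes differing by
    at most one; each fold is scored by a model trained on the others. Fold
    assignment is deterministic given ``seed``.
    """
    if k > len(scenes):
        raise ValueError(f"k={k} exceeds the number of scenes ({len(scenes)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(scenes))
    folds = [sorted(int(i) for i in part) for part in np.array_split(order, k)]
    per_fold = []
    for fi, test_idx in enumerate(folds):
        train = [scenes[i] for i in range(len(scenes)) if i not in test_idx]
        test = [scenes[i] for i in test_idx]
        # same training seed for every fold: identical scenes => identical
        # models => zero spread across folds
        metrics, _, _, _ = train_and_eval(train, test, cfg, seed=seed, stride=stride)
        per_fold.append(metrics)
    return KFoldResult(per_fold=per_fold, fold_assignment=folds)


@dataclass
class AblationResult:
    """Change in metrics (ablated - full) mirroring the ablation protocol."""

    full: KFoldResult
    ablated: KFoldResult
    dropped: tuple[str, ...]

    def delta_table(self) -> pd.DataFrame:
        return self.ablated.table() - self.full.table()

    @property
    def delta_mean_f1(self) -> float:
        return self.ablated.mean_f1 - self.full.mean_f1


def ablate(scenes, blocks_to_drop: tuple[str, ...], cfg: TemporalModelConfig,
           k: int = 2, seed: int = 0, stride: int = 1) -> AblationResult:
    """Retrain with feature blocks removed and report the metric change.

    ``blocks_to_drop`` is a subset of the block names (typically ``("xc1",)``
    or ``("xc2",)``); the model's input dimension shrinks by D per dropped
    block. Both runs use the same folds and seeds, so an empty drop set
    yields exactly zero deltas.
    """
    for b in blocks_to_drop:
        if b not in BLOCK_NAMES:
            raise ValueError(f"unknown feature block {b!r}")
    n_blocks = scenes[0][0].shape[1]
    dim = scenes[0][0].shape[2]
    full = kfold(scenes, k, cfg, seed=seed, stride=stride)
    if blocks_to_drop:
        reduced = [(drop_blocks(f, tuple(blocks_to_drop)), l) for f, l in scenes]
        cfg_abl = TemporalModelConfig(
            **{**cfg.__dict__, "input_dim": (n_blocks - len(blocks_to_drop)) * dim}
        )
        ablated = kfold(reduced, k, cfg_abl, seed=seed, stride=stride)
    else:
        ablated = full
    return AblationResult(full=full, ablated=ablated, dropped=tuple(blocks_to_drop))
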