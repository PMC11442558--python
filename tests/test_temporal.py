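import numpy as np
import pytest

from trocartrack.autodiff import Tensor
from trocartrack.config import FocalLossParams, TemporalModelConfig
from trocartrack.features import SequenceDataset
from trocartrack.temporal import (
    _focal_loss_tensor,
    build_model,
    fit,
    focal_loss,
    load_model,
    predict,
    save_model,
)

UNIT = FocalLossParams(gamma=0.0, alpha=(1.0, 1.0, 1.0))


class TestFocalLoss:
    def test_gamma_zero_is_cross_entropy_at_half(self):
        assert focal_loss(np.array([0.5, 0.25, 0.25]), 0, UNIT) == pytest.approx(
            np.log(2.0), abs=1e-12
        )

    def test_certain_prediction_costs_nothing(self):
        for gamma in (0.0, 2.0):
            fp = FocalLossParams(gamma=gamma, alpha=(1.0, 1.0, 1.0))
            assert focal_loss(np.array([0.0, 1.0, 0.0]), 1, fp) == 0.0

    def test_hand_computed_value_gamma_two(self):
        fp = FocalLossParams(gamma=2.0, alpha=(1.0, 1.0, 1.0))
        val = focal_loss(np.array([0.9, 0.05, 0.05]), 0, fp)
        assert val == pytest.approx(0.01 * -np.log(0.9), rel=1e-9)
        assert val == pytest.approx(1.05361e-3, rel=1e-4)

    def test_zero_probability_clamped_finite(self):
        val = focal_loss(np.array([0.0, 1.0, 0.0]), 0, UNIT)
        assert np.isfinite(val) and val == pytest.approx(-np.log(1e-8))

    def test_batch_agrees_with_scalar_and_reduces_to_cross_entropy(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(3), size=200)
        ys = rng.integers(0, 3, size=200)
        batch = focal_loss(probs, ys, UNIT)
        ce = -np.log(probs[np.arange(200), ys])
        assert np.allclose(batch, ce, atol=1e-12)
        assert batch[7] == pytest.approx(focal_loss(probs[7], ys[7], UNIT))

    def test_strictly_decreasing_in_true_class_probability(self):
        fp = FocalLossParams(gamma=2.0)
        ps = np.linspace(0.05, 0.99, 30)
        vals = [focal_loss(np.array([p, 1 - p, 0.0]), 0, fp) for p in ps]
        assert np.all(np.diff(vals) < 0)

    def test_padding_cells_excluded_from_tensor_loss(self):
        probs = Tensor(np.full((2, 3), 1 / 3), requires_grad=True)
        y = np.array([1, -1])
        loss = _focal_loss_tensor(probs, y, UNIT)
        assert float(loss.data) == pytest.approx(-np.log(1 / 3))


@pytest.mark.parametrize("kind", ["lstm", "gru", "mstcn"])
class TestForward:
    def _model(self, kind, **kw):
        cfg = TemporalModelConfig(kind=kind, input_dim=12, hidden=16, seq_len=8,
                                  n_stages=2, layers_per_stage=2, **kw)
        return build_model(cfg, seed=0)

    def test_probabilities_normalized(self, kind):
        model = self._model(kind)
        x = np.random.default_rng(0).normal(size=(3, 8, 12))
        probs = model.forward(x).data
        assert probs.shape == (3, 8, 4, 3)
        assert np.allclose(probs.sum(-1), 1.0, atol=1e-6)

    def test_eval_deterministic(self, kind):
        model = self._model(kind)
        x = np.random.default_rng(1).normal(size=(2, 8, 12))
        assert np.array_equal(model.forward(x).data, model.forward(x).data)

    def test_zeroed_head_gives_uniform_probabilities(self, kind):
        model = self._model(kind)
        if kind == "mstcn":
            for stage in model.stages:
                stage["w_out"].data[:] = 0.0
                stage["b_out"].data[:] = 0.0
        else:
            model.w_head.data[:] = 0.0
            model.b_head.data[:] = 0.0
        x = np.random.default_rng(2).normal(size=(2, 8, 12))
        assert np.allclose(model.forward(x).data, 1 / 3, atol=1e-12)

    def test_dimension_mismatch_raises(self, kind):
        model = self._model(kind)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 8, 13)))


def test_mstcn_receptive_field_is_31_frames():
    """Kernel 3 with dilations 1, 2, 4, 8 reaches 1 + 2 (2^4 - 1) = 31
    frames, verified by probing which outputs react to one perturbed input."""
    cfg = TemporalModelConfig(kind="mstcn", input_dim=4, hidden=8, seq_len=64,
                              n_stages=1, layers_per_stage=4)
    model = build_model(cfg, seed=0)
    rng = np.random.default_rng(0)
    x = rng.normal(size=(1, 64, 4))
    base = model.forward(x).data
    x2 = x.copy()
    x2[0, 32] += 1.0
    changed = np.where(np.abs(model.forward(x2).data - base).max(axis=(0, 2, 3)) > 0)[0]
    assert changed.min() == 32 - 15 and changed.max() == 32 + 15
    assert len(changed) == 31


def _oracle_scene(T, seed, n_trocars=4, dim=3, noise=0.0):
    """Features whose trocar blocks are (noisy) one-hot encodings of the true
    state — linearly separable by construction."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 3, size=(T, n_trocars)).astype(np.int8)
    feats = np.zeros((T, 6, dim), dtype=np.float32)
    for i in range(n_trocars):
        feats[np.arange(T), i, labels[:, i] % dim] = 1.0
    if noise:
        feats += rng.normal(0, noise, feats.shape).astype(np.float32)
    return feats, labels


def test_training_loss_decreases_on_separable_features():
    feats, labels = _oracle_scene(240, seed=5)
    cfg = TemporalModelConfig(kind="lstm", input_dim=18, hidden=16, seq_len=8,
                              max_epochs=6, patience=6)
    ds = SequenceDataset([(feats, labels)], cfg.seq_len)
    model = build_model(cfg, seed=0)
    history = fit(model, ds, None, seed=0)
    losses = [h["train_loss"] for h in history[:5]]
    assert np.all(np.diff(losses) < 0)


def test_training_is_deterministic_given_seed():
    feats, labels = _oracle_scene(120, seed=6)
    cfg = TemporalModelConfig(kind="gru", input_dim=18, hidden=8, seq_len=6,
                              max_epochs=3, patience=3)
    weights = []
    for _ in range(2):
        ds = SequenceDataset([(feats, labels)], cfg.seq_len)
        model = build_model(cfg, seed=1)
        fit(model, ds, ds, seed=1)
        weights.append(np.concatenate([p.data.ravel() for p in model.params]))
    assert np.array_equal(weights[0], weights[1])


def test_gamma_zero_uniform_alpha_matches_cross_entropy_gradient():
    feats, labels = _oracle_scene(60, seed=7)
    cfg = TemporalModelConfig(kind="lstm", input_dim=18, hidden=8, seq_len=6)
    X = SequenceDataset([(feats, labels)], 6).gather(range(4))
    model = build_model(cfg, seed=0)
    probs = model.forward_stages(Tensor(X[0].astype(np.float64)))[0]
    focal = _focal_loss_tensor(probs, X[1], UNIT)
    focal.backward()
    g_focal = [p.grad.copy() for p in model.params]
    for p in model.params:
        p.zero_grad()
    probs = model.forward_stages(Tensor(X[0].astype(np.float64)))[0]
    onehot = np.eye(3)[X[1]]
    ce = -((probs * Tensor(onehot)).sum(axis=-1).clip_min(1e-8).log()).mean(axis=0).mean(axis=0).mean(axis=0)
    ce.backward()
    for ga, gb in zip(g_focal, (p.grad for p in model.params)):
        assert np.allclose(ga, gb, atol=1e-10)


def test_oracle_features_are_recovered_after_training():
    train = [_oracle_scene(300, seed=s, noise=0.05) for s in (1, 2)]
    test = _oracle_scene(150, seed=9, noise=0.05)
    cfg = TemporalModelConfig(kind="mstcn", input_dim=18, hidden=16, seq_len=8,
                              n_stages=2, layers_per_stage=2, max_epochs=40,
                              patience=10, lr=3e-3)
    tr = SequenceDataset(train[:1], 8)
    va = SequenceDataset(train[1:], 8)
    model = build_model(cfg, seed=0)
    fit(model, tr, va, seed=0)
    states, probs = predict(model, test[0])
    assert (states == test[1]).mean() > 0.97
    assert np.allclose(probs.sum(-1), 1.0, atol=1e-6)


class TestPredict:
    def test_constant_features_give_constant_interior_predictions(self):
        # every frame covered by all window phases sees the same averaged
        # probabilities; only scene-edge frames have partial window coverage
        cfg = TemporalModelConfig(kind="gru", input_dim=6, hidden=8, seq_len=4)
        model = build_model(cfg, seed=0)
        T, L = 20, 4
        feats = np.ones((T, 6), dtype=np.float32)
        states, probs = predict(model, feats)
        interior = slice(L - 1, T - L + 1)
        assert np.all(states[interior] == states[L - 1])
        assert np.allclose(probs[interior], probs[L - 1])

    def test_single_window_equals_forward_argmax(self):
        cfg = TemporalModelConfig(kind="lstm", input_dim=6, hidden=8, seq_len=5)
        model = build_model(cfg, seed=0)
        feats = np.random.default_rng(0).normal(size=(5, 6)).astype(np.float32)
        states, _ = predict(model, feats)
        direct = model.forward(feats[None].astype(np.float64)).data[0].argmax(-1)
        assert np.array_equal(states, direct)

    def test_short_stream_padded_not_dropped(self):
        cfg = TemporalModelConfig(kind="lstm", input_dim=6, hidden=8, seq_len=8)
        model = build_model(cfg, seed=0)
        states, _ = predict(model, np.zeros((3, 6), dtype=np.float32))
        assert states.shape == (3, 4)


def test_save_load_roundtrip(tmp_path):
    cfg = TemporalModelConfig(kind="mstcn", input_dim=6, hidden=8, seq_len=4,
                              n_stages=2, layers_per_stage=2)
    model = build_model(cfg, seed=3)
    path = tmp_path / "model.npz"
    save_model(model, path)
    clone = load_model(path)
    x = np.random.default_rng(0).normal(size=(2, 4, 6))
    assert np.array_equal(model.forward(x).data, clone.forward(x).data)
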