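import numpy as np
import pytest

from trocartrack.features import (
    BLOCK_NAMES,
    ReferenceEncoder,
    SequenceDataset,
    crop_adaptive_pad,
    drop_blocks,
    extract_features,
    fuse,
    make_sequences,
)
from trocartrack.tracking import FrameSlots


@pytest.fixture()
def gradient_frame():
    # distinct value at every pixel so geometry errors are visible
    yy, xx = np.mgrid[0:120, 0:160]
    return (yy * 1000 + xx).astype(np.float64)


class TestCropAdaptivePad:
    def test_square_box_is_plain_crop(self, gradient_frame):
        patch = crop_adaptive_pad(gradient_frame, (50, 60, 90, 100), target=40)
        assert np.array_equal(patch, gradient_frame[60:100, 50:90])

    def test_wide_box_padded_symmetrically_with_context(self, gradient_frame):
        # 40x20 box -> square 40x40 with 10 rows of frame context above/below
        patch = crop_adaptive_pad(gradient_frame, (50, 60, 90, 80), target=40)
        assert np.array_equal(patch, gradient_frame[50:90, 50:90])
        assert np.array_equal(patch[10:30], gradient_frame[60:80, 50:90])

    def test_left_edge_box_zero_pads_only_left(self, gradient_frame):
        # 20x40 box at the left border: x expansion runs off the frame
        patch = crop_adaptive_pad(gradient_frame, (0, 60, 20, 100), target=40)
        assert np.all(patch[:, :10] == 0.0)
        assert np.array_equal(patch[:, 10:], gradient_frame[60:100, 0:30])

    def test_resampled_when_target_differs(self, gradient_frame):
        patch = crop_adaptive_pad(gradient_frame, (50, 60, 90, 100), target=32)
        assert patch.shape == (32, 32)

    def test_box_outside_frame_raises(self, gradient_frame):
        with pytest.raises(ValueError):
            crop_adaptive_pad(gradient_frame, (200, 10, 220, 30), target=32)


class TestReferenceEncoder:
    def test_deterministic_and_fixed_dimension(self):
        enc = ReferenceEncoder(dim=64)
        patch = np.random.default_rng(0).uniform(0, 255, (32, 32))
        v1, v2 = enc(patch), enc(patch)
        assert v1.shape == (64,)
        assert np.array_equal(v1, v2)

    def test_two_encoders_same_seed_agree(self):
        patch = np.random.default_rng(1).uniform(0, 255, (32, 32))
        assert np.array_equal(ReferenceEncoder()(patch), ReferenceEncoder()(patch))

    def test_illumination_invariance(self):
        enc = ReferenceEncoder(dim=32)
        patch = np.random.default_rng(2).uniform(10, 200, (32, 32))
        assert np.allclose(enc(patch), enc(patch * 1.3), atol=1e-9)

    def test_rejects_wrong_patch_size(self):
        with pytest.raises(ValueError):
            ReferenceEncoder().encode_batch(np.zeros((1, 16, 16)))


def _slots(visible_ids, box=(10.0, 10.0, 40.0, 40.0)):
    return FrameSlots(
        frame=0,
        slots={i: ((25.0, 25.0), 900.0, box, i in visible_ids) for i in (1, 2, 3, 4)},
    )


class TestFuse:
    def test_invisible_slots_are_zero_vectors(self, encoder):
        f1 = np.random.default_rng(0).uniform(0, 255, (90, 160))
        f2 = np.random.default_rng(1).uniform(0, 255, (45, 80))
        feat = fuse(f1, f2, _slots(set()).slots, encoder)
        assert np.all(feat.blocks[:4] == 0.0)
        assert np.any(feat.blocks[4] != 0.0) and np.any(feat.blocks[5] != 0.0)
        assert feat.concat.shape == (6 * encoder.dim,)

    def test_deterministic_on_identical_inputs(self, encoder):
        f1 = np.random.default_rng(0).uniform(0, 255, (90, 160))
        f2 = np.random.default_rng(1).uniform(0, 255, (45, 80))
        a = fuse(f1, f2, _slots({1, 3}).slots, encoder)
        b = fuse(f1, f2, _slots({1, 3}).slots, encoder)
        assert np.array_equal(a.blocks, b.blocks)

    def test_concat_equals_blockwise_slices(self, encoder):
        f1 = np.random.default_rng(0).uniform(0, 255, (90, 160))
        f2 = np.random.default_rng(1).uniform(0, 255, (45, 80))
        feat = fuse(f1, f2, _slots({2}).slots, encoder)
        D = encoder.dim
        for b, name in enumerate(BLOCK_NAMES):
            assert np.array_equal(feat.concat[b * D : (b + 1) * D], feat.block(name))


class TestDropBlocks:
    def test_dropping_xc2_keeps_first_five_blocks(self):
        feats = np.random.default_rng(0).normal(size=(7, 6, 8)).astype(np.float32)
        reduced = drop_blocks(feats, ("xc2",))
        assert reduced.shape == (7, 5, 8)
        assert np.array_equal(reduced, feats[:, :5])

    def test_cannot_drop_everything(self):
        feats = np.zeros((3, 6, 4), dtype=np.float32)
        with pytest.raises(ValueError):
            drop_blocks(feats, BLOCK_NAMES)

    def test_unknown_block_rejected(self):
        with pytest.raises(ValueError):
            drop_blocks(np.zeros((3, 6, 4)), ("xc9",))


class TestMakeSequences:
    @pytest.mark.parametrize("T,L,expected", [(12, 12, 1), (100, 12, 89), (11, 12, 0)])
    def test_window_counts(self, T, L, expected):
        feats = np.zeros((T, 6, 4), dtype=np.float32)
        labels = np.zeros((T, 4), dtype=np.int8)
        if expected == 0:
            with pytest.warns(UserWarning):
                X, Y = make_sequences(feats, labels, L)
        else:
            X, Y = make_sequences(feats, labels, L)
        assert X.shape == (expected, L, 24)
        assert Y.shape == (expected, L, 4)

    def test_windows_are_consecutive_slices(self):
        T = 20
        feats = np.arange(T, dtype=np.float32).reshape(T, 1, 1)
        labels = np.arange(T).reshape(T, 1) % 3
        X, Y = make_sequences(feats, labels, 5, stride=2)
        assert X.shape[0] == 8
        assert np.array_equal(X[3, :, 0], np.arange(6, 11, dtype=np.float32))

    def test_dataset_windows_never_cross_scene_boundaries(self):
        scenes = [
            (np.zeros((10, 2, 2), dtype=np.float32), np.zeros((10, 4), dtype=np.int8)),
            (np.ones((7, 2, 2), dtype=np.float32), np.ones((7, 4), dtype=np.int8)),
        ]
        ds = SequenceDataset(scenes, seq_len=5)
        assert len(ds) == (10 - 5 + 1) + (7 - 5 + 1)
        X, Y = ds.gather(range(len(ds)))
        # every window is pure: all-zeros (scene 1) or all-ones (scene 2)
        sums = X.reshape(len(ds), -1).sum(axis=1)
        assert set(np.unique(sums)) <= {0.0, 5 * 4.0}


def test_extract_features_marks_invisible_slots_zero(encoder):
    frames_c1 = [np.random.default_rng(t).uniform(0, 255, (90, 160)) for t in range(3)]
    frames_c2 = [np.random.default_rng(10 + t).uniform(0, 255, (45, 80)) for t in range(3)]
    slots = [_slots({1} if t != 1 else set()) for t in range(3)]
    feats = extract_features(frames_c1, frames_c2, slots, encoder)
    assert feats.shape == (3, 6, encoder.dim)
    assert np.any(feats[0, 0] != 0) and np.all(feats[1, 0] == 0)
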