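import pytest

from trocartrack.config import DetectorParams, SceneConfig, TrackerParams
from trocartrack.features import ReferenceEncoder
from trocartrack.pipeline import labels_from_truth, process_scene
from trocartrack.synthetic_scene import simulate_timeline


@pytest.fixture(scope="session")
def encoder():
    return ReferenceEncoder(dim=64)


@pytest.fixture(scope="session")
def small_scene():
    """A 20 s default 4-trocar scene with its ground truth."""
    cfg = SceneConfig(duration_s=20.0, seed=7)
    return cfg, simulate_timeline(cfg)


def run_scene(cfg, encoder, tracker=None, detector=None):
    """Render + detect + track + featurize one simulated scene."""
    truth = simulate_timeline(cfg)
    tracker = tracker or TrackerParams(id_mode="position")
    detector = detector or DetectorParams()
    frames_c1, frames_c2, dets, slots, feats = process_scene(
        truth, cfg, detector, tracker, encoder
    )
    return truth, frames_c1, frames_c2, dets, slots, feats


@pytest.fixture(scope="session")
def pipeline_scenes(encoder):
    """Four processed default scenes (features + labels) shared by the
    model-level tests."""
    scenes = []
    for s in range(4):
        cfg = SceneConfig(duration_s=40.0, seed=500 + s)
        truth, *_, feats = run_scene(cfg, encoder)
        scenes.append((feats, labels_from_truth(truth)))
    return scenes
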