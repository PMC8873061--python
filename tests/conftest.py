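import numpy as np
import pytest

from sacroseg.core import (
    ClipLabelSequence,
    PhaseAnnotation,
    PhaseEvent,
    frames_to_clips,
    intervals_to_frame_labels,
)
from sacroseg.synthetic import (
    EmitterConfig,
    WorkflowSimConfig,
    emit_features,
    emit_fine_predictions,
    simulate_workflow,
)
from sacroseg.training import VideoSample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_annotation():
    """Two phases with a gap: P1 [0,10), gap, P2 [12,20); 20 s video."""
    return PhaseAnnotation(
        events=[
            PhaseEvent(1, "start", 0.0),
            PhaseEvent(1, "end", 10.0),
            PhaseEvent(2, "start", 12.0),
            PhaseEvent(2, "end", 20.0),
        ],
        video_duration_s=20.0,
    )


@pytest.fixture(scope="session")
def emitter32():
    """Test-scale emitter (32-dim features, default noise and accuracy)."""
    return EmitterConfig(feature_dim=32, seed=42)


def make_cohort(n_videos: int, emitter: EmitterConfig, sim_seed: int = 100,
                fps: float = 2.4) -> list:
    """Simulated procedures with shared class means and per-video noise."""
    videos = []
    for i in range(n_videos):
        ann = simulate_workflow(WorkflowSimConfig(seed=sim_seed + i))
        clips = frames_to_clips(intervals_to_frame_labels(ann, fps))
        videos.append(VideoSample(
            features=emit_features(clips, emitter, stream=i),
            gt=clips,
            fine_preds=emit_fine_predictions(clips, emitter, stream=i),
        ))
    return videos


def random_label_pair(rng: np.random.Generator, max_len: int = 50,
                      n_classes: int = 4):
    """A random (gt, pred) clip-label pair for metric stress tests."""
    length = int(rng.integers(1, max_len + 1))
    classes = np.arange(1, n_classes + 1)
    gt = rng.choice(classes, size=length)
    pred = rng.choice(classes, size=length)
    return gt, pred
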