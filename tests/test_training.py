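"""Loss, target strategies, window sampling, and the training loop."""

import numpy as np
import pytest

from sacroseg.core import ClipLabelSequence, ValidationError
from sacroseg.models import SeqModelConfig, build_model
from sacroseg.synthetic import FeatureSequence
from sacroseg.training import (
    LossWeights,
    TrainConfig,
    VideoSample,
    build_target,
    inject_noise,
    sample_window_starts,
    train_seq2seq,
    weighted_cross_entropy,
)


class TestWeightedCrossEntropy:
    def test_uniform_binary_gives_ln2(self):
        probs = np.array([[[0.5, 0.5]]])
        onehot = np.array([[[1.0, 0.0]]])
        loss = weighted_cross_entropy(probs, onehot, LossWeights(w=np.ones(2)))
        assert loss == pytest.approx(np.log(2.0))

    def test_perfect_prediction_zero_loss(self):
        probs = np.eye(3)[None, :, :]
        onehot = np.eye(3)[None, :, :]
        loss = weighted_cross_entropy(probs, onehot, LossWeights(w=np.ones(3)))
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_sequence_form_reduces_to_batch_form_at_t1(self, rng):
        """The time-extended loss at t=1 equals the per-clip loss exactly."""
        d, n = 4, 6
        probs = rng.dirichlet(np.ones(n), size=d)
        onehot = np.eye(n)[rng.integers(n, size=d)]
        w = LossWeights.default(n)
        # manual per-clip form: -(1/d) sum_j sum_i w_i y_ij log x_ij
        manual = -(w.w * onehot * np.log(probs)).sum() / d
        batch = weighted_cross_entropy(probs[None], onehot[None], w)
        assert batch == pytest.approx(manual)
        # two identical time slices average to the single-slice loss
        double = weighted_cross_entropy(np.stack([probs, probs]),
                                        np.stack([onehot, onehot]), w)
        assert double == pytest.approx(batch)

    def test_transition_weight_ten_times_smaller(self):
        w = LossWeights.default(6)
        assert w.w[5] == pytest.approx(w.w[0] / 10.0)

    def test_nonnegative_on_random_inputs(self, rng):
        probs = rng.dirichlet(np.ones(6), size=(3, 4))
        onehot = np.eye(6)[rng.integers(6, size=(3, 4))]
        assert weighted_cross_entropy(probs, onehot, LossWeights.default(6)) >= 0


class TestInjectNoise:
    @pytest.mark.parametrize("rate,length,expected", [
        (0.4, 100, 40), (0.0, 50, 0), (1.0, 30, 30), (0.4, 90, 36),
    ])
    def test_exact_replacement_count(self, rate, length, expected):
        seq = ClipLabelSequence(labels=np.full(length, 3))
        out = inject_noise(seq, rate, seed=0)
        assert int((out.labels != seq.labels).sum()) == expected

    def test_replacements_never_equal_original(self):
        seq = ClipLabelSequence(labels=np.full(200, 2))
        out = inject_noise(seq, 1.0, seed=1)
        assert not np.any(out.labels == 2)
        assert set(np.unique(out.labels)) <= set(range(1, 7))

    def test_deterministic_given_seed(self):
        seq = ClipLabelSequence(labels=np.arange(1, 6).repeat(20))
        a = inject_noise(seq, 0.4, seed=9)
        b = inject_noise(seq, 0.4, seed=9)
        assert np.array_equal(a.labels, b.labels)


class TestBuildTarget:
    def test_strategies(self, rng):
        gt = ClipLabelSequence(labels=rng.integers(1, 6, size=90))
        fine = ClipLabelSequence(labels=rng.integers(1, 6, size=90))
        cfg = TrainConfig(noise_rate=0.4)
        assert build_target("baseline", gt, fine, cfg) is gt
        assert build_target("pred", gt, fine, cfg) is fine
        noised = build_target("noised", gt, fine, cfg, rng)
        assert int((noised.labels != gt.labels).sum()) == 36  # round(0.4*90)
        with pytest.raises(ValidationError):
            build_target("teacher", gt, fine, cfg)


class TestSampleWindowStarts:
    def test_even_spacing_long_video(self):
        starts = sample_window_starts(1089, 200, 100)
        assert len(starts) == 200
        assert starts[0] == 0
        assert starts[-1] == 989
        assert all(b >= a for a, b in zip(starts, starts[1:]))

    def test_single_window(self):
        assert sample_window_starts(500, 1, 100) == [0]

    def test_degenerate_exact_fit(self):
        assert sample_window_starts(100, 5, 100) == [0] * 5

    def test_video_shorter_than_window_rejected(self):
        with pytest.raises(ValidationError):
            sample_window_starts(50, 10, 100)


def _toy_videos(rng, n_videos=2, n_clips=40, feature_dim=4):
    """Trivially learnable videos: features are one-hot-ish in the label."""
    videos = []
    for _ in range(n_videos):
        labels = np.repeat(rng.integers(1, 6, size=n_clips // 10), 10)
        feats = np.eye(6)[labels - 1] + 0.05 * rng.normal(size=(n_clips, 6))
        videos.append(VideoSample(
            features=FeatureSequence(matrix=feats),
            gt=ClipLabelSequence(labels=labels),
            fine_preds=ClipLabelSequence(labels=labels),
        ))
    return videos


class TestTrainLoop:
    def _config(self, arch="lstm_seq2seq"):
        return SeqModelConfig(arch=arch, window_len=20, out_len=20, shift=0,
                              n_classes=6, feature_dim=6, d_model=8,
                              lstm_layers=1, tf_layers=1, tf_heads=2,
                              ffn_dim=8, seed=5)

    def test_overfits_single_video(self, rng):
        """Loss drops below 0.1 when overfitting one easy synthetic video."""
        videos = _toy_videos(rng, n_videos=1)
        model = build_model(self._config())
        cfg = TrainConfig(strategy="baseline", windows_per_video=10, epochs=50,
                          lr=1e-2, lr_decay=1.0, seed=0)
        model, history = train_seq2seq(videos, model, cfg)
        assert history.steps[-1]["loss"] < 0.1

    def test_same_seed_identical_history(self, rng):
        videos = _toy_videos(rng)
        cfg = TrainConfig(strategy="noised", windows_per_video=5, epochs=2,
                          lr=1e-3, seed=4)
        losses = []
        for _ in range(2):
            model = build_model(self._config())
            _, history = train_seq2seq(videos, model, cfg)
            losses.append([s["loss"] for s in history.steps])
        assert losses[0] == losses[1]

    def test_history_length_equals_steps(self, rng):
        videos = _toy_videos(rng)
        cfg = TrainConfig(strategy="baseline", windows_per_video=5, epochs=3,
                          lr=1e-3, seed=4)
        model = build_model(self._config())
        _, history = train_seq2seq(videos, model, cfg)
        assert len(history.steps) == 5 * 3

    def test_best_checkpoint_dominates_validations(self, rng):
        videos = _toy_videos(rng, n_videos=3)
        cfg = TrainConfig(strategy="noised", windows_per_video=8, epochs=3,
                          lr=3e-3, seed=4, validations_per_epoch=4,
                          val_windows_per_video=3)
        model = build_model(self._config())
        _, history = train_seq2seq(videos[:2], model, cfg, val_videos=videos[2:])
        accs = [v["accuracy"] for v in history.validations]
        assert history.best_accuracy == pytest.approx(max(accs))

    def test_non_finite_loss_aborts(self, rng):
        videos = _toy_videos(rng, n_videos=1)
        videos[0].features.matrix[:] = np.nan  # corrupt inputs downstream
        model = build_model(self._config())
        cfg = TrainConfig(strategy="baseline", windows_per_video=2, epochs=1,
                          lr=1e-3, seed=0)
        with pytest.raises((RuntimeError, FloatingPointError, ValidationError)):
            train_seq2seq(videos, model, cfg)
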