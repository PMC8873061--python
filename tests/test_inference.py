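"""Sliding-window assembly, recursive prediction, and the mode filter."""

import numpy as np
import pytest

from sacroseg.core import ClipLabelSequence, ValidationError
from sacroseg.inference import (
    mode_average_filter,
    segment_time_shifted,
    segment_time_synchronous,
)
from sacroseg.models import SeqModelConfig
from sacroseg.synthetic import FeatureSequence


class _StubLogits:
    def __init__(self, data):
        self.data = data


class CopyTargetModel:
    """Outputs one-hot logits that reproduce the target sequence."""

    def __init__(self, config):
        self.config = config

    def forward(self, features, target_codes):
        codes = np.asarray(target_codes)
        out = np.full(codes.shape + (self.config.n_classes,), -5.0)
        for b in range(codes.shape[0]):
            out[b, np.arange(codes.shape[1]), codes[b] - 1] = 5.0
        return _StubLogits(out)


class OracleModel:
    """Predicts the groundtruth for the supervised (shifted) span."""

    def __init__(self, config, gt_labels):
        self.config = config
        self.gt = np.asarray(gt_labels)

    def forward(self, features, target_codes):
        # locate the window by matching its features against the stored video
        feats = np.asarray(features)[0]
        start = int(round(feats[0, 0]))
        cfg = self.config
        span = self.gt[start + cfg.shift:start + cfg.window_len]
        out = np.full((1, cfg.out_len, cfg.n_classes), -5.0)
        out[0, np.arange(cfg.out_len), span - 1] = 5.0
        return _StubLogits(out)


def _video(n_clips, rng):
    """Features whose first column encodes the clip index (for OracleModel)."""
    labels = rng.integers(1, 6, size=n_clips)
    feats = np.zeros((n_clips, 2))
    feats[:, 0] = np.arange(n_clips)
    return FeatureSequence(matrix=feats), ClipLabelSequence(labels=labels)


class TestTimeSynchronous:
    def _cfg(self):
        return SeqModelConfig(arch="lstm_seq2seq", window_len=100, out_len=100,
                              shift=0, feature_dim=2, d_model=8, lstm_layers=1)

    def test_exact_tiling(self, rng):
        feats, fine = _video(200, rng)
        result = segment_time_synchronous(CopyTargetModel(self._cfg()), feats, fine)
        assert len(result.labels) == 200
        assert np.array_equal(result.labels.labels, fine.labels)

    def test_right_aligned_final_window(self, rng):
        """250 clips: windows at 0, 100, and 150; earlier windows win overlaps."""
        feats, fine = _video(250, rng)
        result = segment_time_synchronous(CopyTargetModel(self._cfg()), feats, fine)
        assert len(result.labels) == 250
        assert np.array_equal(result.labels.labels, fine.labels)  # copy model
        assert set(result.provenance) == {"model"}

    def test_video_shorter_than_window_rejected(self, rng):
        feats, fine = _video(60, rng)
        with pytest.raises(ValidationError, match="passthrough"):
            segment_time_synchronous(CopyTargetModel(self._cfg()), feats, fine)


class TestTimeShifted:
    def _cfg(self):
        return SeqModelConfig(arch="lstm_seq2seq", window_len=100, out_len=90,
                              shift=10, feature_dim=2, d_model=8, lstm_layers=1)

    def test_window_and_vote_bookkeeping(self, rng):
        """190 clips, stride 10: ten windows; vote counts follow the overlap."""
        feats, fine = _video(190, rng)
        result = segment_time_shifted(CopyTargetModel(self._cfg()), feats, fine)
        assert len(result.labels) == 190
        votes = result.votes_per_clip
        assert np.all(votes[:10] == 0)           # init prefix, no predictions
        assert votes.max() == 9                  # deep interior of the video
        assert votes[10] == 1 and votes[189] == 1
        assert all(result.provenance[:10] == "fine_init")
        assert all(result.provenance[10:] == "model")

    def test_copy_model_propagates_fine_preds(self, rng):
        feats, fine = _video(190, rng)
        result = segment_time_shifted(CopyTargetModel(self._cfg()), feats, fine)
        # a model that copies its target forward reproduces the initial labels
        assert np.array_equal(result.labels.labels[:10], fine.labels[:10])

    def test_perfect_oracle_recovers_groundtruth(self, rng):
        feats, gt = _video(230, rng)
        fine = ClipLabelSequence(labels=rng.integers(1, 6, size=230))  # noisy init
        model = OracleModel(self._cfg(), gt.labels)
        result = segment_time_shifted(model, feats, fine)
        assert np.array_equal(result.labels.labels[10:], gt.labels[10:])

    def test_deterministic(self, rng):
        feats, fine = _video(150, rng)
        a = segment_time_shifted(CopyTargetModel(self._cfg()), feats, fine)
        b = segment_time_shifted(CopyTargetModel(self._cfg()), feats, fine)
        assert np.array_equal(a.labels.labels, b.labels.labels)

    def test_coverage_is_exact(self, rng):
        for n in (100, 137, 190, 251):
            feats, fine = _video(n, rng)
            result = segment_time_shifted(CopyTargetModel(self._cfg()), feats, fine)
            assert len(result.labels) == n
            assert np.all(result.votes_per_clip[10:] >= 1)

    def test_stride_above_shift_warns(self, rng):
        feats, fine = _video(150, rng)
        with pytest.warns(UserWarning, match="stride"):
            segment_time_shifted(CopyTargetModel(self._cfg()), feats, fine,
                                 stride=20)


class TestModeAverageFilter:
    def test_constant_sequence_unchanged(self):
        seq = ClipLabelSequence(labels=np.full(20, 4))
        for width in (1, 3, 11):
            out = mode_average_filter(seq, width)
            assert np.array_equal(out.labels, seq.labels)

    def test_isolated_error_removed(self):
        seq = ClipLabelSequence(labels=np.array([1, 1, 2, 1, 1]))
        out = mode_average_filter(seq, 3)
        assert out.labels.tolist() == [1, 1, 1, 1, 1]

    def test_width_one_is_identity(self, rng):
        seq = ClipLabelSequence(labels=rng.integers(1, 7, size=50))
        out = mode_average_filter(seq, 1)
        assert np.array_equal(out.labels, seq.labels)

    def test_even_width_rejected(self):
        seq = ClipLabelSequence(labels=np.array([1, 2, 3]))
        with pytest.raises(ValidationError):
            mode_average_filter(seq, 4)

    def test_brute_force_window_modes(self, rng):
        seq = ClipLabelSequence(labels=rng.integers(1, 4, size=40))
        width = 5
        out = mode_average_filter(seq, width)
        for t in range(40):
            lo, hi = max(0, t - 2), min(40, t + 3)
            window = seq.labels[lo:hi].tolist()
            counts = {c: window.count(c) for c in set(window)}
            best = min(c for c in counts if counts[c] == max(counts.values()))
            assert out.labels[t] == best
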