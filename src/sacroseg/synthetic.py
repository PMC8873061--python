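"""Synthetic sacrocolpopexy workflows, clip features, and noisy predictions.

The simulator emulates the empirical structure of laparoscopic sacrocolpopexy:
five phases in a nearly fixed order (phase 5 may optionally precede phase 4),
with phase durations drawn from per-phase normal distributions reflecting the
reported statistics — 633±365, 3097±1212, 3888±879, 211±157 and 1073±548
seconds — separated by short transition gaps, optionally interrupted by a
single pause, and flanked by short non-phase lead-in/out.

The emitter stands in for a fine-level video classifier: it produces one
feature vector per clip (a class mean plus isotropic Gaussian noise, with
consecutive phases pulled closer together to mimic their visual
confusability) and a corrupted copy of the groundtruth labels whose errors
arrive in temporally correlated bursts, matching the behaviour of a real
short-context classifier.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .core import (
    ClipLabelSequence,
    PhaseAnnotation,
    PhaseEvent,
    PhaseLabel,
    ValidationError,
)

__all__ = [
    "WorkflowSimConfig",
    "EmitterConfig",
    "FeatureSequence",
    "simulate_workflow",
    "emit_features",
    "emit_fine_predictions",
    "class_means",
]

#: Reported per-phase duration statistics (seconds): mean, sd.
DEFAULT_PHASE_MEAN_S: Tuple[float, ...] = (633.0, 3097.0, 3888.0, 211.0, 1073.0)
DEFAULT_PHASE_SD_S: Tuple[float, ...] = (365.0, 1212.0, 879.0, 157.0, 548.0)

#: Minimum admissible phase duration (seconds); the normal draw is clamped at
#: max(DURATION_FLOOR_S, mean - 2*sd).
DURATION_FLOOR_S = 30.0


@dataclass
class WorkflowSimConfig:
    phase_mean_s: Tuple[float, ...] = DEFAULT_PHASE_MEAN_S
    phase_sd_s: Tuple[float, ...] = DEFAULT_PHASE_SD_S
    transition_range_s: Tuple[float, float] = (10.0, 120.0)
    p_phase5_before_4: float = 0.0
    p_pause: float = 0.15
    pause_range_s: Tuple[float, float] = (30.0, 120.0)
    lead_range_s: Tuple[float, float] = (30.0, 120.0)
    fps: float = 2.4
    seed: int = 0

    def validate(self) -> None:
        if len(self.phase_mean_s) != 5 or len(self.phase_sd_s) != 5:
            raise ValidationError("exactly five phase mean/sd entries required")
        if any(m <= 0 for m in self.phase_mean_s):
            raise ValidationError("phase means must be positive")
        if any(s < 0 for s in self.phase_sd_s):
            raise ValidationError("phase sds must be nonnegative")
        for p in (self.p_phase5_before_4, self.p_pause):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        for lo, hi in (self.transition_range_s, self.pause_range_s, self.lead_range_s):
            if lo < 0 or hi < lo:
                raise ValidationError("ranges must satisfy 0 <= lo <= hi")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")


@dataclass
class EmitterConfig:
    feature_dim: int = 1200
    class_separation: float = 3.0
    adjacency_shrink: float = 0.25
    noise_sd: float = 1.0
    fine_accuracy: float = 0.69
    error_burst_len: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.feature_dim < 2:
            raise ValidationError("feature_dim must be >= 2")
        if not 0.0 < self.fine_accuracy <= 1.0:
            raise ValidationError("fine_accuracy must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if self.error_burst_len < 1:
            raise ValidationError("error_burst_len must be >= 1")


@dataclass
class FeatureSequence:
    """Per-clip feature vectors (n_clips x feature_dim), fc8-like."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValidationError("feature matrix must be 2-D")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("feature matrix contains non-finite values")

    def __len__(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def feature_dim(self) -> int:
        return int(self.matrix.shape[1])


def simulate_workflow(cfg: WorkflowSimConfig) -> PhaseAnnotation:
    """Draw one synthetic procedure annotation.

    Phases appear in order 1,2,3,4,5 — or 1,2,3,5,4 with probability
    ``p_phase5_before_4``.  Each phase's unpaused duration is a normal draw
    clamped below at ``max(30 s, mean - 2*sd)``; with probability ``p_pause``
    a single pause interrupts the phase (the pause extends wall time, not the
    active duration).  Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    order = [1, 2, 3, 4, 5]
    if rng.random() < cfg.p_phase5_before_4:
        order = [1, 2, 3, 5, 4]

    events = []
    t = rng.uniform(*cfg.lead_range_s)
    for i, phase_id in enumerate(order):
        mean = cfg.phase_mean_s[phase_id - 1]
        sd = cfg.phase_sd_s[phase_id - 1]
        floor = max(DURATION_FLOOR_S, mean - 2.0 * sd)
        duration = max(float(rng.normal(mean, sd)) if sd > 0 else mean, floor)

        events.append(PhaseEvent(phase_id, "start", t))
        end = t + duration
        if rng.random() < cfg.p_pause:
            split = rng.uniform(0.2, 0.8)
            pause_len = rng.uniform(*cfg.pause_range_s)
            pause_at = t + split * duration
            events.append(PhaseEvent(phase_id, "pause", pause_at))
            events.append(PhaseEvent(phase_id, "resume", pause_at + pause_len))
            end += pause_len
        events.append(PhaseEvent(phase_id, "end", end))
        t = end
        if i < len(order) - 1:
            t += rng.uniform(*cfg.transition_range_s)

    tail = rng.uniform(*cfg.lead_range_s)
    return PhaseAnnotation(events=events, video_duration_s=t + tail)


def class_means(cfg: EmitterConfig) -> np.ndarray:
    """Fixed class mean vectors, one row per label code 0..6.

    Means are random unit directions scaled by ``class_separation``;
    consecutive-phase means are then pulled toward each other by
    ``adjacency_shrink`` to emulate the confusability of adjacent phases.
    """
    cfg.validate()
    rng = np.random.default_rng(_substream(cfg.seed, "means"))
    raw = rng.normal(size=(7, cfg.feature_dim))
    raw /= np.linalg.norm(raw, axis=1, keepdims=True)
    raw *= cfg.class_separation
    means = raw.copy()
    for code in range(1, 6):  # phases 1..5; neighbours are adjacent phases
        nbs = [c for c in (code - 1, code + 1) if 1 <= c <= 5]
        nb_mean = raw[nbs].mean(axis=0)
        means[code] = raw[code] + cfg.adjacency_shrink * (nb_mean - raw[code])
    return means


def emit_features(clips: ClipLabelSequence, cfg: EmitterConfig,
                  stream: int = 0) -> FeatureSequence:
    """Per-clip features: the clip label's class mean plus isotropic noise.

    The class means are a property of the emulated fine-level classifier and
    depend only on ``cfg.seed``; ``stream`` selects an independent noise
    realisation (one per video) without changing the means.
    """
    cfg.validate()
    means = class_means(cfg)
    rng = np.random.default_rng(_substream(cfg.seed, f"features:{stream}"))
    rows = means[clips.labels]
    if cfg.noise_sd > 0:
        rows = rows + cfg.noise_sd * rng.normal(size=(len(clips), cfg.feature_dim))
    return FeatureSequence(matrix=rows)


def emit_fine_predictions(clips: ClipLabelSequence, cfg: EmitterConfig,
                          stream: int = 0) -> ClipLabelSequence:
    """A corrupted copy of ``clips`` emulating a short-context classifier.

    Errors occur in bursts governed by a two-state Markov chain whose
    stationary error fraction is ``1 - fine_accuracy`` and whose mean error
    run length is ``error_burst_len``.  Within a burst the wrong label is
    held constant (re-drawn only if it collides with the moving groundtruth),
    biased toward the neighbouring phases of the true label.
    """
    cfg.validate()
    rng = np.random.default_rng(_substream(cfg.seed, f"fine:{stream}"))
    gt = clips.labels.copy()
    n = gt.size
    if cfg.fine_accuracy >= 1.0:
        return ClipLabelSequence(labels=gt, clip_len_frames=clips.clip_len_frames)

    err = 1.0 - cfg.fine_accuracy
    p_exit = 1.0 / cfg.error_burst_len
    p_enter = min(err * p_exit / max(cfg.fine_accuracy, 1e-12), 1.0)

    # two-state (correct/error) Markov chain, started from its stationary law
    in_error = np.empty(n, dtype=bool)
    state = bool(rng.random() < err)
    for i in range(n):
        in_error[i] = state
        if state:
            state = rng.random() >= p_exit
        else:
            state = rng.random() < p_enter

    out = gt.copy()
    burst_label = -1
    for i in range(n):
        if not in_error[i]:
            burst_label = -1
            continue
        if burst_label < 0 or burst_label == gt[i]:
            burst_label = _draw_wrong_label(int(gt[i]), rng)
        out[i] = burst_label
    return ClipLabelSequence(labels=out, clip_len_frames=clips.clip_len_frames)


def _draw_wrong_label(true_code: int, rng: np.random.Generator) -> int:
    """A wrong label among phases+transition, biased toward phase neighbours."""
    neighbours = [c for c in (true_code - 1, true_code + 1) if 1 <= c <= 5]
    candidates = [c for c in range(1, 7) if c != true_code]
    u = rng.random()
    if neighbours and u < 0.6:
        return int(neighbours[rng.integers(len(neighbours))])
    if u < 0.8 and true_code != int(PhaseLabel.TRANSITION):
        return int(PhaseLabel.TRANSITION)
    return int(candidates[rng.integers(len(candidates))])


def _substream(seed: int, tag: str) -> np.random.SeedSequence:
    tag_hash = int.from_bytes(hashlib.sha256(tag.encode()).digest()[:4], "big")
    return np.random.SeedSequence([seed & 0x7FFFFFFF, tag_hash & 0x7FFFFFFF])
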