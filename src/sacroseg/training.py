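"""Losses, target-sequence strategies, window sampling, and the training loop.

The loss is a class-weighted cross-entropy averaged over time steps and batch:

    L(y, x) = -(1 / (t*d)) * sum_k sum_j sum_i  w_i * y_ijk * log(x_ijk)

with the five phases weighted 1.0, the transition class 0.1 (ten times
smaller, to avoid its overestimation), and non-phase positions excluded
(weight 0).

Three target-sequence strategies are supported for the seq2seq decoder:

* ``baseline`` — the groundtruth labels (standard teacher forcing);
* ``noised``  — groundtruth with a fixed fraction (default 40%) of positions
  replaced by random wrong labels, teaching the model a filtering action and
  countering exposure bias;
* ``pred``    — the fine-level classifier's predicted labels, which preserve
  the real error structure of deployment.

Windows are sampled as a fixed number of evenly spaced sliding windows per
video, and each optimisation batch gathers the windows with the same index
across all videos, i.e. the samples at the same relative position in every
procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .core import ClipLabelSequence, PhaseLabel, ValidationError
from .models import SeqModelConfig, code_to_class
from .synthetic import FeatureSequence

logger = logging.getLogger(__name__)

__all__ = [
    "LossWeights",
    "TrainConfig",
    "TrainHistory",
    "VideoSample",
    "weighted_cross_entropy",
    "inject_noise",
    "build_target",
    "sample_window_starts",
    "train_seq2seq",
    "micro_accuracy",
]

STRATEGIES = ("baseline", "noised", "pred")

_EPS = 1e-12


@dataclass
class LossWeights:
    """Per-class weights indexed by network class (phases 0-4, transition 5)."""

    w: np.ndarray

    @classmethod
    def default(cls, n_classes: int = 6, transition_weight: float = 0.1) -> "LossWeights":
        w = np.ones(n_classes)
        if n_classes == 6:
            w[5] = transition_weight
        return cls(w=w)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if np.any(self.w < 0):
            raise ValidationError("loss weights must be nonnegative")


@dataclass
class TrainConfig:
    strategy: str = "noised"
    noise_rate: float = 0.4
    windows_per_video: int = 200
    epochs: int = 10
    lr: float = 1e-5
    lr_decay: float = 0.93
    lr_decay_every: int = 5
    validations_per_epoch: int = 4
    val_windows_per_video: int = 10
    resample_noise_each_epoch: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValidationError("noise_rate must lie in [0, 1]")
        if self.windows_per_video < 1:
            raise ValidationError("windows_per_video must be >= 1")
        if self.epochs < 1 or self.lr <= 0:
            raise ValidationError("epochs must be >= 1 and lr > 0")


@dataclass
class VideoSample:
    """One procedure's worth of aligned coarse-level sequences."""

    features: FeatureSequence
    gt: ClipLabelSequence
    fine_preds: ClipLabelSequence

    def __post_init__(self) -> None:
        if not (len(self.features) == len(self.gt) == len(self.fine_preds)):
            raise ValidationError("features, gt and fine_preds must be aligned")


@dataclass
class TrainHistory:
    steps: List[dict] = field(default_factory=list)
    validations: List[dict] = field(default_factory=list)
    best_accuracy: float = float("nan")
    best_step: int = -1


def weighted_cross_entropy(probs: np.ndarray, onehot: np.ndarray,
                           weights: LossWeights) -> float:
    """Weighted cross-entropy on softmax outputs of shape (t, d, n).

    ``t`` is sequence length, ``d`` batch size, ``n`` classes.  With t = 1
    this reduces exactly to the per-clip classification loss.  Zero
    probability at a true class is clamped at 1e-12 (and logged).
    """
    probs = np.asarray(probs, dtype=np.float64)
    onehot = np.asarray(onehot, dtype=np.float64)
    if probs.shape != onehot.shape:
        raise ValidationError(f"shape mismatch {probs.shape} vs {onehot.shape}")
    if probs.ndim == 2:
        probs, onehot = probs[None], onehot[None]
    t, d, _ = probs.shape
    hit = probs[(onehot > 0) & (probs < _EPS)]
    if hit.size:
        logger.warning("clamped %d zero probabilities at true classes", hit.size)
    logp = np.log(np.clip(probs, _EPS, None))
    return float(-(weights.w * onehot * logp).sum() / (t * d))


def inject_noise(labels: ClipLabelSequence, rate: float,
                 seed: int | np.random.Generator = 0) -> ClipLabelSequence:
    """Replace exactly ``round(rate * L)`` positions with random wrong labels.

    Positions are chosen uniformly without replacement; the replacement is
    drawn uniformly from phases+transition excluding the original label.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValidationError("rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = labels.labels.copy()
    n_flip = int(round(rate * out.size))
    if n_flip == 0:
        return ClipLabelSequence(labels=out, clip_len_frames=labels.clip_len_frames)
    positions = rng.choice(out.size, size=n_flip, replace=False)
    vocab = np.arange(1, 7)  # phases 1-5 and transition
    for pos in positions:
        options = vocab[vocab != out[pos]]
        out[pos] = options[rng.integers(options.size)]
    return ClipLabelSequence(labels=out, clip_len_frames=labels.clip_len_frames)


def build_target(strategy: str, gt: ClipLabelSequence, fine_preds: ClipLabelSequence,
                 cfg: TrainConfig,
                 rng: Optional[np.random.Generator] = None) -> ClipLabelSequence:
    """Construct the decoder target sequence for one training window."""
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown strategy {strategy!r}")
    if len(gt) != len(fine_preds):
        raise ValidationError("gt and fine_preds must be aligned")
    if strategy == "baseline":
        return gt
    if strategy == "pred":
        return fine_preds
    return inject_noise(gt, cfg.noise_rate,
                        rng if rng is not None else cfg.seed)


def sample_window_starts(n_clips: int, n_windows: int, window_len: int) -> List[int]:
    """Evenly spaced window start indices covering the whole video.

    ``start_i = round(i * (n_clips - window_len) / (n_windows - 1))``, so the
    first window starts at 0 and the last ends exactly at the video end; the
    spacing adapts to the video length.
    """
    if n_clips < window_len:
        raise ValidationError(f"video has {n_clips} clips < window_len {window_len}")
    span = n_clips - window_len
    if n_windows == 1:
        return [0]
    return [int(round(i * span / (n_windows - 1))) for i in range(n_windows)]


def _onehot_targets(gt_window: np.ndarray, n_classes: int,
                    weights: LossWeights) -> Tuple[np.ndarray, np.ndarray]:
    """One-hot labels and per-position validity for supervision codes."""
    classes = code_to_class(gt_window)
    valid = (classes >= 0) & (classes < n_classes)
    onehot = np.zeros(gt_window.shape + (n_classes,))
    idx = np.nonzero(valid)
    onehot[idx + (classes[valid],)] = 1.0
    return onehot, valid


def micro_accuracy(gt_codes: np.ndarray, pred_codes: np.ndarray) -> float:
    """Fraction correct over positions whose groundtruth is a phase (1-5)."""
    gt_codes = np.asarray(gt_codes).ravel()
    pred_codes = np.asarray(pred_codes).ravel()
    mask = (gt_codes >= 1) & (gt_codes <= 5)
    if not mask.any():
        raise ValidationError("no phase positions in groundtruth")
    return float((pred_codes[mask] == gt_codes[mask]).mean())


def train_seq2seq(videos: Sequence[VideoSample], model, cfg: TrainConfig,
                  val_videos: Sequence[VideoSample] = (),
                  weights: Optional[LossWeights] = None):
    """Train a sequence model; returns ``(model, TrainHistory)``.

    Batches gather the same window index across all training videos; the
    learning rate decays by ``lr_decay`` every ``lr_decay_every`` epochs;
    validation micro accuracy (transition and non-phase excluded) is computed
    ``validations_per_epoch`` times per epoch and the best parameters seen
    are restored at the end.  Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    if not videos:
        raise ValidationError("at least one training video required")
    mcfg: SeqModelConfig = model.config
    if weights is None:
        weights = LossWeights.default(mcfg.n_classes)
    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    optimizer = ad.Adam(params, lr=cfg.lr)

    starts = [sample_window_starts(len(v.gt), cfg.windows_per_video, mcfg.window_len)
              for v in videos]
    history = TrainHistory()
    best_state: Optional[List[np.ndarray]] = None
    step = 0
    steps_per_epoch = cfg.windows_per_video
    val_every = max(1, steps_per_epoch // max(cfg.validations_per_epoch, 1))

    for epoch in range(cfg.epochs):
        optimizer.lr = cfg.lr * cfg.lr_decay ** (epoch // cfg.lr_decay_every)
        order = rng.permutation(steps_per_epoch)
        for window_idx in order:
            feats, targets, sup = _assemble_batch(videos, starts, int(window_idx),
                                                  mcfg, cfg, rng)
            logits = model.forward(feats, targets)
            onehot, _ = _onehot_targets(sup, mcfg.n_classes, weights)
            # loss axes per the sequence form: (t, d, n)
            loss_t = ad.weighted_softmax_cross_entropy(
                logits.transpose(1, 0, 2), onehot.transpose(1, 0, 2), weights.w)
            loss = float(loss_t.data)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"divergent loss at step {step} (epoch {epoch}, window "
                    f"{window_idx}): {loss}"
                )
            optimizer.zero_grad()
            loss_t.backward()
            optimizer.step()
            history.steps.append({"step": step, "epoch": epoch,
                                  "loss": loss, "lr": optimizer.lr})
            step += 1
            if val_videos and step % val_every == 0:
                acc = _validate(model, val_videos, cfg)
                history.validations.append({"step": step, "accuracy": acc})
                if not (acc <= history.best_accuracy):  # NaN-safe strict improvement
                    history.best_accuracy = acc
                    history.best_step = step
                    best_state = [p.data.copy() for p in params]
    if best_state is not None:
        for p, data in zip(params, best_state):
            p.data = data
    return model, history


def _assemble_batch(videos, starts, window_idx: int, mcfg: SeqModelConfig,
                    cfg: TrainConfig, rng: np.random.Generator):
    feats, targets, sup = [], [], []
    for vid_idx, (video, vid_starts) in enumerate(zip(videos, starts)):
        s = vid_starts[window_idx]
        w = mcfg.window_len
        gt_window = ClipLabelSequence(labels=video.gt.labels[s:s + w])
        fine_window = ClipLabelSequence(labels=video.fine_preds.labels[s:s + w])
        noise_rng = rng
        if cfg.strategy == "noised" and not cfg.resample_noise_each_epoch:
            # frozen noise pattern per (window, video), identical across epochs
            noise_rng = np.random.default_rng([cfg.seed, window_idx, vid_idx])
        target = build_target(cfg.strategy, gt_window, fine_window, cfg, noise_rng)
        feats.append(video.features.matrix[s:s + w])
        targets.append(target.labels[: mcfg.out_len])
        sup.append(gt_window.labels[mcfg.shift:])
    return np.stack(feats), np.stack(targets), np.stack(sup)


def _validate(model, val_videos, cfg: TrainConfig) -> float:
    mcfg: SeqModelConfig = model.config
    gts, preds = [], []
    for video in val_videos:
        vstarts = sample_window_starts(len(video.gt), cfg.val_windows_per_video,
                                       mcfg.window_len)
        for s in vstarts:
            w = mcfg.window_len
            feats = video.features.matrix[s:s + w][None]
            target = video.fine_preds.labels[s:s + mcfg.out_len][None]
            logits = model.forward(feats, target)
            pred_codes = logits.data[0].argmax(axis=-1) + 1
            gt = video.gt.labels[s + mcfg.shift:s + w]
            mask = (gt >= 1) & (gt <= 5)
            gts.append(gt[mask])
            preds.append(pred_codes[mask])
    gt_all = np.concatenate(gts)
    pred_all = np.concatenate(preds)
    if gt_all.size == 0:
        return float("nan")
    return float((gt_all == pred_all).mean())
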