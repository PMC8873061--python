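"""Whole-video segmentation by sliding windows.

Two assembly schemes mirror the two window geometries:

* time-synchronous — non-overlapping windows tile the video, each refined
  against the fine-level predictions for the same interval, and the outputs
  are concatenated (the final partial window is right-aligned to the video
  end, with already-covered clips keeping the earlier window's label);

* time-shifted — only the first ``out_len`` clips are initialised from the
  fine-level predictions; windows then advance by ``stride`` clips, each one
  taking the current working labels as its target and predicting the
  time-shifted span, so the segmentation propagates recursively through the
  video.  Where overlapping windows disagree, the final label is the
  per-clip mode of all recorded predictions.

A sliding mode filter over the raw fine-level labels serves as the
non-learned smoothing baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .core import ClipLabelSequence, ValidationError
from .synthetic import FeatureSequence

__all__ = [
    "SegmentationResult",
    "segment_time_synchronous",
    "segment_time_shifted",
    "mode_average_filter",
]


@dataclass
class SegmentationResult:
    """Final whole-video labels plus the per-clip source of each label."""

    labels: ClipLabelSequence
    provenance: np.ndarray  # per clip: 'fine_init' | 'model' | 'filter'
    votes_per_clip: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.labels) != self.provenance.size:
            raise ValidationError("provenance must cover every clip")


def _predict_window(model, features: np.ndarray, target_codes: np.ndarray) -> np.ndarray:
    """Label codes for one window; ``model`` exposes forward(feats, targets)."""
    logits = model.forward(features[None], target_codes[None])
    data = logits.data if hasattr(logits, "data") else np.asarray(logits)
    return data[0].argmax(axis=-1) + 1  # class indices -> label codes


def segment_time_synchronous(model, features: FeatureSequence,
                             fine_preds: ClipLabelSequence) -> SegmentationResult:
    """Tile the video with non-overlapping windows refined against fine preds."""
    cfg = model.config
    w = cfg.window_len
    n = len(features)
    if n != len(fine_preds):
        raise ValidationError("features and fine_preds must be aligned")
    if n < w:
        raise ValidationError(
            f"video has {n} clips < one window ({w}); use the fine-level "
            "predictions directly (passthrough)"
        )
    starts = list(range(0, n - w + 1, w))
    if starts[-1] + w < n:
        starts.append(n - w)  # right-aligned final partial window
    out = np.full(n, -1, dtype=np.int64)
    for s in starts:
        pred = _predict_window(model, features.matrix[s:s + w],
                               fine_preds.labels[s:s + w])
        uncovered = out[s:s + w] < 0  # earlier windows keep their labels
        out[s:s + w][uncovered] = pred[uncovered]
    provenance = np.full(n, "model", dtype=object)
    return SegmentationResult(
        labels=ClipLabelSequence(labels=out, clip_len_frames=fine_preds.clip_len_frames),
        provenance=provenance,
    )


def segment_time_shifted(model, features: FeatureSequence,
                         fine_preds: ClipLabelSequence,
                         stride: Optional[int] = None,
                         update_rule: str = "last") -> SegmentationResult:
    """Recursive whole-video inference for the time-shifted configuration.

    The working label sequence starts as the fine-level predictions for the
    first ``out_len`` clips; each window's target is the working labels for
    its first ``out_len`` positions and its predictions are recorded for the
    shifted span.  ``update_rule`` controls what the recursion feeds forward:
    the latest window's predictions (``"last"``, default) or the running
    per-clip mode (``"mode"``).  Final labels are the per-clip mode over all
    recorded predictions; clips before the first predicted position keep the
    fine-level labels (provenance ``fine_init``).
    """
    cfg = model.config
    w, out_len, shift = cfg.window_len, cfg.out_len, cfg.shift
    if shift < 1:
        raise ValidationError("segment_time_shifted requires a time-shifted model")
    if stride is None:
        stride = shift
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    if stride > shift:
        warnings.warn(
            f"stride {stride} > shift {shift}: some clips receive no model "
            "prediction and fall back to fine-level labels", stacklevel=2)
    n = len(features)
    if n != len(fine_preds):
        raise ValidationError("features and fine_preds must be aligned")
    if n < w:
        raise ValidationError(f"video has {n} clips < one window ({w})")

    working = fine_preds.labels.copy()
    votes: List[List[int]] = [[] for _ in range(n)]
    starts = list(range(0, n - w + 1, stride))
    if starts[-1] != n - w:
        starts.append(n - w)  # right-aligned final window
    for s in starts:
        pred = _predict_window(model, features.matrix[s:s + w],
                               working[s:s + out_len])
        span = np.arange(s + shift, s + w)
        for pos, code in zip(span, pred):
            votes[pos].append(int(code))
        if update_rule == "mode":
            for pos in span:
                working[pos] = _mode(votes[pos])
        else:
            working[span] = pred

    out = np.empty(n, dtype=np.int64)
    provenance = np.empty(n, dtype=object)
    n_votes = np.zeros(n, dtype=np.int64)
    for pos in range(n):
        n_votes[pos] = len(votes[pos])
        if votes[pos]:
            out[pos] = _mode(votes[pos])
            provenance[pos] = "model"
        else:
            out[pos] = fine_preds.labels[pos]
            provenance[pos] = "fine_init"
    return SegmentationResult(
        labels=ClipLabelSequence(labels=out, clip_len_frames=fine_preds.clip_len_frames),
        provenance=provenance,
        votes_per_clip=n_votes,
    )


def _mode(values) -> int:
    """Most frequent value; ties break toward the lowest label code."""
    counts = np.bincount(np.asarray(values, dtype=np.int64))
    return int(counts.argmax())


def mode_average_filter(labels: ClipLabelSequence, width: int = 101) -> ClipLabelSequence:
    """Sliding mode filter; window clipped at the sequence boundaries."""
    if width < 1 or width % 2 == 0:
        raise ValidationError("filter width must be odd and >= 1")
    arr = labels.labels
    half = (width - 1) // 2
    out = np.empty_like(arr)
    for t in range(arr.size):
        lo = max(0, t - half)
        hi = min(arr.size, t + half + 1)
        out[t] = _mode(arr[lo:hi])
    return ClipLabelSequence(labels=out, clip_len_frames=labels.clip_len_frames)
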