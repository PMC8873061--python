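"""Frame(clip)-based metrics and the event-based Ward error taxonomy.

Frame-based metrics follow the conventions of the surgical-workflow
literature: macro-averaged precision and recall over the five procedure
phases (the transition class is excluded from the macro average, non-phase
positions are excluded entirely), F1 as the harmonic mean of macro precision
and recall, and micro accuracy over all positions whose groundtruth is a
phase.

The event-based evaluation treats every maximal run of a class as an event
with a start and stop time and scores it one-vs-rest, phase by phase, then
sums the counts.  Each groundtruth event falls in exactly one category —
Correct (C), Deletion (D), Fragmented (F), Merged (M), or Fragmented-and-
Merged (FM) — and each predicted event in exactly one of C, Insertion (I'),
Fragmenting (F'), Merging (M'), or FM', so the counts obey

    n_gt_events  = C + D + F + M + FM
    n_pred_events = C + I' + F' + M' + FM'.

The event ratio n_gt_events / n_pred_events summarises over-fragmentation:
values near 1 indicate a consistent phase-transition structure, values near
0 a heavily fragmented prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .core import PHASES, ClipLabelSequence, PhaseLabel, ValidationError

__all__ = [
    "Event",
    "WardSummary",
    "FrameMetrics",
    "extract_events",
    "ward_score",
    "frame_metrics",
    "harmonic_f1",
    "confusion_matrix",
    "event_analysis_summary",
]


@dataclass(frozen=True)
class Event:
    """A maximal run of one class: inclusive clip indices [start, stop]."""

    label: int
    start: int
    stop: int

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


WARD_CATEGORIES = ("C", "D", "F", "M", "FM", "I'", "F'", "M'", "FM'")


@dataclass
class WardSummary:
    counts: Dict[str, int] = field(default_factory=lambda: {c: 0 for c in WARD_CATEGORIES})
    per_class: Dict[int, Dict[str, int]] = field(default_factory=dict)
    n_gt_events: int = 0
    n_pred_events: int = 0

    @property
    def event_ratio(self) -> float:
        """n_gt / n_pred; 0 with no predicted events (worst case), 1 if both empty."""
        if self.n_pred_events == 0:
            return 1.0 if self.n_gt_events == 0 else 0.0
        return self.n_gt_events / self.n_pred_events

    def __getitem__(self, key: str) -> int:
        return self.counts[key]


def extract_events(labels: ClipLabelSequence | np.ndarray, label: int) -> List[Event]:
    """Maximal runs of ``label``, in order."""
    arr = labels.labels if isinstance(labels, ClipLabelSequence) else np.asarray(labels)
    hits = np.asarray(arr) == label
    if not hits.any():
        return []
    padded = np.concatenate([[False], hits, [False]])
    edges = np.diff(padded.astype(np.int8))
    starts = np.nonzero(edges == 1)[0]
    stops = np.nonzero(edges == -1)[0] - 1
    return [Event(int(label), int(b), int(e)) for b, e in zip(starts, stops)]


def ward_score(gt: ClipLabelSequence | np.ndarray, pred: ClipLabelSequence | np.ndarray,
               classes: Optional[Sequence[int]] = None) -> WardSummary:
    """Event-based scoring, one-vs-rest per class, counts summed over classes.

    ``classes`` defaults to the five procedure phases; transition and
    non-phase stay in the timeline (they can separate runs) but are not
    scored.  Overlap means sharing at least one clip index.
    """
    gt_arr = gt.labels if isinstance(gt, ClipLabelSequence) else np.asarray(gt)
    pred_arr = pred.labels if isinstance(pred, ClipLabelSequence) else np.asarray(pred)
    if gt_arr.size != pred_arr.size:
        raise ValidationError(
            f"length mismatch: gt has {gt_arr.size} clips, pred {pred_arr.size}")
    if classes is None:
        classes = [int(p) for p in PHASES]

    summary = WardSummary()
    for cls in classes:
        g_events = extract_events(gt_arr, cls)
        p_events = extract_events(pred_arr, cls)
        overlaps = [[_overlap(g, p) for p in p_events] for g in g_events]
        g_deg = [sum(row) for row in overlaps]                     # preds per gt event
        p_deg = [sum(row[j] for row in overlaps) for j in range(len(p_events))]

        local = {c: 0 for c in WARD_CATEGORIES}
        for gi, g in enumerate(g_events):
            partners = [j for j in range(len(p_events)) if overlaps[gi][j]]
            if not partners:
                local["D"] += 1
            elif len(partners) > 1:
                if any(p_deg[j] > 1 for j in partners):
                    local["FM"] += 1
                else:
                    local["F"] += 1
            elif p_deg[partners[0]] > 1:
                local["M"] += 1
            else:
                local["C"] += 1
        for pj in range(len(p_events)):
            partners = [gi for gi in range(len(g_events)) if overlaps[gi][pj]]
            if not partners:
                local["I'"] += 1
            elif len(partners) > 1:
                if any(g_deg[gi] > 1 for gi in partners):
                    local["FM'"] += 1
                else:
                    local["M'"] += 1
            elif g_deg[partners[0]] > 1:
                local["F'"] += 1
            # else: the matched pair, already counted as C from the GT side

        summary.per_class[cls] = local
        for cat, count in local.items():
            summary.counts[cat] += count
        summary.n_gt_events += len(g_events)
        summary.n_pred_events += len(p_events)
    return summary


def _overlap(a: Event, b: Event) -> bool:
    return a.start <= b.stop and b.start <= a.stop


def harmonic_f1(precision: float, recall: float) -> float:
    """F1 = 2PR/(P+R); scale-consistent (fractions in/out, percents in/out)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class FrameMetrics:
    """All values as fractions in [0, 1]."""

    macro_precision: float
    macro_recall: float
    f1: float
    micro_accuracy: float


def frame_metrics(gt: ClipLabelSequence | np.ndarray,
                  pred: ClipLabelSequence | np.ndarray) -> FrameMetrics:
    """Macro P/R over phases present in the groundtruth, F1, micro accuracy."""
    gt_arr = np.asarray(gt.labels if isinstance(gt, ClipLabelSequence) else gt)
    pred_arr = np.asarray(pred.labels if isinstance(pred, ClipLabelSequence) else pred)
    if gt_arr.size != pred_arr.size:
        raise ValidationError(
            f"length mismatch: gt has {gt_arr.size} clips, pred {pred_arr.size}")

    keep = gt_arr != int(PhaseLabel.NONPHASE)  # non-phase excluded entirely
    g, p = gt_arr[keep], pred_arr[keep]
    phase_mask = (g >= 1) & (g <= 5)
    if not phase_mask.any():
        raise ValidationError("no phase positions in groundtruth: metrics undefined")

    present = sorted(set(np.unique(g[phase_mask]).tolist()))
    prec, rec, _, _ = precision_recall_fscore_support(
        g, p, labels=present, zero_division=0)
    macro_p = float(np.mean(prec))
    macro_r = float(np.mean(rec))
    micro = float((g[phase_mask] == p[phase_mask]).mean())
    return FrameMetrics(macro_precision=macro_p, macro_recall=macro_r,
                        f1=harmonic_f1(macro_p, macro_r), micro_accuracy=micro)


def confusion_matrix(gt: ClipLabelSequence | np.ndarray,
                     pred: ClipLabelSequence | np.ndarray) -> np.ndarray:
    """5x5 row-normalised confusion over phases; transition/non-phase dropped.

    Row k (groundtruth phase k+1) is divided by that phase's retained sample
    count; a phase absent from the groundtruth leaves a zero row.
    """
    gt_arr = np.asarray(gt.labels if isinstance(gt, ClipLabelSequence) else gt)
    pred_arr = np.asarray(pred.labels if isinstance(pred, ClipLabelSequence) else pred)
    if gt_arr.size != pred_arr.size:
        raise ValidationError("length mismatch between gt and pred")
    keep = ((gt_arr >= 1) & (gt_arr <= 5)) & ((pred_arr >= 1) & (pred_arr <= 5))
    labels = [int(p) for p in PHASES]
    counts = _sk_confusion(gt_arr[keep], pred_arr[keep], labels=labels).astype(float)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        normed = np.where(row_sums > 0, counts / row_sums, 0.0)
    return normed


def event_analysis_summary(summary: WardSummary) -> str:
    """Plain-text event-analysis-diagram style summary."""
    lines = ["event analysis (per-category counts, summed over phases)"]
    gt_part = "  groundtruth: " + "  ".join(
        f"{c}={summary.counts[c]}" for c in ("C", "D", "F", "M", "FM"))
    pr_part = "  prediction:  " + "  ".join(
        f"{c}={summary.counts[c]}" for c in ("C", "I'", "F'", "M'", "FM'"))
    lines += [gt_part, pr_part,
              f"  events: gt={summary.n_gt_events} pred={summary.n_pred_events}"
              f"  event_ratio={summary.event_ratio:.3f}"]
    return "\n".join(lines)
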