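"""Domain types for coarse-level surgical workflow segmentation.

The package models a laparoscopic sacrocolpopexy procedure as a timeline of
five surgical phases (promontory preparation; dissection of vault and gutter;
mesh fixation to vault; mesh fixation to promontory; peritonealisation),
annotated with timestamped start / pause / resume / end events.  Everything
downstream works on two resolutions:

* frames — the video downsampled to a fixed rate (2.4 fps by default);
* clips — blocks of 16 consecutive frames, the atomic unit of coarse-level
  sequence modelling.  A clip's label is the modal frame label.

Label codes (CSV interface): 0 = non-phase (before the first / after the last
phase), 1–5 = surgical phases, 6 = transition (between two phases, or a
paused span of a phase).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "ValidationError",
    "ParseError",
    "PhaseLabel",
    "PHASES",
    "PhaseEvent",
    "PhaseAnnotation",
    "FrameLabelSequence",
    "ClipLabelSequence",
    "intervals_to_frame_labels",
    "frames_to_clips",
    "read_annotation",
    "write_annotation",
    "read_labels",
    "write_labels",
]


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


class ParseError(ValueError):
    """Raised on malformed input files; message carries the line number."""


class PhaseLabel(enum.IntEnum):
    """Label vocabulary: five phases plus the two bookkeeping classes."""

    NONPHASE = 0
    P1 = 1
    P2 = 2
    P3 = 3
    P4 = 4
    P5 = 5
    TRANSITION = 6


#: The five procedure phases, in workflow order.  TRANSITION and NONPHASE are
#: never counted as procedure phases by any metric.
PHASES: Tuple[PhaseLabel, ...] = (
    PhaseLabel.P1,
    PhaseLabel.P2,
    PhaseLabel.P3,
    PhaseLabel.P4,
    PhaseLabel.P5,
)

_EVENT_KINDS = ("start", "pause", "resume", "end")


@dataclass(frozen=True)
class PhaseEvent:
    phase_id: int
    kind: str
    time_s: float


@dataclass
class PhaseAnnotation:
    """Timestamped phase intervals (with pause/resume) for one procedure."""

    events: List[PhaseEvent]
    video_duration_s: float
    fps_native: float = 24.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.video_duration_s < 0:
            raise ValidationError("video_duration_s must be nonnegative")
        if self.fps_native <= 0:
            raise ValidationError("fps_native must be positive")
        last_t = -np.inf
        for ev in self.events:
            if ev.kind not in _EVENT_KINDS:
                raise ValidationError(f"unknown event kind {ev.kind!r}")
            if ev.phase_id not in range(1, 6):
                raise ValidationError(f"phase_id {ev.phase_id} outside 1..5")
            if ev.time_s < last_t - 1e-9:
                raise ValidationError(
                    f"events not time-sorted at {ev.phase_id}/{ev.kind} t={ev.time_s}"
                )
            if not (0 <= ev.time_s <= self.video_duration_s + 1e-9):
                raise ValidationError(
                    f"event time {ev.time_s} outside [0, {self.video_duration_s}]"
                )
            last_t = ev.time_s
        # every start closed by end; pause/resume strictly nested
        open_phase: dict[int, str] = {}
        for ev in self.events:
            state = open_phase.get(ev.phase_id)
            if ev.kind == "start":
                if state is not None:
                    raise ValidationError(f"phase {ev.phase_id} started twice")
                open_phase[ev.phase_id] = "active"
            elif ev.kind == "pause":
                if state != "active":
                    raise ValidationError(f"pause outside active phase {ev.phase_id}")
                open_phase[ev.phase_id] = "paused"
            elif ev.kind == "resume":
                if state != "paused":
                    raise ValidationError(f"resume without pause in phase {ev.phase_id}")
                open_phase[ev.phase_id] = "active"
            else:  # end
                if state != "active":
                    raise ValidationError(f"end without active phase {ev.phase_id}")
                open_phase[ev.phase_id] = "closed"
        still_open = [p for p, s in open_phase.items() if s not in (None, "closed")]
        if still_open:
            raise ValidationError(f"phases never ended: {still_open}")

    def active_intervals(self) -> List[Tuple[int, float, float]]:
        """Unpaused (phase_id, begin_s, end_s) spans, in timeline order."""
        spans: List[Tuple[int, float, float]] = []
        open_at: dict[int, float] = {}
        for ev in self.events:
            if ev.kind in ("start", "resume"):
                open_at[ev.phase_id] = ev.time_s
            else:  # pause or end closes the current active span
                spans.append((ev.phase_id, open_at.pop(ev.phase_id), ev.time_s))
        spans.sort(key=lambda s: s[1])
        return spans

    def phase_active_duration(self, phase_id: int) -> float:
        """Summed unpaused duration of one phase, in seconds."""
        return sum(e - b for p, b, e in self.active_intervals() if p == phase_id)

    def phase_span(self) -> Tuple[float, float]:
        """(first start, last end) over all phases; (0, 0) if no events."""
        starts = [ev.time_s for ev in self.events if ev.kind == "start"]
        ends = [ev.time_s for ev in self.events if ev.kind == "end"]
        if not starts:
            return (0.0, 0.0)
        return (min(starts), max(ends))


@dataclass
class FrameLabelSequence:
    """One PhaseLabel per downsampled frame."""

    labels: np.ndarray
    fps: float = 2.4

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size == 0:
            raise ValidationError("FrameLabelSequence must be non-empty")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        _check_codes(self.labels)

    def __len__(self) -> int:
        return int(self.labels.size)


@dataclass
class ClipLabelSequence:
    """One PhaseLabel per clip; the unit of all coarse-level modelling."""

    labels: np.ndarray
    clip_len_frames: int = 16

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size < 1:
            raise ValidationError("ClipLabelSequence must contain at least one clip")
        if self.clip_len_frames < 1:
            raise ValidationError("clip_len_frames must be >= 1")
        _check_codes(self.labels)

    def __len__(self) -> int:
        return int(self.labels.size)


def _check_codes(labels: np.ndarray) -> None:
    valid = set(int(v) for v in PhaseLabel)
    bad = set(np.unique(labels).tolist()) - valid
    if bad:
        raise ValidationError(f"unknown label codes {sorted(bad)}")


def intervals_to_frame_labels(ann: PhaseAnnotation, fps: float) -> FrameLabelSequence:
    """Rasterize a phase annotation onto a fixed frame grid.

    Frame ``t`` covers the time interval ``[t/fps, (t+1)/fps)`` and receives
    the phase active at ``t/fps``.  Gaps between phases and paused spans map
    to TRANSITION; time before the first start / after the last end maps to
    NONPHASE.  Overlapping active phases raise :class:`ValidationError`.
    """
    if fps <= 0:
        raise ValidationError("fps must be positive")
    ann.validate()
    n = int(np.floor(ann.video_duration_s * fps))
    if n < 1:
        raise ValidationError("video too short for a single frame")
    labels = np.full(n, int(PhaseLabel.NONPHASE), dtype=np.int64)

    spans = ann.active_intervals()
    for (p1, b1, e1), (p2, b2, e2) in zip(spans, spans[1:]):
        if b2 < e1 - 1e-9:
            raise ValidationError(
                f"overlapping active phases: phase {p1} [{b1}, {e1}] and "
                f"phase {p2} [{b2}, {e2}]"
            )

    first_start, last_end = ann.phase_span()
    if spans:
        _fill(labels, first_start, last_end, fps, int(PhaseLabel.TRANSITION))
        for phase_id, begin, end in spans:
            _fill(labels, begin, end, fps, phase_id)
    return FrameLabelSequence(labels=labels, fps=fps)


def _fill(labels: np.ndarray, begin_s: float, end_s: float, fps: float, code: int) -> None:
    # frame t is inside [begin, end) iff t/fps in that interval
    t0 = int(np.ceil(begin_s * fps - 1e-9))
    t1 = int(np.ceil(end_s * fps - 1e-9))
    labels[max(t0, 0) : min(t1, labels.size)] = code


def frames_to_clips(fls: FrameLabelSequence, clip_len: int = 16) -> ClipLabelSequence:
    """Group frames into non-overlapping clips labelled by their modal frame.

    Ties break toward the lowest label code; a trailing partial block is
    dropped.  Raises :class:`ValidationError` if fewer than ``clip_len``
    frames are available.
    """
    if clip_len < 1:
        raise ValidationError("clip_len must be >= 1")
    n_clips = len(fls) // clip_len
    if n_clips == 0:
        raise ValidationError(
            f"need at least {clip_len} frames to form one clip, got {len(fls)}"
        )
    blocks = fls.labels[: n_clips * clip_len].reshape(n_clips, clip_len)
    n_codes = max(int(v) for v in PhaseLabel) + 1
    counts = np.zeros((n_clips, n_codes), dtype=np.int64)
    for code in range(n_codes):
        counts[:, code] = (blocks == code).sum(axis=1)
    clip_labels = counts.argmax(axis=1)  # argmax returns the lowest code on ties
    return ClipLabelSequence(labels=clip_labels, clip_len_frames=clip_len)


# ---------------------------------------------------------------------------
# File I/O: annotation CSV (phase_id,event,time_s) and label CSV (one code
# per line).  Parsed by hand so errors can name the offending line.
# ---------------------------------------------------------------------------

_ANN_HEADER = ["phase_id", "event", "time_s"]


def write_annotation(path, ann: PhaseAnnotation) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ANN_HEADER)
        for ev in ann.events:
            writer.writerow([ev.phase_id, ev.kind, f"{ev.time_s:.6f}"])
        writer.writerow(["#video_duration_s", "", f"{ann.video_duration_s:.6f}"])
        writer.writerow(["#fps_native", "", f"{ann.fps_native:.6f}"])


def read_annotation(path) -> PhaseAnnotation:
    events: List[PhaseEvent] = []
    duration = None
    fps_native = 24.0
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (lineno == 1 and row == _ANN_HEADER):
                continue
            if row[0].startswith("#"):
                key = row[0].lstrip("#")
                if key == "video_duration_s":
                    duration = float(row[2])
                elif key == "fps_native":
                    fps_native = float(row[2])
                continue
            if len(row) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            try:
                phase_id = int(row[0])
                time_s = float(row[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            kind = row[1].strip()
            if kind not in _EVENT_KINDS:
                raise ParseError(f"{path}:{lineno}: unknown event kind {kind!r}")
            events.append(PhaseEvent(phase_id, kind, time_s))
    if duration is None:
        duration = max((ev.time_s for ev in events), default=0.0)
    try:
        return PhaseAnnotation(events=events, video_duration_s=duration, fps_native=fps_native)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_labels(path, seq: ClipLabelSequence | FrameLabelSequence) -> None:
    with open(path, "w") as fh:
        for code in np.asarray(seq.labels):
            fh.write(f"{int(code)}\n")


def read_labels(path, clip_len_frames: int = 16) -> ClipLabelSequence:
    codes: List[int] = []
    valid = set(int(v) for v in PhaseLabel)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                code = int(line)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: not an integer label: {line!r}") from exc
            if code not in valid:
                raise ParseError(f"{path}:{lineno}: unknown label code {code}")
            codes.append(code)
    if not codes:
        raise ParseError(f"{path}: empty label file")
    return ClipLabelSequence(labels=np.array(codes), clip_len_frames=clip_len_frames)
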