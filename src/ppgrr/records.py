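"""Domain types for PPG recordings and their respiratory-rate references.

A :class:`PPGRecord` holds one subject recording: the raw photoplethysmogram,
its sampling rate, and exactly one *reference* from which ground-truth
respiratory rate (RR, breaths per minute) can be derived:

* :class:`RRSeries` — a low-rate (typically 1 Hz) numeric RR trace, as shipped
  with ICU monitor exports;
* :class:`BreathAnnotations` — expert-annotated breath onset times, as in
  capnography benchmark datasets;
* :class:`ExhalationMarks` — manually keyed exhalation instants recorded at
  the bedside.

Window labels use the half-open interval convention ``[start_s, end_s)`` in
seconds from recording start, so an event falling exactly on a window
boundary is counted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple, Union

import numpy as np

from .errors import LabelingError, ValidationError

__all__ = [
    "RRSeries",
    "ExhalationMarks",
    "BreathAnnotations",
    "PPGRecord",
    "rr_label_for_interval",
    "record_mean_rr",
]


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def _check_strictly_increasing(t: np.ndarray, name: str) -> None:
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValidationError(f"{name} must be strictly increasing")


@dataclass(frozen=True)
class RRSeries:
    """A sampled respiratory-rate trace (times in s, values in brpm)."""

    times_s: np.ndarray
    rr_brpm: np.ndarray

    def __post_init__(self):
        t = _as_1d_float(self.times_s, "times_s")
        v = _as_1d_float(self.rr_brpm, "rr_brpm")
        if t.size != v.size:
            raise ValidationError("times_s and rr_brpm must have equal length")
        _check_strictly_increasing(t, "times_s")
        if np.any(v[np.isfinite(v)] < 0):
            raise ValidationError("rr_brpm values must be >= 0")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "rr_brpm", v)


@dataclass(frozen=True)
class ExhalationMarks:
    """Exhalation keypress instants, seconds from recording start."""

    times_s: np.ndarray

    def __post_init__(self):
        t = _as_1d_float(self.times_s, "times_s")
        _check_strictly_increasing(t, "times_s")
        if t.size and (t[0] < 0):
            raise ValidationError("exhalation marks must be >= 0 s")
        object.__setattr__(self, "times_s", t)


@dataclass(frozen=True)
class BreathAnnotations:
    """Annotated breath-onset times, seconds from recording start."""

    breath_times_s: np.ndarray

    def __post_init__(self):
        t = _as_1d_float(self.breath_times_s, "breath_times_s")
        _check_strictly_increasing(t, "breath_times_s")
        object.__setattr__(self, "breath_times_s", t)


RRReference = Union[RRSeries, ExhalationMarks, BreathAnnotations]


@dataclass
class PPGRecord:
    """One subject recording with exactly one RR reference."""

    subject_id: str
    ppg: np.ndarray
    fs: float
    rr_reference: RRReference
    demographics: Optional[Mapping[str, object]] = None
    duration_s: Optional[float] = None
    flags: Tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.subject_id:
            raise ValidationError("subject_id must be non-empty")
        if self.fs <= 0:
            raise ValidationError("fs must be > 0")
        self.ppg = _as_1d_float(self.ppg, "ppg")
        if self.duration_s is None:
            self.duration_s = self.ppg.size / self.fs
        if self.ppg.size != round(self.fs * self.duration_s):
            raise ValidationError(
                f"ppg length {self.ppg.size} != round(fs*duration_s) = "
                f"{round(self.fs * self.duration_s)}"
            )
        if not isinstance(self.rr_reference, (RRSeries, ExhalationMarks, BreathAnnotations)):
            raise ValidationError("rr_reference must be one of the reference variants")
        if isinstance(self.rr_reference, ExhalationMarks):
            t = self.rr_reference.times_s
            if t.size and t[-1] > self.duration_s:
                raise ValidationError("exhalation marks must lie within [0, duration_s]")

    def event_times(self) -> Optional[np.ndarray]:
        """Event instants for event-based references, None for RRSeries."""
        if isinstance(self.rr_reference, ExhalationMarks):
            return self.rr_reference.times_s
        if isinstance(self.rr_reference, BreathAnnotations):
            return self.rr_reference.breath_times_s
        return None


def rr_label_for_interval(
    record: PPGRecord, start_s: float, end_s: float, statistic: str = "mean"
) -> float:
    """Ground-truth RR (brpm) over the half-open window ``[start_s, end_s)``.

    For an :class:`RRSeries` reference the label is the arithmetic mean of
    the series samples inside the window (``statistic="median"`` selects
    the median for heavy-tailed references); for event references it is
    the event count scaled to a per-minute rate.
    """
    if statistic not in ("mean", "median"):
        raise ValidationError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    if not (0 <= start_s < end_s <= record.duration_s + 1e-9):
        raise ValidationError(
            f"window [{start_s}, {end_s}) not within [0, {record.duration_s}]"
        )
    ref = record.rr_reference
    if isinstance(ref, RRSeries):
        mask = (ref.times_s >= start_s) & (ref.times_s < end_s)
        vals = ref.rr_brpm[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise LabelingError(
                f"no RR series samples in [{start_s}, {end_s}) for {record.subject_id}"
            )
        return float(np.median(vals)) if statistic == "median" else float(vals.mean())
    events = record.event_times()
    count = int(np.count_nonzero((events >= start_s) & (events < end_s)))
    return count * 60.0 / (end_s - start_s)


def record_mean_rr(record: PPGRecord) -> float:
    """Mean RR of a whole record (used to assign a subject's breathing group)."""
    return rr_label_for_interval(record, 0.0, float(record.duration_s))
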