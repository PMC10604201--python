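"""Raw PPG records → filtered, resampled, normalized, RR-labeled windows.

The chain, applied in this order to each record:

1. band-pass the whole record at its source rate with a Hamming-window FIR
   filter (0.1–0.4 Hz, the respiratory band), applied zero-phase so breath
   timing is not delayed relative to the RR labels;
2. slice 60 s windows with a 1 s shift;
3. resample each window to 30 Hz by linear interpolation;
4. min–max normalize each window into [0, 1];
5. label each window with the reference RR over its half-open interval and
   tag it with its breathing group (slow < 12, normal 12–20, rapid > 20 brpm).

Normalization scope is per-window so that inference never depends on
dataset-level statistics; RR labels stay in brpm by default (an optional
helper normalizes targets for experiments probing that choice).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import DesignError, ParameterError, ShapeError, ValidationError
from .records import PPGRecord, rr_label_for_interval

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "WindowSpec",
    "WindowSample",
    "design_bandpass",
    "apply_filter",
    "resample_linear",
    "minmax_normalize",
    "assign_group",
    "count_windows",
    "slice_windows",
    "save_windows",
    "load_windows",
    "normalize_labels_minmax",
]

GROUPS = ("slow", "normal", "rapid")


@dataclass(frozen=True)
class FilterSpec:
    """Respiratory-band FIR band-pass specification.

    1025 taps at 125 Hz are enough for the narrow 0.1–0.4 Hz band: the
    Hamming transition leaves the passband centre at 0 dB and the edges
    within 3 dB, while everything at and above 1 Hz (the cardiac band)
    drops by more than 50 dB. The frequency-response contract, not the tap
    count, is normative; :func:`design_bandpass` verifies it.
    """

    low_hz: float = 0.1
    high_hz: float = 0.4
    taps: int = 1025
    window_name: str = "hamming"

    def validate(self, fs: float) -> None:
        if not (0 < self.low_hz < self.high_hz < fs / 2):
            raise DesignError(
                f"need 0 < low ({self.low_hz}) < high ({self.high_hz}) < fs/2 ({fs / 2})"
            )
        if self.taps < 3 or self.taps % 2 == 0:
            raise DesignError("taps must be a positive odd integer >= 3")


@dataclass(frozen=True)
class WindowSpec:
    """Windowing parameters: 60 s windows, 1 s shift, resampled to 30 Hz."""

    length_s: float = 60.0
    shift_s: float = 1.0
    target_fs: float = 30.0

    def validate(self, source_fs: float) -> None:
        if self.shift_s <= 0 or self.length_s <= 0:
            raise ParameterError("length_s and shift_s must be > 0")
        if self.shift_s > self.length_s:
            raise ParameterError("shift_s must be <= length_s")
        if self.target_fs <= 0 or self.target_fs > source_fs:
            raise ParameterError("target_fs must be in (0, source fs]")

    @property
    def samples_out(self) -> int:
        return int(round(self.length_s * self.target_fs))


@dataclass
class WindowSample:
    """One preprocessed window with its scalar ground-truth RR label."""

    subject_id: str
    values: np.ndarray
    rr_true: float
    group: str
    start_s: float = 0.0
    window_index: int = 0


def design_bandpass(spec: FilterSpec, fs: float) -> np.ndarray:
    """Design the linear-phase FIR band-pass and verify its response contract.

    The designed response must stay within 3 dB of unity over the passband
    interior (edges pulled in by 0.05 Hz) and at or below −20 dB from
    2.5 × ``high_hz`` upward; failure raises :class:`DesignError` with a
    suggestion to increase the tap count.
    """
    spec.validate(fs)
    b = sps.firwin(
        spec.taps,
        [spec.low_hz, spec.high_hz],
        pass_zero=False,
        window=spec.window_name,
        fs=fs,
    )
    w, h = sps.freqz(b, worN=8192, fs=fs)
    mag_db = 20 * np.log10(np.abs(h) + 1e-300)
    inner_lo, inner_hi = spec.low_hz + 0.05, spec.high_hz - 0.05
    pass_mask = (w >= inner_lo) & (w <= inner_hi)
    stop_mask = w >= 2.5 * spec.high_hz
    if pass_mask.any() and mag_db[pass_mask].min() < -3.0:
        raise DesignError(
            f"passband [{inner_lo:.2f}, {inner_hi:.2f}] Hz dips to "
            f"{mag_db[pass_mask].min():.1f} dB; increase taps (got {spec.taps})"
        )
    if stop_mask.any() and mag_db[stop_mask].max() > -20.0:
        raise DesignError(
            f"stopband attenuation only {mag_db[stop_mask].max():.1f} dB at "
            f">= {2.5 * spec.high_hz:.2f} Hz; increase taps (got {spec.taps})"
        )
    return b


def apply_filter(ppg: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Zero-phase (forward–backward) FIR filtering, length-preserving.

    Equivalent to filtering with the squared magnitude response and zero
    phase: the signal is reflect-padded, convolved with the autocorrelation
    of the FIR taps, and cropped back.
    """
    x = np.asarray(ppg, dtype=float)
    b = np.asarray(coeffs, dtype=float)
    if x.size <= b.size:
        raise ShapeError(f"signal length {x.size} must exceed filter length {b.size}")
    pad = b.size
    xp = np.pad(x, pad, mode="reflect")
    kernel = np.correlate(b, b, mode="full")  # symmetric, zero-phase, |H|^2
    y = sps.fftconvolve(xp, kernel, mode="same")
    return y[pad:-pad]


def resample_linear(ppg: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Resample onto a uniform ``fs_out`` grid by linear interpolation."""
    if fs_out <= 0:
        raise ParameterError("fs_out must be > 0")
    if fs_out > fs_in:
        raise ParameterError("fs_out must be <= fs_in")
    x = np.asarray(ppg, dtype=float)
    if fs_out == fs_in:
        return x.copy()
    n_out = int(round(x.size * fs_out / fs_in))
    t_in = np.arange(x.size) / fs_in
    t_out = np.arange(n_out) / fs_out
    return np.interp(t_out, t_in, x)


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Affinely map a window onto [0, 1]; a constant window becomes all 0.5."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ShapeError("cannot normalize an empty window")
    lo, hi = x.min(), x.max()
    if hi == lo:
        logger.warning("constant window encountered; normalized to all-0.5")
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def assign_group(rr: float) -> str:
    """Breathing group of an RR value: slow < 12 <= normal <= 20 < rapid."""
    if rr < 0:
        raise ParameterError(f"rr must be >= 0, got {rr}")
    if rr < 12.0:
        return "slow"
    if rr <= 20.0:
        return "normal"
    return "rapid"


def count_windows(duration_s: float, length_s: float, shift_s: float) -> int:
    """Number of windows a record yields: floor((D − L)/S) + 1, 0 if too short."""
    if duration_s < length_s:
        return 0
    return int(np.floor((duration_s - length_s) / shift_s + 1e-9)) + 1


def slice_windows(
    record: PPGRecord,
    spec: WindowSpec = WindowSpec(),
    filt: FilterSpec = FilterSpec(),
    exclusion_hook: Optional[Callable[[PPGRecord, int, float, float], bool]] = None,
    dtype=np.float32,
) -> List[WindowSample]:
    """Run the full preprocessing chain on one record.

    ``exclusion_hook(record, window_index, start_s, rr) -> bool`` may drop
    individual windows (dataset-specific exclusion rules are not baked in).
    A record shorter than one window yields an empty list with a warning.
    """
    spec.validate(record.fs)
    n_win = count_windows(record.duration_s, spec.length_s, spec.shift_s)
    if n_win == 0:
        warnings.warn(
            f"{record.subject_id}: record shorter than one window; no samples",
            stacklevel=2,
        )
        return []
    coeffs = design_bandpass(filt, record.fs)
    filtered = apply_filter(record.ppg, coeffs)
    len_in = int(round(spec.length_s * record.fs))
    out: List[WindowSample] = []
    for i in range(n_win):
        start_s = i * spec.shift_s
        i0 = int(round(start_s * record.fs))
        seg = filtered[i0 : i0 + len_in]
        rr = rr_label_for_interval(record, start_s, start_s + spec.length_s)
        if exclusion_hook is not None and exclusion_hook(record, i, start_s, rr):
            continue
        seg = resample_linear(seg, record.fs, spec.target_fs)
        seg = minmax_normalize(seg)
        out.append(
            WindowSample(
                subject_id=record.subject_id,
                values=seg.astype(dtype),
                rr_true=float(rr),
                group=assign_group(rr),
                start_s=float(start_s),
                window_index=i,
            )
        )
    return out


def save_windows(windows: Sequence[WindowSample], out_dir) -> Path:
    """Persist a windowed dataset as values.npy + a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not windows:
        raise ValidationError("no windows to save")
    values = np.stack([w.values for w in windows])
    np.save(out / "values.npy", values)
    pd.DataFrame(
        {
            "subject_id": [w.subject_id for w in windows],
            "window_index": [w.window_index for w in windows],
            "start_s": [w.start_s for w in windows],
            "rr_true": [w.rr_true for w in windows],
            "group": [w.group for w in windows],
        }
    ).to_csv(out / "manifest.csv", index=False)
    return out


def load_windows(in_dir) -> List[WindowSample]:
    """Load a dataset written by :func:`save_windows`."""
    src = Path(in_dir)
    values = np.load(src / "values.npy")
    manifest = pd.read_csv(src / "manifest.csv")
    if len(manifest) != values.shape[0]:
        raise ValidationError("manifest rows and value rows disagree")
    return [
        WindowSample(
            subject_id=str(row.subject_id),
            values=values[i],
            rr_true=float(row.rr_true),
            group=str(row.group),
            start_s=float(row.start_s),
            window_index=int(row.window_index),
        )
        for i, row in enumerate(manifest.itertuples())
    ]


def normalize_labels_minmax(
    windows: Sequence[WindowSample],
) -> tuple[List[WindowSample], float, float]:
    """Min–max-scale RR labels across a dataset (experimental switch).

    Returns rescaled copies plus the (min, max) needed to undo the scaling.
    The default pipeline keeps labels in brpm; this helper exists to probe
    the alternative reading in which targets are normalized too.
    """
    rr = np.array([w.rr_true for w in windows], dtype=float)
    lo, hi = rr.min(), rr.max()
    span = hi - lo if hi > lo else 1.0
    scaled = [
        WindowSample(
            subject_id=w.subject_id,
            values=w.values,
            rr_true=float((w.rr_true - lo) / span),
            group=w.group,
            start_s=w.start_s,
            window_index=w.window_index,
        )
        for w in windows
    ]
    return scaled, float(lo), float(hi)
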