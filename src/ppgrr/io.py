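"""Readers and writers for the three record dialects.

* **BIDMC dialect** — per subject, a ``<id>_Signals.csv`` table (high-rate
  waveforms including a ``PLETH`` column at 125 Hz) plus a ``<id>_Numerics.csv``
  table (1 Hz numerics including a ``RESP`` rate column).
* **CapnoBase dialect** — a per-subject MAT container with a nested struct
  layout (``signal.pleth.y``, ``param.samplingrate.pleth``,
  ``labels.co2.startinsp.x``, ``meta.subject.age``).
* **Collector dialect** — a JSON document exported by a bedside respiratory
  counter: ``{id, demographics{gender, age, diagnosis}, fs, ppg[...],
  exhalations_s[...]}``. The counter runs slightly longer than its nominal
  2 minutes, so the reader truncates to the 120 s core.

A record whose reference RR is entirely missing is rejected at read time;
partially missing 1 Hz RR samples are linearly interpolated with a warning.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import loadmat, savemat

from .errors import ExclusionError, FormatError, ValidationError
from .records import BreathAnnotations, ExhalationMarks, PPGRecord, RRSeries

__all__ = [
    "read_bidmc_record",
    "write_bidmc_record",
    "read_capnobase_record",
    "write_capnobase_record",
    "read_collector_record",
    "write_collector_record",
]

COLLECTOR_CORE_S = 120.0


def _bidmc_paths(path) -> tuple[Path, Path, str]:
    p = Path(path)
    name = p.name
    if name.endswith("_Signals.csv"):
        stem = name[: -len("_Signals.csv")]
        base = p.parent
    elif name.endswith("_Numerics.csv"):
        stem = name[: -len("_Numerics.csv")]
        base = p.parent
    else:
        stem = name
        base = p.parent
    return base / f"{stem}_Signals.csv", base / f"{stem}_Numerics.csv", stem


def _read_csv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FormatError(f"missing file: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"empty table: {path}")
    df.columns = [c.strip() for c in df.columns]
    return df


def read_bidmc_record(path) -> PPGRecord:
    """Read one BIDMC-dialect subject (Signals + Numerics CSV pair).

    ``path`` may be the ``*_Signals.csv`` file, the ``*_Numerics.csv`` file,
    or the shared prefix. Raises :class:`FormatError` if the PLETH or RESP
    column is absent and :class:`ExclusionError` when the RESP column holds
    no finite value at all (such records are unusable as labeled data).
    """
    sig_path, num_path, subject_id = _bidmc_paths(path)
    sig = _read_csv(sig_path)
    num = _read_csv(num_path)
    if "PLETH" not in sig.columns:
        raise FormatError(f"{sig_path}: missing column 'PLETH'")
    if "RESP" not in num.columns:
        raise FormatError(f"{num_path}: missing column 'RESP'")
    tcol = "Time [s]"
    if tcol in sig.columns:
        t = sig[tcol].to_numpy(dtype=float)
        fs = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 125.0
        fs = float(round(fs))
    else:
        fs = 125.0
    ppg = sig["PLETH"].to_numpy(dtype=float)

    rr = num["RESP"].to_numpy(dtype=float)
    if num_path and tcol in num.columns:
        rr_t = num[tcol].to_numpy(dtype=float)
    else:
        rr_t = np.arange(rr.size, dtype=float)
    finite = np.isfinite(rr)
    if not finite.any():
        raise ExclusionError(
            f"{subject_id}: reference RR entirely missing; record excluded"
        )
    if not finite.all():
        warnings.warn(
            f"{subject_id}: {np.count_nonzero(~finite)} missing RR samples "
            "linearly interpolated",
            stacklevel=2,
        )
        rr = np.interp(rr_t, rr_t[finite], rr[finite])
    return PPGRecord(
        subject_id=subject_id,
        ppg=ppg,
        fs=fs,
        rr_reference=RRSeries(times_s=rr_t, rr_brpm=rr),
    )


def write_bidmc_record(record: PPGRecord, out_dir) -> tuple[Path, Path]:
    """Write a record as a BIDMC-dialect CSV pair. Requires an RRSeries reference."""
    if not isinstance(record.rr_reference, RRSeries):
        raise ValidationError("BIDMC dialect requires an RRSeries reference")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sig_path = out / f"{record.subject_id}_Signals.csv"
    num_path = out / f"{record.subject_id}_Numerics.csv"
    t = np.arange(record.ppg.size) / record.fs
    pd.DataFrame({"Time [s]": t, "PLETH": record.ppg}).to_csv(sig_path, index=False)
    ref = record.rr_reference
    pd.DataFrame({"Time [s]": ref.times_s, "RESP": ref.rr_brpm}).to_csv(
        num_path, index=False
    )
    return sig_path, num_path


def _mat_attr(obj, *names):
    cur = obj
    for n in names:
        if isinstance(cur, dict):
            if n not in cur:
                raise KeyError(n)
            cur = cur[n]
        else:
            if not hasattr(cur, n):
                raise KeyError(n)
            cur = getattr(cur, n)
    return cur


def read_capnobase_record(path) -> PPGRecord:
    """Read one CapnoBase-dialect MAT container.

    Expects the benchmark's nested struct layout. Breath onsets are taken
    from ``labels.co2.startinsp.x``; values larger than the recording
    duration are interpreted as sample indices at the CO2 rate
    (``param.samplingrate.co2``) and converted to seconds. The subject's
    age (``meta.subject.age``) populates demographics and an ``adult`` flag
    so callers can filter pediatric records.
    """
    p = Path(path)
    if not p.exists():
        raise FormatError(f"missing file: {p}")
    try:
        mat = loadmat(p, squeeze_me=True, struct_as_record=False)
    except Exception as exc:
        raise FormatError(f"cannot read MAT container {p}: {exc}") from exc
    try:
        ppg = np.asarray(_mat_attr(mat, "signal", "pleth", "y"), dtype=float).ravel()
        fs = float(np.asarray(_mat_attr(mat, "param", "samplingrate", "pleth")).ravel()[0])
    except KeyError as exc:
        raise FormatError(f"{p}: missing required field {exc}") from exc
    try:
        breaths = np.asarray(
            _mat_attr(mat, "labels", "co2", "startinsp", "x"), dtype=float
        ).ravel()
    except KeyError as exc:
        raise FormatError(f"{p}: missing breath labels ({exc})") from exc
    duration_s = ppg.size / fs
    if breaths.size and breaths.max() > duration_s:
        try:
            fs_co2 = float(
                np.asarray(_mat_attr(mat, "param", "samplingrate", "co2")).ravel()[0]
            )
        except KeyError as exc:
            raise FormatError(
                f"{p}: breath labels look like sample indices but co2 rate is absent"
            ) from exc
        breaths = breaths / fs_co2
    demographics = {}
    flags: tuple[str, ...] = ()
    try:
        age = float(np.asarray(_mat_attr(mat, "meta", "subject", "age")).ravel()[0])
        demographics["age"] = age
        demographics["adult"] = bool(age >= 18)
        flags = ("adult",) if age >= 18 else ("pediatric",)
    except KeyError:
        pass
    return PPGRecord(
        subject_id=p.stem,
        ppg=ppg,
        fs=fs,
        rr_reference=BreathAnnotations(breath_times_s=np.sort(breaths)),
        demographics=demographics or None,
        flags=flags,
    )


def write_capnobase_record(record: PPGRecord, path) -> Path:
    """Write a record in the CapnoBase-dialect nested MAT layout (synthetic fixtures)."""
    if not isinstance(record.rr_reference, BreathAnnotations):
        raise ValidationError("CapnoBase dialect requires a BreathAnnotations reference")
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    age = (record.demographics or {}).get("age", 50)
    savemat(
        p,
        {
            "signal": {"pleth": {"y": record.ppg}},
            "param": {"samplingrate": {"pleth": float(record.fs)}},
            "labels": {"co2": {"startinsp": {"x": record.rr_reference.breath_times_s}}},
            "meta": {"subject": {"age": float(age)}},
        },
    )
    return p


def read_collector_record(path) -> PPGRecord:
    """Read one exported collector JSON document.

    Missing demographics produce a warning, not an error; missing exhalation
    marks load as an empty reference with an ``unlabeled`` flag. Marks and
    PPG samples beyond the 120 s core are truncated (collection runs a few
    seconds long by design); marks outside the recording or non-increasing
    marks are validation errors.
    """
    p = Path(path)
    if not p.exists():
        raise FormatError(f"missing file: {p}")
    try:
        doc = json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"cannot parse collector JSON {p}: {exc}") from exc
    for key in ("id", "fs", "ppg"):
        if key not in doc:
            raise FormatError(f"{p}: missing field '{key}'")
    fs = float(doc["fs"])
    ppg = np.asarray(doc["ppg"], dtype=float)
    n_core = int(round(COLLECTOR_CORE_S * fs))
    if ppg.size < n_core:
        raise FormatError(
            f"{p}: PPG shorter than the {COLLECTOR_CORE_S:.0f} s core "
            f"({ppg.size} < {n_core} samples)"
        )
    ppg = ppg[:n_core]
    demographics = doc.get("demographics")
    if not demographics:
        warnings.warn(f"{doc['id']}: demographics missing", stacklevel=2)
        demographics = None
    marks = np.asarray(doc.get("exhalations_s", []), dtype=float)
    flags: tuple[str, ...] = ()
    if marks.size == 0:
        flags = ("unlabeled",)
    else:
        raw_duration = float(doc.get("duration_s", len(doc["ppg"]) / fs))
        if np.any(marks < 0) or np.any(marks > raw_duration):
            raise ValidationError(f"{doc['id']}: exhalation marks outside [0, duration]")
        if np.any(np.diff(marks) <= 0):
            raise ValidationError(f"{doc['id']}: exhalation marks not strictly increasing")
        marks = marks[marks < COLLECTOR_CORE_S]
    return PPGRecord(
        subject_id=str(doc["id"]),
        ppg=ppg,
        fs=fs,
        rr_reference=ExhalationMarks(times_s=marks),
        demographics=demographics,
        duration_s=COLLECTOR_CORE_S,
        flags=flags,
    )


def write_collector_record(record: PPGRecord, path) -> Path:
    """Write a record as a collector-dialect JSON document."""
    if not isinstance(record.rr_reference, ExhalationMarks):
        raise ValidationError("collector dialect requires an ExhalationMarks reference")
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "id": record.subject_id,
        "demographics": dict(record.demographics) if record.demographics else {},
        "fs": record.fs,
        "duration_s": record.duration_s,
        "ppg": record.ppg.tolist(),
        "exhalations_s": record.rr_reference.times_s.tolist(),
    }
    p.write_text(json.dumps(doc))
    return p
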