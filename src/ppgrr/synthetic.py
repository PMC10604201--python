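"""Respiratory-modulated synthetic PPG with known ground-truth RR.

Respiration leaves three fingerprints on a finger PPG, and the generator
reproduces all three around a cardiac pulse train:

* **baseline wander** — an additive low-frequency oscillation at the
  respiratory frequency (intrathoracic pressure coupling);
* **amplitude modulation** — a breath-synchronous envelope on the pulse
  amplitude (stroke-volume variation);
* **frequency modulation** — a breath-synchronous variation of the heart
  period (respiratory sinus arrhythmia).

The cardiac cycle is a fixed two-Gaussian systolic/diastolic template
evaluated on an (optionally frequency-modulated) phase ramp. The model is

``ppg(t) = (1 + a_am sin(2π f_r t)) · pulse(φ(t)) + a_bw sin(2π f_r t + ψ) + ε(t)``

with ``f_r = rr_brpm/60`` and ``φ'(t) = (hr_bpm/60)(1 + a_fm sin(2π f_r t))``.

Artifact injection adds a random multi-sinusoid wander calibrated exactly to
a target SNR, where SNR = 10·log10(P_signal/P_artifact) on mean-removed
signals — the convention :func:`measure_snr` verifies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ParameterError, SNRUndefinedError, ValidationError
from .records import PPGRecord, RRSeries

__all__ = [
    "SynthConfig",
    "SNRSpec",
    "generate_ppg",
    "pulse_template",
    "measure_snr",
    "inject_artifact_to_snr",
    "make_cohort",
    "GROUP_RR_RANGES",
]

# Per-group subject RR ranges (brpm) used when drawing cohorts.
GROUP_RR_RANGES = {
    "slow": (6.0, 11.5),
    "normal": (12.0, 20.0),
    "rapid": (20.5, 35.0),
}
HR_RANGE = (55.0, 110.0)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic recording.

    Modulation depths default to values in the range reported for real
    finger PPG: wander ~30% of pulse amplitude, AM ~20%, FM ~5% of the
    heart period, plus a small white sensor-noise floor.
    """

    duration_s: float = 480.0
    fs: float = 125.0
    hr_bpm: float = 75.0
    rr_brpm: float = 15.0
    bw_depth: float = 0.3
    am_depth: float = 0.2
    fm_depth: float = 0.05
    noise_sd: float = 0.01
    seed: int = 0
    subject_id: str = "synth-000"

    def validate(self) -> None:
        if not (self.hr_bpm > self.rr_brpm > 0):
            raise ParameterError("need hr_bpm > rr_brpm > 0")
        if min(self.bw_depth, self.am_depth, self.fm_depth, self.noise_sd) < 0:
            raise ParameterError("depths and noise_sd must be >= 0")
        if not (self.am_depth < 1 and self.fm_depth < 1):
            raise ParameterError("am_depth and fm_depth must be < 1")
        if self.fs < 4 * self.hr_bpm / 60:
            raise ParameterError("fs too low for the cardiac harmonic content")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be > 0")


@dataclass(frozen=True)
class SNRSpec:
    """Target for calibrated artifact injection."""

    target_db: float = 10.0
    artifact_band_hz: Tuple[float, float] = (0.05, 1.0)
    seed: int = 0
    n_components: int = 8

    def validate(self) -> None:
        lo, hi = self.artifact_band_hz
        if not lo < hi:
            raise ParameterError("artifact band must satisfy f_lo < f_hi")
        if np.isnan(self.target_db):
            raise ParameterError("target_db must not be NaN")


def pulse_template(phase: np.ndarray) -> np.ndarray:
    """Two-Gaussian cardiac-cycle template on phase in cycles (wraps mod 1)."""
    p = np.mod(phase, 1.0)
    systolic = np.exp(-0.5 * ((p - 0.30) / 0.09) ** 2)
    diastolic = 0.45 * np.exp(-0.5 * ((p - 0.62) / 0.12) ** 2)
    return systolic + diastolic


def generate_ppg(cfg: SynthConfig) -> PPGRecord:
    """Generate one respiratory-modulated PPG record.

    The reference is a 1 Hz :class:`RRSeries` constant at ``rr_brpm``, so
    every 60 s window cut from this record is labeled exactly ``rr_brpm``.
    Reproducible under a fixed seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    f_r = cfg.rr_brpm / 60.0
    f_h = cfg.hr_bpm / 60.0
    # closed-form integral of the FM-modulated instantaneous rate
    phase = f_h * (t + cfg.fm_depth * (1.0 - np.cos(2 * np.pi * f_r * t)) / (2 * np.pi * f_r))
    psi = rng.uniform(0, 2 * np.pi)
    ppg = (1.0 + cfg.am_depth * np.sin(2 * np.pi * f_r * t)) * pulse_template(phase)
    ppg += cfg.bw_depth * np.sin(2 * np.pi * f_r * t + psi)
    if cfg.noise_sd > 0:
        ppg += rng.normal(0.0, cfg.noise_sd, size=n)
    ref_t = np.arange(int(np.floor(cfg.duration_s)), dtype=float)
    reference = RRSeries(times_s=ref_t, rr_brpm=np.full(ref_t.size, cfg.rr_brpm))
    return PPGRecord(
        subject_id=cfg.subject_id,
        ppg=ppg,
        fs=cfg.fs,
        rr_reference=reference,
        demographics={"hr_bpm": cfg.hr_bpm, "rr_brpm": cfg.rr_brpm},
    )


def measure_snr(clean: np.ndarray, noisy: np.ndarray) -> float:
    """SNR in dB: 10·log10(P_clean / P_(noisy−clean)) on mean-removed signals."""
    c = np.asarray(clean, dtype=float)
    y = np.asarray(noisy, dtype=float)
    if c.shape != y.shape:
        raise ValidationError(f"length mismatch: {c.shape} vs {y.shape}")
    c0 = c - c.mean()
    p_c = float(np.mean(c0**2))
    if p_c == 0.0:
        raise SNRUndefinedError("clean signal has zero power; SNR undefined")
    d = y - c
    d0 = d - d.mean()
    p_d = float(np.mean(d0**2))
    if p_d == 0.0:
        return float("inf")
    return 10.0 * np.log10(p_c / p_d)


def inject_artifact_to_snr(record: PPGRecord, spec: SNRSpec) -> PPGRecord:
    """Add a random multi-sinusoid baseline wander scaled exactly to a target SNR.

    Component frequencies are drawn uniformly from the artifact band (default
    0.05–1 Hz, overlapping the respiratory band so the robustness protocol is
    a real stressor). ``target_db = +inf`` is an exact no-op.
    """
    spec.validate()
    if np.isposinf(spec.target_db):
        return record
    rng = np.random.default_rng(spec.seed)
    n = record.ppg.size
    t = np.arange(n) / record.fs
    freqs = rng.uniform(*spec.artifact_band_hz, size=spec.n_components)
    phases = rng.uniform(0, 2 * np.pi, size=spec.n_components)
    amps = rng.uniform(0.5, 1.0, size=spec.n_components)
    w = np.zeros(n)
    for f, ph, a in zip(freqs, phases, amps):
        w += a * np.sin(2 * np.pi * f * t + ph)
    c0 = record.ppg - record.ppg.mean()
    p_c = float(np.mean(c0**2))
    if p_c == 0.0:
        raise SNRUndefinedError("record has zero signal power; SNR undefined")
    w0 = w - w.mean()
    p_w = float(np.mean(w0**2))
    scale = np.sqrt(p_c / (p_w * 10.0 ** (spec.target_db / 10.0)))
    noisy = record.ppg + scale * w0
    return PPGRecord(
        subject_id=record.subject_id,
        ppg=noisy,
        fs=record.fs,
        rr_reference=record.rr_reference,
        demographics=record.demographics,
        duration_s=record.duration_s,
        flags=record.flags + (f"snr_{spec.target_db:g}db",),
    )


def make_cohort(
    n_subjects: int,
    group_mix: Sequence[float] = (0.2, 0.5, 0.3),
    duration_s: float = 480.0,
    fs: float = 125.0,
    seed: int = 0,
    base: Optional[SynthConfig] = None,
) -> List[PPGRecord]:
    """Draw a cohort of synthetic subjects with per-group RR distributions.

    ``group_mix`` gives (slow, normal, rapid) proportions; subject counts use
    largest-remainder rounding so the composition is deterministic, and all
    draws come from one seeded generator. Heart rates are uniform on
    55–110 bpm; modulation depths jitter mildly around the ``base`` config.
    """
    if n_subjects <= 0:
        raise ParameterError("n_subjects must be > 0")
    mix = np.asarray(group_mix, dtype=float)
    if mix.size != 3 or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
        raise ParameterError("group_mix must be three proportions summing to 1")
    base = base or SynthConfig(duration_s=duration_s, fs=fs)
    # largest-remainder apportionment of subjects to groups
    raw = mix * n_subjects
    counts = np.floor(raw).astype(int)
    remainder = n_subjects - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(remainder):
        counts[order[i]] += 1
    rng = np.random.default_rng(seed)
    records: List[PPGRecord] = []
    idx = 0
    for group, count in zip(("slow", "normal", "rapid"), counts):
        lo, hi = GROUP_RR_RANGES[group]
        for _ in range(count):
            rr = rng.uniform(lo, hi)
            hr = rng.uniform(*HR_RANGE)
            cfg = replace(
                base,
                duration_s=duration_s,
                fs=fs,
                hr_bpm=float(hr),
                rr_brpm=float(rr),
                bw_depth=float(base.bw_depth * rng.uniform(0.7, 1.3)),
                am_depth=float(min(0.95, base.am_depth * rng.uniform(0.7, 1.3))),
                fm_depth=float(min(0.95, base.fm_depth * rng.uniform(0.7, 1.3))),
                seed=int(rng.integers(0, 2**31 - 1)),
                subject_id=f"synth-{idx:03d}",
            )
            records.append(generate_ppg(cfg))
            idx += 1
    return records
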