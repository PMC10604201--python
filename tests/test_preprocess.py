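"""Filter, resampling, normalization, grouping and windowing contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from ppgrr.errors import DesignError, ParameterError, ShapeError
from ppgrr.preprocess import (
    FilterSpec,
    WindowSpec,
    apply_filter,
    assign_group,
    count_windows,
    design_bandpass,
    load_windows,
    minmax_normalize,
    resample_linear,
    save_windows,
    slice_windows,
)
from ppgrr.records import PPGRecord, RRSeries


def gain_db(coeffs, freq, fs=125.0):
    w, h = sps.freqz(coeffs, worN=8192, fs=fs)
    return 20 * np.log10(np.abs(h[np.argmin(np.abs(w - freq))]))


def sinusoid_amplitude(x, freq, fs):
    """Least-squares fit of a sinusoid at a known frequency; returns amplitude."""
    t = np.arange(x.size) / fs
    A = np.column_stack([np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t)])
    coef, *_ = np.linalg.lstsq(A, x, rcond=None)
    return float(np.hypot(*coef))


class TestFilterDesign:
    def test_respiratory_band_within_3db(self):
        b = design_bandpass(FilterSpec(), 125.0)
        assert gain_db(b, 0.25) >= -3.0
        assert gain_db(b, 0.25) <= 0.5
        for f in (0.15, 0.35):
            assert gain_db(b, f) >= -3.0

    def test_cardiac_band_attenuated_20db(self):
        b = design_bandpass(FilterSpec(), 125.0)
        for f in (1.0, 1.5, 2.0):
            assert gain_db(b, f) <= -20.0

    def test_inverted_band_rejected(self):
        with pytest.raises(DesignError):
            design_bandpass(FilterSpec(low_hz=0.5, high_hz=0.4), 125.0)

    def test_too_few_taps_suggests_more(self):
        with pytest.raises(DesignError, match="taps"):
            design_bandpass(FilterSpec(taps=51), 125.0)


class TestApplyFilter:
    def test_respiratory_sinusoid_survives(self):
        fs = 125.0
        t = np.arange(int(120 * fs)) / fs
        x = np.sin(2 * np.pi * 0.25 * t)
        y = apply_filter(x, design_bandpass(FilterSpec(), fs))
        assert y.size == x.size
        core = slice(int(20 * fs), int(100 * fs))  # avoid edge transients
        ratio = sinusoid_amplitude(y[core], 0.25, fs)
        assert 0.9 <= ratio <= 1.1

    def test_cardiac_sinusoid_attenuated_tenfold(self):
        fs = 125.0
        t = np.arange(int(120 * fs)) / fs
        x = np.sin(2 * np.pi * 1.5 * t)
        y = apply_filter(x, design_bandpass(FilterSpec(), fs))
        assert sinusoid_amplitude(y, 1.5, fs) <= 0.1

    def test_zero_in_zero_out(self):
        b = design_bandpass(FilterSpec(), 125.0)
        y = apply_filter(np.zeros(10000), b)
        np.testing.assert_array_equal(y, 0.0)

    def test_short_signal_rejected(self):
        b = design_bandpass(FilterSpec(), 125.0)
        with pytest.raises(ShapeError):
            apply_filter(np.zeros(100), b)


class TestResample:
    def test_7500_at_125_gives_1800_at_30(self):
        assert resample_linear(np.zeros(7500), 125, 30).size == 1800

    def test_identity_at_equal_rates(self):
        x = np.random.default_rng(0).random(500)
        np.testing.assert_array_equal(resample_linear(x, 30, 30), x)

    def test_exact_on_affine_signals(self):
        x = 3.0 * np.arange(1250) / 125.0 + 1.0
        y = resample_linear(x, 125, 25)
        t_out = np.arange(y.size) / 25.0
        np.testing.assert_allclose(y, 3.0 * t_out + 1.0, rtol=1e-12)

    def test_bad_rate_rejected(self):
        with pytest.raises(ParameterError):
            resample_linear(np.zeros(10), 125, 0)
        with pytest.raises(ParameterError):
            resample_linear(np.zeros(10), 30, 125)


class TestNormalize:
    def test_closed_form(self):
        np.testing.assert_allclose(minmax_normalize([2, 4, 6]), [0, 0.5, 1])

    def test_idempotent_on_unit_ramp(self):
        x = np.linspace(0, 1, 11)
        np.testing.assert_allclose(minmax_normalize(x), x)

    def test_constant_window_becomes_half(self):
        np.testing.assert_array_equal(minmax_normalize([5.0, 5.0, 5.0]), 0.5)


class TestGroups:
    @pytest.mark.parametrize(
        "rr,expected",
        [(11.9, "slow"), (12.0, "normal"), (15.0, "normal"), (20.0, "normal"),
         (20.1, "rapid"), (0.0, "slow"), (35.0, "rapid")],
    )
    def test_boundaries_inclusive_for_normal(self, rr, expected):
        assert assign_group(rr) == expected

    def test_negative_rr_rejected(self):
        with pytest.raises(ParameterError):
            assign_group(-1.0)


class TestWindowing:
    def test_eight_minutes_yield_421_windows(self, constant_rr_record):
        wins = slice_windows(constant_rr_record)
        assert len(wins) == 421  # (480 - 60)/1 + 1
        assert all(w.values.size == 1800 for w in wins)
        assert all(w.rr_true == 17.0 for w in wins)
        assert all(w.group == "normal" for w in wins)

    def test_values_in_unit_interval_and_group_consistent(self, short_record):
        from ppgrr.preprocess import assign_group as grp

        wins = slice_windows(short_record)
        for w in wins:
            assert w.values.min() >= 0.0 and w.values.max() <= 1.0
            assert w.group == grp(w.rr_true)

    def test_pipeline_deterministic(self, short_record):
        a = slice_windows(short_record)
        b = slice_windows(short_record)
        for wa, wb in zip(a, b):
            np.testing.assert_array_equal(wa.values, wb.values)
            assert wa.rr_true == wb.rr_true

    def test_too_short_record_warns_and_returns_empty(self):
        rec = PPGRecord(
            subject_id="tiny",
            ppg=np.zeros(125 * 30),
            fs=125.0,
            rr_reference=RRSeries(np.arange(30.0), np.full(30, 15.0)),
        )
        with pytest.warns(UserWarning, match="shorter"):
            assert slice_windows(rec) == []

    def test_exclusion_hook_drops_windows(self, constant_rr_record):
        wins = slice_windows(
            constant_rr_record,
            exclusion_hook=lambda rec, i, start, rr: i % 2 == 1,
        )
        assert len(wins) == 211

    def test_filter_once_equals_per_record_prefilter(self, short_record):
        """Slicing a pre-filtered record gives the same windows (filter applied
        once per record, before slicing)."""
        from ppgrr.preprocess import FilterSpec, design_bandpass

        b = design_bandpass(FilterSpec(), short_record.fs)
        pre = apply_filter(short_record.ppg, b)
        wins = slice_windows(short_record)
        spec = WindowSpec()
        for i in (0, 30, 60):
            seg = pre[int(i * 125) : int(i * 125) + 7500]
            manual = minmax_normalize(resample_linear(seg, 125, 30))
            np.testing.assert_allclose(wins[i].values, manual, atol=1e-6)

    def test_save_load_round_trip(self, tmp_path, short_record):
        wins = slice_windows(short_record)
        save_windows(wins, tmp_path / "ds")
        back = load_windows(tmp_path / "ds")
        assert len(back) == len(wins)
        np.testing.assert_array_equal(back[3].values, wins[3].values)
        assert back[3].rr_true == wins[3].rr_true
        assert back[3].subject_id == wins[3].subject_id


@settings(max_examples=100, deadline=None)
@given(
    duration=st.integers(60, 700),
    length=st.integers(10, 120),
    shift=st.integers(1, 30),
)
def test_window_count_formula_matches_enumeration(duration, length, shift):
    """The closed-form window count equals brute-force enumeration."""
    if duration < length:
        duration, length = length, duration
    starts = []
    s = 0
    while s + length <= duration:
        starts.append(s)
        s += shift
    assert count_windows(duration, length, shift) == len(starts)
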