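"""Generator physics, SNR calibration, and cohort determinism."""

import numpy as np
import pytest

from ppgrr.errors import ParameterError, SNRUndefinedError, ValidationError
from ppgrr.preprocess import FilterSpec, apply_filter, design_bandpass, slice_windows
from ppgrr.synthetic import (
    SNRSpec,
    SynthConfig,
    generate_ppg,
    inject_artifact_to_snr,
    make_cohort,
    measure_snr,
)


def bandpassed_peak_hz(ppg, fs):
    b = design_bandpass(FilterSpec(), fs)
    y = apply_filter(ppg, b)
    f = np.fft.rfftfreq(y.size, 1 / fs)
    P = np.abs(np.fft.rfft(y - y.mean())) ** 2
    return f[P.argmax()], f[1] - f[0]


class TestGenerator:
    def test_sample_count_is_duration_times_fs(self):
        rec = generate_ppg(SynthConfig(duration_s=480, fs=125, seed=0))
        assert rec.ppg.size == 60000

    def test_unmodulated_signal_is_strictly_periodic(self):
        cfg = SynthConfig(duration_s=60, fs=125, hr_bpm=75, bw_depth=0,
                          am_depth=0, fm_depth=0, noise_sd=0, seed=0)
        rec = generate_ppg(cfg)
        period = int(round(125 * 60 / 75))  # 100 samples per beat
        n = (rec.ppg.size // period) * period
        x = rec.ppg[:n].reshape(-1, period)
        np.testing.assert_allclose(x, np.broadcast_to(x[0], x.shape), atol=1e-9)

    def test_respiratory_peak_at_configured_rate(self):
        cfg = SynthConfig(duration_s=240, fs=125, rr_brpm=15, seed=2)
        peak, df = bandpassed_peak_hz(generate_ppg(cfg).ppg, 125)
        assert abs(peak - 0.25) <= df  # within one FFT bin

    @pytest.mark.parametrize("depths", [
        {"bw_depth": 0.3, "am_depth": 0.0, "fm_depth": 0.0},
        {"bw_depth": 0.0, "am_depth": 0.3, "fm_depth": 0.0},
    ], ids=["baseline_wander_only", "amplitude_modulation_only"])
    def test_additive_mechanisms_place_peak_at_rr(self, depths):
        cfg = SynthConfig(duration_s=240, fs=125, rr_brpm=18, noise_sd=0.0,
                          seed=3, **depths)
        peak, df = bandpassed_peak_hz(generate_ppg(cfg).ppg, 125)
        assert abs(peak - 0.30) <= df

    def test_frequency_modulation_carries_rr_in_heart_period(self):
        """FM leaves the respiratory band empty; its RR signature lives in the
        instantaneous heart period, recovered here by demodulating beat peaks."""
        cfg = SynthConfig(duration_s=240, fs=125, hr_bpm=75, rr_brpm=12,
                          bw_depth=0.0, am_depth=0.0, fm_depth=0.1,
                          noise_sd=0.0, seed=4)
        rec = generate_ppg(cfg)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(rec.ppg, distance=int(125 * 60 / 75 * 0.6))
        t_peaks = peaks[:-1] / 125.0
        periods = np.diff(peaks) / 125.0
        # uniform resample of the beat-period series, then periodogram
        t_grid = np.arange(t_peaks[0], t_peaks[-1], 0.25)
        p_grid = np.interp(t_grid, t_peaks, periods)
        p_grid -= p_grid.mean()
        f = np.fft.rfftfreq(p_grid.size, 0.25)
        P = np.abs(np.fft.rfft(p_grid)) ** 2
        band = (f > 0.05) & (f < 0.7)
        assert abs(f[band][P[band].argmax()] - 0.20) < 0.03

    def test_reference_is_constant_at_rr(self):
        rec = generate_ppg(SynthConfig(duration_s=120, rr_brpm=22.5, seed=5))
        np.testing.assert_array_equal(rec.rr_reference.rr_brpm, 22.5)

    def test_seed_reproducibility(self):
        a = generate_ppg(SynthConfig(seed=9, duration_s=60))
        b = generate_ppg(SynthConfig(seed=9, duration_s=60))
        np.testing.assert_array_equal(a.ppg, b.ppg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            SynthConfig(hr_bpm=10, rr_brpm=15).validate()


class TestSNR:
    def test_equal_power_is_zero_db(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10000)
        assert measure_snr(x, x + x) == pytest.approx(0.0)

    def test_tenfold_power_ratio_is_10db(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10000)
        noise = x / np.sqrt(10)
        assert measure_snr(x, x + noise) == pytest.approx(10.0)

    def test_identical_inputs_give_infinite_snr(self):
        x = np.arange(100.0)
        assert measure_snr(x, x) == np.inf

    def test_zero_power_clean_is_undefined(self):
        with pytest.raises(SNRUndefinedError):
            measure_snr(np.zeros(100), np.ones(100))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            measure_snr(np.zeros(10), np.zeros(11))

    @pytest.mark.parametrize("target", [20.0, 15.0, 10.0])
    def test_injection_round_trip_within_tenth_db(self, target, short_record):
        for seed in range(25):
            noisy = inject_artifact_to_snr(short_record, SNRSpec(target, seed=seed))
            assert measure_snr(short_record.ppg, noisy.ppg) == pytest.approx(target, abs=0.1)

    def test_infinite_target_is_exact_noop(self, short_record):
        out = inject_artifact_to_snr(short_record, SNRSpec(np.inf, seed=0))
        assert out is short_record

    def test_different_seeds_different_artifacts_same_snr(self, short_record):
        a = inject_artifact_to_snr(short_record, SNRSpec(15.0, seed=1))
        b = inject_artifact_to_snr(short_record, SNRSpec(15.0, seed=2))
        assert not np.array_equal(a.ppg, b.ppg)
        assert measure_snr(short_record.ppg, a.ppg) == pytest.approx(
            measure_snr(short_record.ppg, b.ppg), abs=0.2
        )

    def test_zero_power_record_rejected(self):
        from ppgrr.records import PPGRecord, RRSeries

        rec = PPGRecord("z", np.zeros(1250), 125.0,
                        RRSeries(np.arange(10.0), np.full(10, 15.0)))
        with pytest.raises(SNRUndefinedError):
            inject_artifact_to_snr(rec, SNRSpec(10.0))


class TestCohort:
    def test_group_mix_respected_exactly(self):
        recs = make_cohort(10, (0.2, 0.5, 0.3), duration_s=64, seed=0)
        rrs = [r.demographics["rr_brpm"] for r in recs]
        assert len(recs) == 10
        assert sum(rr < 12 for rr in rrs) == 2
        assert sum(12 <= rr <= 20 for rr in rrs) == 5
        assert sum(rr > 20 for rr in rrs) == 3

    def test_all_normal_mix_bounds_labels(self):
        recs = make_cohort(6, (0, 1, 0), duration_s=64, seed=1)
        for r in recs:
            assert 12 <= r.demographics["rr_brpm"] <= 20

    def test_same_seed_identical_cohorts(self):
        a = make_cohort(4, (0.25, 0.5, 0.25), duration_s=64, seed=3)
        b = make_cohort(4, (0.25, 0.5, 0.25), duration_s=64, seed=3)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.ppg, rb.ppg)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            make_cohort(0, (0.2, 0.5, 0.3))
        with pytest.raises(ParameterError):
            make_cohort(5, (0.5, 0.5, 0.5))

    def test_windowed_cohort_labels_equal_configured_rr(self):
        recs = make_cohort(3, (0, 1, 0), duration_s=90, seed=4)
        for rec in recs:
            wins = slice_windows(rec)
            for w in wins:
                assert w.rr_true == pytest.approx(rec.demographics["rr_brpm"])
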