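import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wearvalid.cardio import (
    BeatSeries,
    QualityGate,
    QualityWindow,
    bandpass_cardiac,
    cva_parameters,
    detect_beats,
    filter_intervals,
    gate_block,
    sqi_windows,
)
from wearvalid.core import Channel, TimeSeries
from wearvalid.synth import ecg_waveform, ppg_waveform


def brute_force_rmssd(intervals):
    """Independent evaluation of the printed formula."""
    iv = np.asarray(intervals, float)
    n = len(iv)
    acc = 0.0
    for i in range(n - 1):
        acc += (iv[i + 1] - iv[i]) ** 2
    return (acc / (n - 1)) ** 0.5


class TestBandpass:
    def test_inband_tone_passes(self):
        t = np.arange(20 * 200) / 200.0
        x = TimeSeries(0, 200.0, np.sin(2 * np.pi * 10 * t), channel=Channel.ECG)
        y = bandpass_cardiac(x)
        assert np.max(np.abs(y.values[400:-400])) > 0.7

    def test_slow_drift_attenuated(self):
        t = np.arange(20 * 200) / 200.0
        x = TimeSeries(0, 200.0, np.sin(2 * np.pi * 0.5 * t), channel=Channel.ECG)
        y = bandpass_cardiac(x)
        assert np.max(np.abs(y.values[400:-400])) < 0.1

    def test_zero_in_zero_out(self):
        x = TimeSeries(0, 200.0, np.zeros(1000), channel=Channel.ECG)
        np.testing.assert_allclose(bandpass_cardiac(x).values, 0.0, atol=1e-12)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            bandpass_cardiac(TimeSeries(0, 20.0, np.zeros(100)))


class TestBeatDetection:
    def test_one_hz_impulse_train_count(self):
        beats = np.arange(0.5, 60.0, 1.0)
        x = bandpass_cardiac(ecg_waveform(beats, fs=200.0, duration=61.0))
        found = detect_beats(x)
        assert abs(found.n_beats - 60) <= 1

    def test_flat_line_no_beats(self):
        x = TimeSeries(0, 200.0, np.zeros(2000), channel=Channel.ECG)
        assert detect_beats(x).n_beats == 0

    def test_ppg_75_bpm_mean_interval(self):
        from wearvalid.cardio import PPG_BAND

        beats = np.arange(0.5, 60.0, 0.8)
        x = bandpass_cardiac(
            ppg_waveform(beats, fs=200.0, duration=61.0), *PPG_BAND
        )
        found = detect_beats(x)
        iv = np.diff(found.peak_times)
        assert abs(iv.mean() - 0.8) < 0.01


class TestIntervalFilter:
    def test_out_of_range_deleted(self):
        b = BeatSeries(
            np.array([0.0, 0.2, 1.0, 2.6, 3.6]), source=Channel.ECG
        )
        # intervals 0.2, 0.8, 1.6, 1.0
        f = filter_intervals(b)
        np.testing.assert_allclose(f.intervals, [0.8, 1.0])
        assert f.n_removed == 2

    def test_boundary_values_retained(self):
        b = BeatSeries(
            np.array([0.0, 0.33, 1.83]), source=Channel.ECG
        )
        f = filter_intervals(b)
        np.testing.assert_allclose(f.intervals, [0.33, 1.5])

    @given(
        st.lists(
            st.floats(min_value=0.05, max_value=3.0), min_size=2, max_size=40
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_idempotent_and_invariant(self, gaps):
        b = BeatSeries(np.cumsum(np.asarray(gaps)) + 0.0, source=Channel.PPG)
        once = filter_intervals(b)
        twice = filter_intervals(once)
        assert ((once.intervals >= 0.33) & (once.intervals <= 1.5)).all()
        np.testing.assert_array_equal(once.intervals, twice.intervals)


class TestCVAParams:
    def test_constant_intervals(self):
        b = BeatSeries(np.arange(0, 40, 0.8), source=Channel.ECG)
        p = cva_parameters(b)
        assert p.mean_hr == pytest.approx(75.0)
        assert p.sd_interval == pytest.approx(0.0)
        assert p.rmssd == pytest.approx(0.0)

    def test_two_intervals_single_difference(self):
        b = BeatSeries(np.array([0.0, 0.8, 1.7]), source=Channel.ECG)
        p = cva_parameters(b)
        assert p.rmssd == pytest.approx(0.1)

    def test_rmssd_matches_brute_force(self, rng):
        iv = rng.uniform(0.5, 1.2, size=1000)
        peaks = np.concatenate([[0.0], np.cumsum(iv)])
        p = cva_parameters(BeatSeries(peaks, source=Channel.ECG))
        assert p.rmssd == pytest.approx(brute_force_rmssd(iv), abs=1e-12)

    def test_insufficient_intervals_not_available(self):
        p = cva_parameters(BeatSeries(np.array([0.0, 0.8]), source=Channel.ECG),
                           window=(10.0, 20.0))
        assert p.mean_hr is None and p.rmssd is None

    @given(shift=st.floats(-100, 100), scale=st.floats(0.5, 1.6))
    @settings(max_examples=25, deadline=None)
    def test_translation_and_scale_behavior(self, shift, scale):
        rng = np.random.default_rng(3)
        iv = rng.uniform(0.5, 1.0, size=50)
        base = BeatSeries(np.concatenate([[0.0], np.cumsum(iv)]),
                          source=Channel.ECG)
        moved = BeatSeries(base.peak_times + shift, source=Channel.ECG)
        p0, p1 = cva_parameters(base), cva_parameters(moved)
        assert p1.sd_interval == pytest.approx(p0.sd_interval, rel=1e-9)
        assert p1.rmssd == pytest.approx(p0.rmssd, rel=1e-9)
        scaled = BeatSeries(base.peak_times[0] + scale * (
            base.peak_times - base.peak_times[0]), source=Channel.ECG)
        p2 = cva_parameters(scaled)
        assert p2.sd_interval == pytest.approx(scale * p0.sd_interval, rel=1e-9)
        assert p2.rmssd == pytest.approx(scale * p0.rmssd, rel=1e-9)


class TestSQI:
    def test_clean_ppg_high_quality(self):
        beats = np.arange(0.5, 60.0, 0.8)
        x = ppg_waveform(beats, fs=64.0, duration=60.0)
        b = BeatSeries(beats, source=Channel.PPG)
        windows = sqi_windows(x, b)
        assert all(w.sqi > 90 for w in windows)

    def test_white_noise_low_quality(self, rng):
        x = TimeSeries(0, 64.0, rng.normal(size=60 * 64), channel=Channel.PPG)
        from wearvalid.cardio import detect_beats as _db

        b = detect_beats(bandpass_cardiac(x))
        windows = sqi_windows(x, b, span=(0.0, 60.0))
        assert np.mean([w.sqi for w in windows]) < 30

    def test_two_beats_scores_zero(self):
        b = BeatSeries(np.array([1.0, 2.0]), source=Channel.PPG)
        windows = sqi_windows(None, b, window_len=10.0, span=(0.0, 10.0))
        assert windows[0].sqi == 0.0

    def test_beat_only_dropout_gap_scores_zero(self):
        beats = np.concatenate([np.arange(0.5, 3.0, 0.8), np.arange(8.0, 10.0, 0.8)])
        b = BeatSeries(beats, source=Channel.PPG)
        windows = sqi_windows(None, b, window_len=10.0, span=(0.0, 10.0))
        assert windows[0].sqi == 0.0


class TestGating:
    def _windows(self, sqis, wlen=5.0):
        return [
            QualityWindow(i * wlen, (i + 1) * wlen, s) for i, s in enumerate(sqis)
        ]

    def test_all_good_full_coverage(self):
        w = self._windows([90] * 7)
        ok, cov = gate_block(w, (0.0, 35.0), QualityGate())
        assert ok and cov == pytest.approx(1.0)

    def test_alternating_good_bad_rejected(self):
        w = self._windows([90, 0, 90, 0, 90, 0, 90])
        ok, cov = gate_block(w, (0.0, 35.0), QualityGate())
        assert not ok
        assert cov == pytest.approx(5.0 / 35.0)

    def test_event_windows_need_higher_quality(self):
        w = self._windows([75, 75])
        ok_long, _ = gate_block(w, (0.0, 10.0), QualityGate(), event=False)
        ok_event, _ = gate_block(w, (0.0, 10.0), QualityGate(), event=True)
        assert ok_long and not ok_event

    def test_lowering_thresholds_never_rejects_an_accepted_block(self, rng):
        for _ in range(20):
            sqis = rng.uniform(0, 100, size=8)
            w = self._windows(list(sqis))
            strict = QualityGate(sqi_long=80, sqi_event=90)
            loose = QualityGate(sqi_long=60, sqi_event=70)
            a_strict, _ = gate_block(w, (0.0, 40.0), strict)
            a_loose, _ = gate_block(w, (0.0, 40.0), loose)
            if a_strict:
                assert a_loose
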