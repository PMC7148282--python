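import numpy as np
import pytest

from wearvalid.core import Channel, TimeSeries
from wearvalid.eda import (
    SCREvent,
    detect_scrs_ttp,
    eda_parameters,
    flag_nonresponder,
    smooth_eda,
)


def eda_series(values, fs=16.0):
    return TimeSeries(0.0, fs, np.asarray(values, float), "uS", Channel.EDA)


class TestSmoothing:
    def test_constant_preserved(self):
        x = eda_series(np.full(960, 2.0))
        y = smooth_eda(x)
        np.testing.assert_allclose(y.values, 2.0, atol=1e-6)

    def test_5hz_attenuated_beyond_90pct(self):
        t = np.arange(960) / 16.0
        y = smooth_eda(eda_series(np.sin(2 * np.pi * 5 * t)))
        gain = np.max(np.abs(y.values[100:-100]))
        assert gain < 0.1

    def test_passband_near_unity_at_low_frequency(self):
        t = np.arange(960) / 16.0
        y = smooth_eda(eda_series(2 + 0.5 * np.sin(2 * np.pi * 0.1 * t)))
        amp = (y.values[100:-100].max() - y.values[100:-100].min()) / 2
        assert amp > 0.45

    def test_step_has_no_overshoot(self):
        v = np.concatenate([np.zeros(200), np.ones(200)])
        y = smooth_eda(eda_series(v))
        assert y.values.max() <= 1.0 + 0.05
        assert y.values.min() >= -0.05
        # Gaussian smoothing is monotone on a step
        d = np.diff(y.values[5:-5])
        assert (d >= -1e-12).all()

    def test_rate_too_low_rejected(self):
        with pytest.raises(ValueError):
            smooth_eda(eda_series(np.zeros(10), fs=1.0))


class TestTTPDetection:
    def test_flat_signal_no_events(self):
        x = smooth_eda(eda_series(np.full(960, 2.0)))
        assert detect_scrs_ttp(x) == []

    def test_amplitude_threshold_separates_bumps(self, make_bump):
        t = np.arange(90 * 16) / 16.0
        v = 2.0 + np.zeros_like(t)
        amps = {20.0: 0.5, 45.0: 0.05, 70.0: 0.005}
        for c, a in amps.items():
            v += make_bump(t, c, 4.0, a)
        # oracle: direct trough-to-peak differencing on the raw construction
        for c, a in amps.items():
            seg = v[int((c - 3) * 16) : int((c + 3) * 16)]
            assert abs((seg.max() - seg.min()) - a) < 1e-9
        events = detect_scrs_ttp(eda_series(v))
        assert len(events) == 2
        assert all(e.amplitude >= 0.01 for e in events)

    def test_single_bump_amplitude_recovered(self, make_bump):
        t = np.arange(60 * 16) / 16.0
        v = 2.0 + make_bump(t, 30.0, 4.0, 0.5)
        events = detect_scrs_ttp(eda_series(v))
        assert len(events) == 1
        assert abs(events[0].amplitude - 0.5) < 0.02
        assert events[0].onset < events[0].peak

    def test_detection_invariant_to_constant_offset(self, make_bump):
        t = np.arange(60 * 16) / 16.0
        v = make_bump(t, 30.0, 4.0, 0.3)
        e0 = detect_scrs_ttp(eda_series(2.0 + v))
        e5 = detect_scrs_ttp(eda_series(7.0 + v))
        assert [(e.onset, e.peak) for e in e0] == [(e.onset, e.peak) for e in e5]
        np.testing.assert_allclose(
            [e.amplitude for e in e0], [e.amplitude for e in e5], atol=1e-9
        )

    def test_recall_on_injected_bumps(self, make_bump):
        """Every injected bump >= 2x threshold found; none below threshold."""
        t = np.arange(300 * 16) / 16.0
        rng = np.random.default_rng(5)
        centers = np.arange(10.0, 291.0, 14.0)
        big = centers[::2]
        tiny = centers[1::2]
        v = 2.0 + np.zeros_like(t)
        for c in big:
            v += make_bump(t, c, 4.0, 0.02 + rng.uniform(0, 0.3))
        for c in tiny:
            v += make_bump(t, c, 4.0, 0.004)
        events = detect_scrs_ttp(smooth_eda(eda_series(v)))
        onsets = np.array([e.peak for e in events])
        for c in big:
            assert np.any(np.abs(onsets - c) < 2.0), f"missed bump at {c}"
        for c in tiny:
            assert not np.any(np.abs(onsets - c) < 2.0), f"false hit at {c}"

    def test_onset_tracks_response_under_rising_drift(self, make_bump):
        """A slow rising tonic must not drag the trough away from the rise."""
        t = np.arange(60 * 16) / 16.0
        v = 2.0 + 0.01 * t + make_bump(t, 30.0, 4.0, 0.4)
        events = detect_scrs_ttp(eda_series(v))
        assert len(events) == 1
        assert 27.0 < events[0].onset < 30.0
        assert abs(events[0].amplitude - 0.4) < 0.05

    def test_events_in_gapped_signal_skip_gaps(self, make_bump):
        t = np.arange(120 * 16) / 16.0
        v = 2.0 + make_bump(t, 20.0, 4.0, 0.3) + make_bump(t, 90.0, 4.0, 0.3)
        v[40 * 16 : 70 * 16] = np.nan
        events = detect_scrs_ttp(eda_series(v))
        assert len(events) == 2


class TestParameters:
    def test_flat_window(self):
        x = eda_series(np.full(960, 2.0))
        p = eda_parameters(x, [], (0.0, 60.0))
        assert p.scl_mean == pytest.approx(2.0)
        assert p.n_scr == 0 and p.total_amplitude == 0.0

    def test_rate_and_total_amplitude_arithmetic(self):
        x = eda_series(np.full(120 * 16, 2.0))
        events = [SCREvent(10.0, 12.0, 0.5), SCREvent(50.0, 52.0, 0.3)]
        p = eda_parameters(x, events, (0.0, 120.0))
        assert p.n_scr == 2
        assert p.total_amplitude == pytest.approx(0.8)
        assert p.scr_per_min == pytest.approx(1.0)

    def test_rate_uses_non_missing_duration(self):
        v = np.full(120 * 16, 2.0)
        v[: 60 * 16] = np.nan  # half the window missing
        x = eda_series(v)
        p = eda_parameters(x, [SCREvent(70.0, 72.0, 0.2)], (0.0, 120.0))
        assert p.scr_per_min == pytest.approx(1.0)

    def test_total_amplitude_additive_over_partition(self):
        x = eda_series(np.full(120 * 16, 2.0))
        events = [SCREvent(float(o), float(o + 2), 0.1) for o in range(5, 115, 10)]
        whole = eda_parameters(x, events, (0.0, 120.0)).total_amplitude
        parts = sum(
            eda_parameters(x, events, (a, a + 30.0)).total_amplitude
            for a in (0.0, 30.0, 60.0, 90.0)
        )
        assert whole == pytest.approx(parts)

    def test_zero_length_window_errors(self):
        with pytest.raises(ValueError):
            eda_parameters(eda_series(np.zeros(16)), [], (1.0, 1.0))


class TestNonresponder:
    def test_zero_events_flagged(self):
        x = eda_series(np.full(160, 2.0))
        flagged, reason = flag_nonresponder(x, [])
        assert flagged and "nonresponder" in reason

    def test_single_event_is_responder(self):
        x = eda_series(np.full(160, 2.0))
        flagged, _ = flag_nonresponder(x, [SCREvent(1.0, 2.0, 0.1)])
        assert not flagged
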