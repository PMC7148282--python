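import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wearvalid.core import (
    Block,
    BlockKind,
    Channel,
    EventSchedule,
    PairedRecording,
    ResponseWindow,
    TimeSeries,
    concatenate,
    detrend_linear,
    resample_to,
    slice_block,
    znormalize,
)


class TestTimeSeries:
    def test_rejects_nonpositive_fs(self, make_ts):
        with pytest.raises(ValueError):
            TimeSeries(0.0, 0.0, np.zeros(4))

    def test_times_and_duration(self, make_ts):
        x = make_ts(np.zeros(32), fs=16.0, start=2.0)
        assert x.duration == 2.0
        assert x.times[0] == 2.0
        assert np.isclose(x.times[-1], 2.0 + 31 / 16)

    def test_missing_markers_counted(self, make_ts):
        v = np.arange(10.0)
        v[3:6] = np.nan
        assert make_ts(v).n_missing == 3


class TestSchedule:
    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            EventSchedule(
                "p", [
                    Block("a", BlockKind.BASELINE, 0, 50),
                    Block("b", BlockKind.BASELINE, 40, 90),
                ],
            )

    def test_beep_must_sit_inside_stressor(self):
        with pytest.raises(ValueError, match="beep"):
            EventSchedule(
                "p", [
                    Block("task", BlockKind.STRESSOR, 0, 60),
                    Block("beep", BlockKind.BEEP, 70, 70.2),
                ],
            )

    def test_beeps_inside_stressor_allowed(self):
        s = EventSchedule(
            "p", [
                Block("task", BlockKind.STRESSOR, 0, 60),
                Block("beep", BlockKind.BEEP, 10, 10.2),
            ],
        )
        assert len(s.beeps) == 1

    def test_response_window_invariant(self):
        with pytest.raises(ValueError):
            ResponseWindow(6.0, 1.0)


class TestPairedRecording:
    def test_one_sided_channel_refused(self, make_ts, schedule):
        rec = PairedRecording(
            "p", rd={"eda": make_ts(np.zeros(4))}, wd={}, schedule=schedule
        )
        with pytest.raises(KeyError, match="both devices"):
            rec.require_channel("eda")


class TestResample:
    def test_upsample_4_to_16_hz_sample_count(self, make_ts):
        x = make_ts(np.random.default_rng(0).normal(size=240), fs=4.0)
        y = resample_to(x, 16.0)
        assert y.fs == 16.0
        assert y.n == 960
        assert abs(y.duration - x.duration) <= 1.0 / 16.0

    def test_identity_when_rate_matches(self, make_ts):
        x = make_ts(np.arange(32.0))
        y = resample_to(x, 16.0)
        np.testing.assert_array_equal(y.values, x.values)

    def test_sinusoid_recovered_through_decimation(self, make_ts):
        t = np.arange(int(60 * 256)) / 256.0
        x = make_ts(np.sin(2 * np.pi * 0.1 * t), fs=256.0)
        y = resample_to(x, 16.0)
        expected = np.sin(2 * np.pi * 0.1 * y.times)
        # ignore filter edge effects
        sl = slice(32, -32)
        assert np.max(np.abs(y.values[sl] - expected[sl])) < 1e-3

    def test_down_up_roundtrip_band_limited(self, make_ts):
        t = np.arange(1024) / 32.0
        x = make_ts(np.sin(2 * np.pi * 0.5 * t), fs=32.0)
        y = resample_to(resample_to(x, 64.0), 32.0)
        sl = slice(64, -64)
        assert np.max(np.abs(y.values[sl] - x.values[sl])) < 1e-3

    def test_up_down_roundtrip_interpolation_tolerance(self, make_ts):
        # heavily band-limited: linear-interpolation error ~ (f/fs)^2
        t = np.arange(4096) / 32.0
        x = make_ts(np.sin(2 * np.pi * 0.01 * t), fs=32.0)
        y = resample_to(resample_to(x, 64.0), 32.0)
        sl = slice(64, -64)
        assert np.max(np.abs(y.values[sl] - x.values[sl])) < 1e-6

    def test_gaps_stay_missing(self, make_ts):
        v = np.sin(np.arange(160) / 10.0)
        v[40:80] = np.nan
        y = resample_to(make_ts(v, fs=16.0), 32.0)
        assert y.n_missing >= 70
        assert not np.isnan(y.values[:70]).any()

    def test_rejects_bad_target(self, make_ts):
        with pytest.raises(ValueError):
            resample_to(make_ts(np.zeros(8)), -1.0)


class TestDetrend:
    def test_exact_line_removed(self, make_ts):
        t = np.arange(64) / 16.0
        y = detrend_linear(make_ts(2 + 3 * t))
        np.testing.assert_allclose(y.values, 0.0, atol=1e-10)

    def test_constant_becomes_zero(self, make_ts):
        y = detrend_linear(make_ts(np.full(16, 5.0)))
        np.testing.assert_allclose(y.values, 0.0, atol=1e-10)

    def test_residual_slope_negligible(self, make_ts):
        t = np.arange(256) / 16.0
        y = detrend_linear(make_ts(np.sin(t)))
        slope = np.polyfit(t, y.values, 1)[0]
        assert abs(slope) < 1e-9
        # matches an independent least-squares fit subtracted by hand
        coef = np.polyfit(t, np.sin(t), 1)
        np.testing.assert_allclose(
            y.values, np.sin(t) - np.polyval(coef, t), atol=1e-12
        )

    def test_all_missing_errors(self, make_ts):
        with pytest.raises(ValueError):
            detrend_linear(make_ts(np.full(8, np.nan)))


class TestZnormalize:
    def test_basic_moments(self, make_ts):
        y = znormalize(make_ts([1.0, 2.0, 3.0]))
        assert abs(np.mean(y.values)) < 1e-9
        assert abs(np.std(y.values, ddof=1) - 1) < 1e-9

    def test_idempotent(self, make_ts, rng):
        x = make_ts(rng.normal(size=100))
        once = znormalize(x)
        twice = znormalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)

    @given(
        a=st.floats(min_value=0.1, max_value=50),
        b=st.floats(min_value=-100, max_value=100),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_invariant(self, a, b):
        v = np.sin(np.arange(64) / 3.0)
        x = TimeSeries(0.0, 16.0, v)
        y = TimeSeries(0.0, 16.0, a * v + b)
        np.testing.assert_allclose(
            znormalize(y).values, znormalize(x).values, atol=1e-7
        )

    def test_zero_variance_names_channel(self, make_ts):
        with pytest.raises(ValueError, match="eda"):
            znormalize(make_ts(np.full(8, 2.0)))


class TestSliceBlock:
    def test_sample_count_half_open(self, make_ts):
        x = make_ts(np.arange(300 * 16, dtype=float))
        b = Block("w", BlockKind.BASELINE, 40.0, 70.0)
        s = slice_block(x, b)
        assert s.n == 480
        assert s.start_time == 40.0

    def test_outside_span_errors(self, make_ts):
        x = make_ts(np.zeros(160))  # 10 s
        with pytest.raises(ValueError):
            slice_block(x, (20.0, 30.0))

    def test_partition_concatenates_exactly(self, make_ts, rng):
        x = make_ts(rng.normal(size=480))  # 30 s at 16 Hz
        cuts = [0.0, 7.0, 13.5, 21.25, 30.0]
        parts = [slice_block(x, (a, b)) for a, b in zip(cuts, cuts[1:])]
        assert sum(p.n for p in parts) == x.n
        np.testing.assert_array_equal(concatenate(parts), x.values)
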