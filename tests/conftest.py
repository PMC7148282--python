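import numpy as np
import pytest

from wearvalid import synth
from wearvalid.core import Block, BlockKind, Channel, EventSchedule, TimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_series(values, fs=16.0, start=0.0, channel=Channel.EDA, units="uS"):
    return TimeSeries(
        start_time=start, fs=fs, values=np.asarray(values, dtype=float),
        units=units, channel=channel,
    )


@pytest.fixture
def make_ts():
    return make_series


@pytest.fixture(scope="session")
def schedule():
    cfg = synth.SynthConfig(seed=99, n_participants=1)
    return synth.generate_schedule(
        cfg, np.random.default_rng(99), participant_id="p001"
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort used by several integration tests."""
    cfg = synth.e4_like(seed=7, n_participants=8)
    cfg.eda.nonresponder_fraction = 0.25
    return synth.simulate_cohort(cfg)


def bump(t, center, width, amplitude):
    """Smooth raised-cosine bump with the given trough-to-peak amplitude."""
    u = (t - center) / (width / 2.0)
    out = np.zeros_like(t)
    m = np.abs(u) <= 1
    out[m] = amplitude * 0.5 * (1 + np.cos(np.pi * u[m]))
    return out


@pytest.fixture
def make_bump():
    return bump
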