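"""Electrodermal activity features: smoothing, trough-to-peak SCR scoring,
nonresponder flagging and per-window aggregates.

Skin conductance responses (SCRs) are scored with the classical
trough-to-peak (TTP) rule: each local conductance peak is paired with the
preceding trough, and the rise counts as a response when its amplitude
reaches the detection threshold (0.01 uS by default) within a plausible
rise time.  Three aggregates summarise a window: the tonic skin conductance
level (SCL, mean of the signal), the SCR rate per minute, and the total
amplitude (sum of SCR amplitudes, "S-AMPL").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import Block, Channel, TimeSeries, _interpolate_gaps

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SCREvent:
    """One skin conductance response.

    ``onset`` is the trough time, ``peak`` the peak time (both seconds from
    recording start); ``amplitude`` is conductance(peak) - conductance(onset)
    in uS.
    """

    onset: float
    peak: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.onset < self.peak:
            raise ValueError("SCR onset must precede its peak")
        if self.amplitude < 0:
            raise ValueError("SCR amplitude must be non-negative")


@dataclass(frozen=True)
class EDAParams:
    """Per-window EDA aggregates."""

    scl_mean: float         # uS
    scr_per_min: float      # responses / minute of non-missing signal
    total_amplitude: float  # uS
    window_length: float    # s (nominal window span)
    n_scr: int
    valid_minutes: float = 0.0  # non-missing signal duration, minutes

    @property
    def total_amplitude_per_min(self) -> float:
        """Summed SCR amplitude per minute of usable signal (uS/min)."""
        return self.total_amplitude / self.valid_minutes if self.valid_minutes else 0.0


def smooth_eda(x: TimeSeries, cutoff: float = 1.0) -> TimeSeries:
    """Zero-phase Gaussian smoothing with -3 dB point at ``cutoff`` Hz.

    A Gaussian kernel is used because its step response is monotone (no
    overshoot that could masquerade as a small SCR) and it preserves the DC
    level exactly.  Missing stretches remain missing.
    """
    if x.channel not in (None, Channel.EDA):
        raise ValueError(f"smooth_eda expects an EDA channel, got {x.channel}")
    if x.fs < 2 * cutoff:
        raise ValueError(
            f"sampling rate {x.fs} Hz too low for a {cutoff} Hz smoother"
        )
    # gain exp(-2 pi^2 sigma^2 f^2) = 1/sqrt(2) at f = cutoff
    sigma_s = np.sqrt(np.log(np.sqrt(2.0)) / 2.0) / (np.pi * cutoff)
    sigma = sigma_s * x.fs
    half = max(int(np.ceil(4 * sigma)), 1)
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    k /= k.sum()
    filled, valid = _interpolate_gaps(x.values)
    padded = np.pad(filled, half, mode="reflect")
    out = np.convolve(padded, k, mode="valid")
    out[~valid] = np.nan
    return x.with_values(out)


def detect_scrs_ttp(
    x: TimeSeries,
    threshold: float = 0.01,
    min_rise: float = 0.5,
    max_rise: float = 5.0,
) -> list[SCREvent]:
    """Trough-to-peak SCR detection on a smoothed EDA series.

    Candidate peaks are local maxima with prominence >= ``threshold``.  The
    onset (trough) is the base of the final rise: within the preceding
    ``max_rise`` seconds (and after the previous accepted peak), the last
    sample before the steep ascent where the slope stays below 10% of the
    rise's maximum slope — this keeps the onset anchored to the response
    even when the tonic level drifts upward underneath it.  The event is
    kept when the rise is at least ``threshold`` uS and the rise time lies
    in ``[min_rise, max_rise]`` seconds.  Events are emitted in time order
    and never share a trough.
    """
    events: list[SCREvent] = []
    valid = x.valid_mask
    if not valid.any():
        return events
    # split into contiguous valid segments so gaps cannot host an event
    edges = np.flatnonzero(np.diff(valid.astype(int)))
    bounds = np.concatenate(([0], edges + 1, [x.n]))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if not valid[lo]:
            continue
        seg = x.values[lo:hi]
        if len(seg) < 3:
            continue
        slope = np.gradient(seg) * x.fs  # uS/s
        peaks, _ = sps.find_peaks(seg, prominence=threshold)
        prev_peak = -1
        for p in peaks:
            w0 = max(prev_peak + 1, p - int(round(max_rise * x.fs)), 0)
            if w0 >= p:
                continue
            steepest = w0 + int(np.argmax(slope[w0:p]))
            thresh = 0.1 * slope[steepest]
            flat = np.flatnonzero(slope[w0:steepest] < thresh)
            if len(flat):
                trough = w0 + int(flat[-1])
            else:
                trough = w0 + int(np.argmin(seg[w0 : steepest + 1]))
            amplitude = float(seg[p] - seg[trough])
            rise = (p - trough) / x.fs
            if amplitude >= threshold and min_rise <= rise <= max_rise:
                events.append(
                    SCREvent(
                        onset=x.start_time + trough / x.fs,
                        peak=x.start_time + p / x.fs,
                        amplitude=amplitude,
                    )
                )
                prev_peak = p
    return events


def eda_parameters(
    x: TimeSeries,
    events: list[SCREvent],
    window: Block | tuple[float, float] | None = None,
) -> EDAParams:
    """Aggregate SCL / SCR rate / total amplitude over ``window``.

    The SCR rate is normalised by the *non-missing* signal duration inside
    the window, so gaps do not deflate rates.  Events are counted by onset
    time, half-open on the right.
    """
    if window is None:
        t0, t1 = x.start_time, x.end_time
    elif isinstance(window, Block):
        t0, t1 = window.onset, window.offset
    else:
        t0, t1 = window
    if not t1 > t0:
        raise ValueError(f"zero-length window [{t0}, {t1})")
    times = x.times
    inside = (times >= t0 - 1e-9) & (times < t1 - 1e-9)
    vals = x.values[inside]
    if len(vals) == 0 or np.isnan(vals).all():
        raise ValueError(f"window [{t0}, {t1}) contains no usable samples")
    in_events = [e for e in events if t0 <= e.onset < t1]
    valid_seconds = float(np.count_nonzero(~np.isnan(vals))) / x.fs
    n = len(in_events)
    return EDAParams(
        scl_mean=float(np.nanmean(vals)),
        scr_per_min=n / (valid_seconds / 60.0),
        total_amplitude=float(sum(e.amplitude for e in in_events)),
        window_length=t1 - t0,
        n_scr=n,
        valid_minutes=valid_seconds / 60.0,
    )


def flag_nonresponder(
    x: TimeSeries, events: list[SCREvent]
) -> tuple[bool, str]:
    """Zero SCRs over the whole recording marks a nonresponder.

    Automated surrogate for visual nonresponder screening; flagged
    participants are excluded from all cohort analyses.
    """
    if len(events) == 0:
        return True, "nonresponder: no SCRs detected over the recording"
    return False, f"responder: {len(events)} SCRs detected"
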