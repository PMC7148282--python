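"""Cardiovascular features: band-pass conditioning, beat detection,
interval filtering, signal-quality gating and time-domain aggregates.

Beat-to-beat intervals (RR for ECG, PP for PPG) outside the physiological
range [0.33, 1.5] s are deleted from the interval sequence — the interval,
not the beat, is removed — and the time-domain parameters (mean HR, SD of
the intervals, RMSSD) are computed on the surviving sequence.  RMSSD uses

    sqrt( (1 / (N - 1)) * sum_{i=1}^{N-1} (I_{i+1} - I_i)^2 )

with N the number of intervals, i.e. N - 1 successive differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .core import Block, Channel, TimeSeries, _interpolate_gaps

log = logging.getLogger(__name__)

PLAUSIBLE_HR = (40.0, 180.0)     # bpm window-plausibility band for the SQI
MAX_INTERVAL_RATIO = 2.2         # max/min interval ratio tolerated per window
MAX_BEAT_GAP = 1.8               # s; a longer beatless stretch marks dropout


@dataclass
class BeatSeries:
    """Detected (or supplied) beat times with their interval sequence.

    ``intervals`` starts as the successive differences of ``peak_times``;
    after :func:`filter_intervals` it is the surviving multiset, with
    ``interval_starts`` recording when each surviving interval began.
    """

    peak_times: np.ndarray
    source: Channel
    intervals: np.ndarray = field(default=None)  # type: ignore[assignment]
    interval_starts: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_removed: int = 0

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if len(self.peak_times) > 1 and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if self.intervals is None:
            self.intervals = np.diff(self.peak_times)
            self.interval_starts = self.peak_times[:-1].copy()
        else:
            self.intervals = np.asarray(self.intervals, dtype=float)
            self.interval_starts = np.asarray(self.interval_starts, dtype=float)

    @property
    def n_beats(self) -> int:
        return len(self.peak_times)


@dataclass(frozen=True)
class QualityWindow:
    """Per-window signal quality index on a 0-100 scale."""

    start: float
    end: float
    sqi: float

    def __post_init__(self) -> None:
        if not 0 <= self.sqi <= 100:
            raise ValueError(f"SQI must be in [0, 100], got {self.sqi}")


@dataclass(frozen=True)
class QualityGate:
    """Acceptance thresholds for quality gating."""

    min_coverage: float = 0.5   # consecutive fraction of the block
    sqi_long: float = 70.0      # baseline / stressor blocks
    sqi_event: float = 80.0     # short beep windows


@dataclass(frozen=True)
class CVAParams:
    """Time-domain cardiovascular aggregates; None marks not-available."""

    mean_hr: float | None       # bpm, 60 / mean interval
    sd_interval: float | None   # s, sample SD
    rmssd: float | None         # s
    coverage: float = 1.0
    n_intervals: int = 0


#: pass-band for the blood-volume pulse: unlike the QRS complex, the PPG
#: pulse carries its energy below 5 Hz, so the ECG band would erase it
PPG_BAND = (0.5, 8.0)


def bandpass_cardiac(
    x: TimeSeries, low: float = 5.0, high: float = 15.0
) -> TimeSeries:
    """Zero-phase band-pass; the 5-15 Hz default isolates the QRS complex."""
    if x.fs < 2 * high:
        raise ValueError(
            f"sampling rate {x.fs} Hz below twice the {high} Hz band edge"
        )
    filled, valid = _interpolate_gaps(x.values)
    sos = sps.butter(2, [low, high], btype="band", fs=x.fs, output="sos")
    out = sps.sosfiltfilt(sos, filled)
    out[~valid] = np.nan
    return x.with_values(out)


def detect_beats(x: TimeSeries, refractory: float = 0.25) -> BeatSeries:
    """Detect beats on a band-passed cardiac series.

    ECG uses adaptive-threshold peak picking on the squared signal (the
    energy of the QRS complex dominates); PPG uses local maxima of the
    filtered pulse wave.  Both enforce a refractory period.  The threshold
    adapts per 10-s stretch to half the local maximum envelope.
    """
    source = x.channel if x.channel is not None else Channel.ECG
    v = np.nan_to_num(x.values, nan=0.0)
    s = v**2 if source == Channel.ECG else v
    dist = max(int(round(refractory * x.fs)), 1)
    cand, _ = sps.find_peaks(s, distance=dist)
    if len(cand) == 0:
        return BeatSeries(np.empty(0), source=source)
    keep = []
    win = int(round(10.0 * x.fs))
    for p in cand:
        lo = max(p - win // 2, 0)
        hi = min(p + win // 2, len(s))
        local_max = s[lo:hi].max()
        if local_max > 0 and s[p] >= 0.4 * local_max:
            keep.append(p)
    peaks = np.asarray(keep, dtype=int)
    if len(peaks) == 0:
        return BeatSeries(np.empty(0), source=source)
    return BeatSeries(x.start_time + peaks / x.fs, source=source)


def filter_intervals(
    b: BeatSeries, lo: float = 0.33, hi: float = 1.5
) -> BeatSeries:
    """Delete intervals outside [lo, hi] s; boundary values are retained."""
    ok = (b.intervals >= lo) & (b.intervals <= hi)
    removed = int(np.count_nonzero(~ok))
    if removed:
        log.info(
            "interval filter removed %d of %d intervals outside [%.2f, %.2f] s",
            removed, len(b.intervals), lo, hi,
        )
    return BeatSeries(
        peak_times=b.peak_times,
        source=b.source,
        intervals=b.intervals[ok],
        interval_starts=b.interval_starts[ok],
        n_removed=b.n_removed + removed,
    )


def _window_plausibility(intervals: np.ndarray) -> float:
    if len(intervals) == 0:
        return 0.0
    hr = 60.0 / intervals.mean()
    if not (PLAUSIBLE_HR[0] <= hr <= PLAUSIBLE_HR[1]):
        return 0.0
    if intervals.min() <= 0 or intervals.max() / intervals.min() > MAX_INTERVAL_RATIO:
        return 0.0
    return 1.0


def sqi_windows(
    x: TimeSeries | None,
    b: BeatSeries,
    window_len: float = 10.0,
    span: tuple[float, float] | None = None,
) -> list[QualityWindow]:
    """Per-window signal quality index, 0-100.

    With a raw waveform, the SQI is 100 x the mean correlation of each
    beat's waveform with the window's average beat template, multiplied by
    a physiological plausibility factor (0 when the window heart rate falls
    outside 40-180 bpm or the max/min interval ratio exceeds 2.2).  With
    beat times only, the SQI reduces to the plausibility factor.  Windows
    with fewer than 3 beats score 0.
    """
    if span is None:
        if x is not None:
            span = (x.start_time, x.end_time)
        elif b.n_beats:
            span = (float(b.peak_times[0]), float(b.peak_times[-1]))
        else:
            return []
    t0, t1 = span
    out: list[QualityWindow] = []
    w0 = t0
    while w0 < t1 - 1e-9:
        w1 = min(w0 + window_len, t1)
        beats = b.peak_times[(b.peak_times >= w0) & (b.peak_times < w1)]
        if len(beats) < 3:
            out.append(QualityWindow(w0, w1, 0.0))
            w0 = w1
            continue
        intervals = np.diff(beats)
        # edge-inclusive gap check: consecutive coverage requires that no
        # beatless stretch inside the window exceeds the physiological
        # maximum interval
        gaps = np.diff(np.concatenate(([w0], beats, [w1])))
        plaus = 0.0 if gaps.max() > MAX_BEAT_GAP else _window_plausibility(intervals)
        if x is None or plaus == 0.0:
            out.append(QualityWindow(w0, w1, 100.0 * plaus))
            w0 = w1
            continue
        half = int(round(0.35 * float(np.median(intervals)) * x.fs))
        segs = []
        for t in beats:
            c = int(round((t - x.start_time) * x.fs))
            if c - half < 0 or c + half + 1 > x.n:
                continue
            seg = x.values[c - half : c + half + 1]
            if np.isnan(seg).any():
                continue
            segs.append(seg)
        if len(segs) < 3 or half < 2:
            out.append(QualityWindow(w0, w1, 0.0))
            w0 = w1
            continue
        mat = np.vstack(segs)
        template = mat.mean(axis=0)
        ts = template - template.mean()
        denom_t = np.sqrt((ts**2).sum())
        corrs = []
        for row in mat:
            rs = row - row.mean()
            denom = np.sqrt((rs**2).sum()) * denom_t
            corrs.append((rs @ ts) / denom if denom > 0 else 0.0)
        score = float(np.clip(np.mean(np.maximum(corrs, 0.0)), 0.0, 1.0))
        out.append(QualityWindow(w0, w1, 100.0 * score * plaus))
        w0 = w1
    return out


def gate_block(
    windows: list[QualityWindow],
    block: Block | tuple[float, float],
    gate: QualityGate,
    event: bool = False,
) -> tuple[bool, float]:
    """Accept a block when a consecutive run of good windows covers enough.

    A window is good when its SQI reaches ``gate.sqi_event`` (beep windows)
    or ``gate.sqi_long`` (longer blocks).  Coverage is the longest
    consecutive run of good windows, as a fraction of the block; the block
    is accepted when coverage >= ``gate.min_coverage``.
    """
    if isinstance(block, Block):
        t0, t1 = block.onset, block.offset
    else:
        t0, t1 = block
    thr = gate.sqi_event if event else gate.sqi_long
    overlapping = [
        w for w in windows if w.end > t0 + 1e-9 and w.start < t1 - 1e-9
    ]
    if not overlapping:
        return False, 0.0
    best = run = 0.0
    for w in overlapping:
        ov = min(w.end, t1) - max(w.start, t0)
        if w.sqi >= thr:
            run += ov
            best = max(best, run)
        else:
            run = 0.0
    coverage = min(best / (t1 - t0), 1.0)
    return coverage >= gate.min_coverage, coverage


def cva_parameters(
    b: BeatSeries,
    window: Block | tuple[float, float] | None = None,
    coverage: float = 1.0,
) -> CVAParams:
    """Mean HR, interval SD and RMSSD over the intervals in ``window``.

    Parameters with too few intervals are returned as None — never a
    silent zero.
    """
    if window is None:
        iv = b.intervals
    else:
        if isinstance(window, Block):
            t0, t1 = window.onset, window.offset
        else:
            t0, t1 = window
        sel = (b.interval_starts >= t0 - 1e-9) & (b.interval_starts < t1 - 1e-9)
        iv = b.intervals[sel]
    n = len(iv)
    if n < 2:
        return CVAParams(None, None, None, coverage=coverage, n_intervals=n)
    mean_hr = 60.0 / float(iv.mean())
    sd = float(iv.std(ddof=1))
    d = np.diff(iv)
    rmssd = float(np.sqrt((d**2).sum() / (n - 1)))
    return CVAParams(mean_hr, sd, rmssd, coverage=coverage, n_intervals=n)
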