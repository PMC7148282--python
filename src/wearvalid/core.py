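"""Core containers and signal-conditioning primitives.

Time convention: all timestamps are seconds from the start of the recording
session.  A :class:`TimeSeries` is uniformly sampled — sample ``i`` sits at
``start_time + i / fs`` — and missing samples are encoded as ``NaN``, never
silently dropped.  Block intervals are half-open ``[onset, offset)`` so that
adjacent blocks partition a recording without sharing a sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps


class Channel(str, Enum):
    """Physiological channel identity."""

    EDA = "eda"
    ECG = "ecg"
    PPG = "ppg"


class BlockKind(str, Enum):
    """Role of a schedule block in the experimental design."""

    BASELINE = "baseline"
    ANTICIPATION = "anticipation"
    STRESSOR = "stressor"
    RECOVERY = "recovery"
    BEEP = "beep"


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled signal with explicit missing-data markers.

    Parameters
    ----------
    start_time : float
        Time of the first sample, seconds from recording start.
    fs : float
        Sampling rate in Hz, strictly positive.
    values : ndarray of float
        Samples; ``NaN`` marks a missing sample.
    units : str
        Physical units, e.g. ``"uS"`` for skin conductance.
    channel : Channel or None
        Which physiological signal this is.
    """

    start_time: float
    fs: float
    values: np.ndarray
    units: str = ""
    channel: Channel | None = None

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        """Span covered by the samples (n / fs)."""
        return self.n / self.fs

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.fs

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class Block:
    """One labelled interval of the event schedule, half-open [onset, offset)."""

    label: str
    kind: BlockKind
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError(
                f"block {self.label!r}: onset {self.onset} must precede "
                f"offset {self.offset}"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class EventSchedule:
    """Ordered experimental blocks for one participant.

    Blocks must be non-overlapping, except that beep markers may sit inside
    a stressor block (the noise task embeds its stimuli).
    """

    participant_id: str
    blocks: list[Block]

    def __post_init__(self) -> None:
        self._check_overlap()

    def _check_overlap(self) -> None:
        stressors = [b for b in self.blocks if b.kind == BlockKind.STRESSOR]
        outer = sorted(
            (b for b in self.blocks if b.kind != BlockKind.BEEP),
            key=lambda b: b.onset,
        )
        for a, b in zip(outer, outer[1:]):
            if b.onset < a.offset:
                raise ValueError(
                    f"blocks {a.label!r} and {b.label!r} overlap "
                    f"([{a.onset}, {a.offset}) vs [{b.onset}, {b.offset}))"
                )
        for beep in (b for b in self.blocks if b.kind == BlockKind.BEEP):
            if not any(
                s.onset <= beep.onset and beep.offset <= s.offset
                for s in stressors
            ):
                raise ValueError(
                    f"beep {beep.label!r} lies outside every stressor block"
                )

    def by_kind(self, kind: BlockKind) -> list[Block]:
        return [b for b in self.blocks if b.kind == kind]

    @property
    def beeps(self) -> list[Block]:
        return self.by_kind(BlockKind.BEEP)

    @property
    def span(self) -> tuple[float, float]:
        return (
            min(b.onset for b in self.blocks),
            max(b.offset for b in self.blocks),
        )


@dataclass(frozen=True)
class ResponseWindow:
    """Post-stimulus window in which a phasic response is expected."""

    post_onset_start: float = 1.0
    post_onset_end: float = 6.0

    def __post_init__(self) -> None:
        if not (0 <= self.post_onset_start < self.post_onset_end):
            raise ValueError(
                "response window must satisfy 0 <= start < end, got "
                f"({self.post_onset_start}, {self.post_onset_end})"
            )

    @property
    def length(self) -> float:
        return self.post_onset_end - self.post_onset_start


@dataclass
class PairedRecording:
    """Synchronized reference-device and wearable channels for one participant.

    ``rd`` and ``wd`` map channel name ("eda", "ecg", "ppg") to a
    :class:`TimeSeries` sharing one clock.  Pre-detected beat times, when the
    acquisition pipeline provides them, live in ``rd_beats`` / ``wd_beats``
    (arrays of peak times in seconds).
    """

    participant_id: str
    rd: dict[str, TimeSeries]
    wd: dict[str, TimeSeries]
    schedule: EventSchedule
    rd_beats: np.ndarray | None = None
    wd_beats: np.ndarray | None = None

    def common_channels(self) -> list[str]:
        return sorted(set(self.rd) & set(self.wd))

    def require_channel(self, channel: str) -> tuple[TimeSeries, TimeSeries]:
        """Return (rd, wd) series for ``channel``, refusing one-sided data."""
        if channel not in self.rd or channel not in self.wd:
            raise KeyError(
                f"participant {self.participant_id}: channel {channel!r} "
                "must exist on both devices to be compared "
                f"(rd has {sorted(self.rd)}, wd has {sorted(self.wd)})"
            )
        return self.rd[channel], self.wd[channel]


# ---------------------------------------------------------------------------
# conditioning operations
# ---------------------------------------------------------------------------


def _interpolate_gaps(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linearly fill internal NaN runs; returns (filled, was_valid)."""
    valid = ~np.isnan(values)
    if valid.all():
        return values.copy(), valid
    if not valid.any():
        raise ValueError("series is entirely missing")
    idx = np.arange(len(values))
    filled = values.copy()
    filled[~valid] = np.interp(idx[~valid], idx[valid], values[valid])
    return filled, valid


def resample_to(x: TimeSeries, target_fs: float) -> TimeSeries:
    """Resample to ``target_fs``; duration is preserved within one period.

    Up-sampling uses linear interpolation; down-sampling applies a
    zero-phase low-pass at ``0.45 * target_fs`` before interpolation to the
    coarser grid.  Missing stretches stay missing: an output sample whose
    neighbourhood was a gap in the input is emitted as NaN.
    """
    if not target_fs > 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if np.isclose(target_fs, x.fs):
        return x.with_values(x.values)
    if x.n < 2:
        raise ValueError("need at least 2 samples to resample")
    filled, valid = _interpolate_gaps(x.values)
    n_out = int(round(x.n * target_fs / x.fs))
    t_old = np.arange(x.n) / x.fs
    t_new = np.arange(n_out) / target_fs
    if target_fs < x.fs:
        # anti-alias before decimation
        sos = sps.butter(4, 0.45 * target_fs, btype="low", fs=x.fs, output="sos")
        filled = sps.sosfiltfilt(sos, filled)
    out = np.interp(t_new, t_old, filled)
    if not valid.all():
        validity = np.interp(t_new, t_old, valid.astype(float))
        out[validity < 0.5] = np.nan
    return replace(x, fs=float(target_fs), values=out)


def detrend_linear(x: TimeSeries) -> TimeSeries:
    """Remove the least-squares line fit over non-missing samples."""
    valid = x.valid_mask
    if valid.sum() < 2:
        raise ValueError("detrend requires at least 2 non-missing samples")
    t = np.arange(x.n) / x.fs
    slope, intercept = np.polyfit(t[valid], x.values[valid], 1)
    return x.with_values(x.values - (slope * t + intercept))


def znormalize(x: TimeSeries) -> TimeSeries:
    """Scale to zero mean, unit sample standard deviation (non-missing)."""
    valid = x.valid_mask
    if valid.sum() < 2:
        raise ValueError("znormalize requires at least 2 non-missing samples")
    v = x.values[valid]
    mu = v.mean()
    sd = v.std(ddof=1)
    if sd <= 1e-15:
        name = x.channel.value if x.channel is not None else "unknown"
        raise ValueError(f"cannot normalize channel {name}: zero variance")
    return x.with_values((x.values - mu) / sd)


def slice_block(x: TimeSeries, block: Block | tuple[float, float]) -> TimeSeries:
    """Samples with ``onset <= t < offset``; result starts at the onset."""
    if isinstance(block, Block):
        onset, offset = block.onset, block.offset
    else:
        onset, offset = block
    eps = 1e-9
    i0 = int(np.ceil((onset - x.start_time) * x.fs - eps))
    i1 = int(np.ceil((offset - x.start_time) * x.fs - eps))
    i0 = max(i0, 0)
    if i0 >= x.n or i1 <= i0 or onset < x.start_time - eps or offset > x.end_time + 1.0 / x.fs:
        raise ValueError(
            f"block [{onset}, {offset}) outside recording span "
            f"[{x.start_time}, {x.end_time})"
        )
    i1 = min(i1, x.n)
    return replace(x, start_time=float(onset), values=x.values[i0:i1])


def concatenate(parts: Sequence[TimeSeries]) -> np.ndarray:
    """Concatenate the sample arrays of consecutive slices (test helper)."""
    return np.concatenate([p.values for p in parts])
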