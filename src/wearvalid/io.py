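"""CSV readers and writers for paired recordings.

Layout: one file per device per channel named
``<participant>_<rd|wd>_<channel>.csv`` with columns ``time_s,value``;
optional pre-detected beats in ``<participant>_<rd|wd>_beats.csv`` with a
``peak_time_s`` column; one ``schedule.csv`` per directory with columns
``participant,label,kind,onset_s,offset_s``.  Timestamps must be strictly
increasing; gaps in the time column are re-gridded and filled with explicit
NaN markers rather than dropped.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Block,
    BlockKind,
    Channel,
    EventSchedule,
    PairedRecording,
    TimeSeries,
)

log = logging.getLogger(__name__)

_CHANNEL_UNITS = {"eda": "uS", "ecg": "a.u.", "ppg": "a.u."}
_FILE_RE = re.compile(r"^(?P<pid>.+)_(?P<device>rd|wd)_(?P<what>eda|ecg|ppg|beats)\.csv$")


class ParseError(ValueError):
    pass


def series_from_table(
    df: pd.DataFrame, channel: str, fs: float | None = None
) -> TimeSeries:
    """Build a TimeSeries from a (time_s, value) table.

    The sampling rate is inferred from the median time step unless
    declared.  Rows are placed on the uniform grid; grid slots without a
    row become NaN (missing markers), so a timestamp gap of k samples
    yields exactly k NaNs.
    """
    t = df["time_s"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ParseError("need at least two samples")
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if len(bad):
        raise ParseError(
            f"time column not strictly increasing at row {bad[0] + 1} "
            f"(t={t[bad[0]]} followed by t={t[bad[0] + 1]})"
        )
    if fs is None:
        fs = 1.0 / float(np.median(dt))
        # timestamps are written with finite precision; snap to an integer
        # rate when the median step is within 1% of one
        if abs(fs - round(fs)) / fs < 0.01:
            fs = float(round(fs))
    n = int(round((t[-1] - t[0]) * fs)) + 1
    idx = np.round((t - t[0]) * fs).astype(int)
    if np.any(np.abs((t - t[0]) * fs - idx) > 0.25):
        off = int(np.argmax(np.abs((t - t[0]) * fs - idx)))
        raise ParseError(
            f"row {off} (t={t[off]}) does not sit on a uniform {fs} Hz grid"
        )
    values = np.full(n, np.nan)
    values[idx] = v
    return TimeSeries(
        start_time=float(t[0]),
        fs=fs,
        values=values,
        units=_CHANNEL_UNITS.get(channel, ""),
        channel=Channel(channel),
    )


def read_schedule(path: str | Path) -> dict[str, EventSchedule]:
    df = pd.read_csv(path)
    required = {"participant", "label", "kind", "onset_s", "offset_s"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"schedule file lacks columns: {sorted(missing)}")
    out: dict[str, EventSchedule] = {}
    for pid, grp in df.groupby("participant", sort=True):
        blocks = [
            Block(
                label=str(r.label),
                kind=BlockKind(str(r.kind)),
                onset=float(r.onset_s),
                offset=float(r.offset_s),
            )
            for r in grp.itertuples()
        ]
        out[str(pid)] = EventSchedule(participant_id=str(pid), blocks=blocks)
    return out


def read_recording(
    data_dir: str | Path,
    participant_id: str,
    schedule: EventSchedule | None = None,
    fs_overrides: dict[str, float] | None = None,
) -> PairedRecording:
    """Assemble one participant's PairedRecording from a data directory."""
    data_dir = Path(data_dir)
    if schedule is None:
        schedules = read_schedule(data_dir / "schedule.csv")
        if participant_id not in schedules:
            raise ParseError(f"no schedule for participant {participant_id!r}")
        schedule = schedules[participant_id]
    rd: dict[str, TimeSeries] = {}
    wd: dict[str, TimeSeries] = {}
    rd_beats = wd_beats = None
    for path in sorted(data_dir.glob(f"{participant_id}_*.csv")):
        m = _FILE_RE.match(path.name)
        if not m or m.group("pid") != participant_id:
            continue
        device, what = m.group("device"), m.group("what")
        if what == "beats":
            beats = np.sort(
                pd.read_csv(path)["peak_time_s"].to_numpy(dtype=float)
            )
            if device == "rd":
                rd_beats = beats
            else:
                wd_beats = beats
            continue
        fs = (fs_overrides or {}).get(f"{device}_{what}")
        try:
            ts = series_from_table(pd.read_csv(path), what, fs=fs)
        except ParseError as exc:
            raise ParseError(f"{path.name}: {exc}") from exc
        (rd if device == "rd" else wd)[what] = ts
    if not rd and not wd and rd_beats is None and wd_beats is None:
        raise ParseError(f"no data files found for {participant_id!r}")
    found = {
        "rd": sorted(rd) + (["beats"] if rd_beats is not None else []),
        "wd": sorted(wd) + (["beats"] if wd_beats is not None else []),
    }
    log.info("participant %s: channels %s", participant_id, found)
    return PairedRecording(
        participant_id=participant_id,
        rd=rd,
        wd=wd,
        schedule=schedule,
        rd_beats=rd_beats,
        wd_beats=wd_beats,
    )


def read_cohort(data_dir: str | Path) -> list[PairedRecording]:
    data_dir = Path(data_dir)
    schedules = read_schedule(data_dir / "schedule.csv")
    return [
        read_recording(data_dir, pid, schedule=schedules[pid])
        for pid in sorted(schedules)
    ]


def write_series(ts: TimeSeries, path: str | Path) -> None:
    """Write (time_s, value); missing samples are omitted rows (a time gap)."""
    mask = ts.valid_mask
    pd.DataFrame(
        {"time_s": ts.times[mask], "value": ts.values[mask]}
    ).to_csv(path, index=False, float_format="%.6f")


def write_recording(rec: PairedRecording, data_dir: str | Path) -> list[Path]:
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for device, channels in (("rd", rec.rd), ("wd", rec.wd)):
        for name, ts in channels.items():
            p = data_dir / f"{rec.participant_id}_{device}_{name}.csv"
            write_series(ts, p)
            written.append(p)
    for device, beats in (("rd", rec.rd_beats), ("wd", rec.wd_beats)):
        if beats is not None:
            p = data_dir / f"{rec.participant_id}_{device}_beats.csv"
            pd.DataFrame({"peak_time_s": beats}).to_csv(
                p, index=False, float_format="%.6f"
            )
            written.append(p)
    return written


def write_cohort(
    recordings: list[PairedRecording],
    data_dir: str | Path,
    manifest_extra: dict | None = None,
) -> None:
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    files: list[str] = []
    for rec in recordings:
        files += [p.name for p in write_recording(rec, data_dir)]
        for b in rec.schedule.blocks:
            rows.append(
                {
                    "participant": rec.participant_id,
                    "label": b.label,
                    "kind": b.kind.value,
                    "onset_s": b.onset,
                    "offset_s": b.offset,
                }
            )
    pd.DataFrame(rows).to_csv(data_dir / "schedule.csv", index=False)
    manifest = {"files": sorted(files) + ["schedule.csv"]}
    if manifest_extra:
        manifest.update(manifest_extra)
    (data_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
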