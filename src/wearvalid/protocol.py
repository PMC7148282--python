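"""The three-level validity study: model object and fitted results.

:class:`ValidityStudy` is built from a cohort of synchronized paired
recordings plus a :class:`~wearvalid.config.ProtocolConfig`; ``fit()`` runs
the requested levels and returns a :class:`ValidityResults` carrying the
per-level results, diagnostics, exclusion counts, the assembled verdict, a
``summary()`` table and ``save()``/plot helpers.

Pipeline per channel family:

EDA — reference and wearable signals are brought to a common 16 Hz grid,
smoothed, and scored for skin conductance responses; nonresponders (zero
SCRs on either device) are excluded from the cohort.  Level 1 correlates
the detrended, z-normalized signals at lags -8..+8.  Level 2 compares the
whole-recording SCL, SCR rate and total amplitude in Bland-Altman plots
against the a-priori boundaries.  Level 3 compares task-wise total SCR
amplitude (duration-matched baselines) and fits the habituation decay over
the beep sequence.

CVA — beat streams (pre-detected, or detected from raw ECG/PPG at 200 Hz
via the 5-15 Hz band) are interval-filtered to [0.33, 1.5] s and quality
gated; ECG vs PPG is never compared at the signal level.  Level 2 compares
mean HR, interval SD and RMSSD; level 3 compares task-wise mean HR under
the consecutive-coverage quality gate.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cardio, eda, event_level, parameter_level, signal_level
from .cardio import BeatSeries, QualityGate
from .config import ProtocolConfig
from .core import (
    Block,
    BlockKind,
    Channel,
    EventSchedule,
    PairedRecording,
    detrend_linear,
    resample_to,
    slice_block,
    znormalize,
)
from .event_level import (
    Effect,
    EventComparison,
    EventStatus,
    EventVerdict,
    HabituationFit,
    TaskSummary,
)
from .parameter_level import (
    AgreementBoundary,
    BlandAltmanResult,
    Parameter,
    ParameterVerdict,
    bland_altman,
    derive_boundary,
    parameter_decision,
)
from .signal_level import SignalVerdict, cohort_signal_decision, cross_correlation_lags
from .verdict import Verdict, assemble_verdict, render_report

log = logging.getLogger(__name__)

EDA_PARAMETERS = (Parameter.SCL, Parameter.SCR_RATE, Parameter.S_AMPL)
CVA_PARAMETERS = (Parameter.HR, Parameter.SD_INTERVAL, Parameter.RMSSD)


@dataclass
class _ParticipantFeatures:
    """Conditioned signals and extracted features for one participant."""

    recording: PairedRecording
    rd_eda: object | None = None       # smoothed 16 Hz TimeSeries
    wd_eda: object | None = None
    rd_eda_raw: object | None = None   # unsmoothed 16 Hz (signal level)
    wd_eda_raw: object | None = None
    rd_events: list = field(default_factory=list)
    wd_events: list = field(default_factory=list)
    nonresponder: bool = False
    nonresponder_reason: str = ""
    rd_beats: BeatSeries | None = None
    wd_beats: BeatSeries | None = None
    rd_sqi: list = field(default_factory=list)
    wd_sqi: list = field(default_factory=list)


@dataclass
class ValidityResults:
    """Fitted results of the three-level protocol."""

    config: ProtocolConfig
    n_recordings: int
    levels: tuple[str, ...]
    channels: tuple[str, ...]
    signal: SignalVerdict | None = None
    parameters: dict[str, dict] = field(default_factory=dict)
    event_summaries: dict[str, dict] = field(default_factory=dict)
    event_comparisons: dict[str, dict] = field(default_factory=dict)
    event_verdicts: dict[str, dict] = field(default_factory=dict)
    habituation: dict[str, HabituationFit | None] = field(default_factory=dict)
    exclusions: Counter = field(default_factory=Counter)
    nonresponders: list[str] = field(default_factory=list)
    verdict: Verdict | None = None

    # -- presentation -----------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Wearable validity assessment",
            "=" * 60,
            f"recordings: {self.n_recordings}   "
            f"nonresponders excluded: {len(self.nonresponders)}",
            f"levels: {', '.join(self.levels)}   "
            f"channels: {', '.join(self.channels)}",
            "",
        ]
        if self.signal is not None:
            lines.append(
                f"[signal]   {'PASS' if self.signal.passed else 'FAIL'}  "
                f"(criterion r > {self.signal.threshold:.2f}; "
                f"mean best r = "
                f"{np.mean([r.best_r for r in self.signal.per_participant]):.3f})"
            )
            if self.signal.systematic_lag is not None:
                lines.append(
                    f"           systematic lag: {self.signal.systematic_lag:+d}"
                )
        for name, entry in self.parameters.items():
            res: BlandAltmanResult = entry["result"]
            pv: ParameterVerdict = entry["verdict"]
            b: AgreementBoundary = entry["boundary"]
            lines.append(
                f"[param]    {name:12s} {pv.status.upper():8s}"
                f"{' BIASED' if pv.biased else '       '} "
                f"mean diff {res.mean_diff:+.3g}, LoA "
                f"({res.loa_low:.3g}, {res.loa_high:.3g}) vs +-{b.boundary:g} "
                f"[{res.pct_within_boundary:.0f}% within, n={res.n}]"
            )
        for channel, verdicts in self.event_verdicts.items():
            counts = Counter(v.status.value for v in verdicts.values())
            lines.append(
                f"[event]    {channel}: "
                + ", ".join(f"{k}={v}" for k, v in sorted(counts.items()))
            )
        for device, fit in self.habituation.items():
            if fit is not None:
                lines.append(
                    f"[habituation] {device}: {100 * fit.decay_rate:.1f}% per "
                    f"stimulus (95% CI {100 * fit.ci[0]:.1f}..{100 * fit.ci[1]:.1f}%)"
                )
        if self.exclusions:
            lines.append("")
            lines.append("exclusions / data loss:")
            for k, v in sorted(self.exclusions.items()):
                lines.append(f"  {k}: {v}")
        if self.verdict is not None:
            lines += ["", "verdict:", f"  signal: {self.verdict.signal}"]
            for k, v in self.verdict.parameter.items():
                lines.append(f"  parameter {k}: {v}")
            for k, v in self.verdict.event.items():
                lines.append(f"  event {k}: {v}")
        return "\n".join(lines) + "\n"

    def tables(self) -> dict[str, pd.DataFrame]:
        out: dict[str, pd.DataFrame] = {}
        if self.signal is not None:
            rows = []
            for r in self.signal.per_participant:
                row = {
                    "participant": r.participant_id,
                    "best_lag": r.best_lag,
                    "best_r": r.best_r,
                }
                row.update(
                    {f"r_lag{int(k):+d}": v for k, v in zip(r.lags, r.r_by_lag)}
                )
                rows.append(row)
            out["signal_crosscorrelation"] = pd.DataFrame(rows)
        for name, entry in self.parameters.items():
            out[f"parameter_{name}"] = entry["result"].pairs
        for channel, summaries in self.event_summaries.items():
            rows = []
            for task, devs in summaries.items():
                for device, summ in devs.items():
                    for pid, v in sorted(summ.per_participant.items()):
                        rows.append(
                            {
                                "task": task,
                                "device": device,
                                "participant": pid,
                                "value": v,
                            }
                        )
            out[f"event_values_{channel}"] = pd.DataFrame(rows)
            rows = []
            for task, devs in summaries.items():
                for device, summ in devs.items():
                    rows.append(
                        {
                            "task": task,
                            "device": device,
                            "mean": summ.mean,
                            "se": summ.se,
                            "n": summ.n_available,
                        }
                    )
            out[f"event_summaries_{channel}"] = pd.DataFrame(rows)
        for channel, verdicts in self.event_verdicts.items():
            comps = self.event_comparisons.get(channel, {})
            rows = []
            for task, ev in verdicts.items():
                c = comps.get(task)
                rows.append(
                    {
                        "task": task,
                        "status": ev.status.value,
                        "reason": "; ".join(ev.reasons),
                        "diff_mean": None if c is None else c.diff_mean,
                        "diff_se": None if c is None else c.diff_se,
                        "ref_effect": None if c is None else c.ref_effect,
                        "n": None if c is None else c.n,
                    }
                )
            out[f"event_verdicts_{channel}"] = pd.DataFrame(rows)
        return out

    def save(self, out_dir: str | Path, make_figures: bool = True) -> list[Path]:
        return render_report(self, out_dir, make_figures=make_figures)


class ValidityStudy:
    """Validity-assessment model over a cohort of paired recordings."""

    def __init__(
        self, recordings: list[PairedRecording], config: ProtocolConfig | None = None
    ):
        if not recordings:
            raise ValueError("need at least one recording")
        self.recordings = recordings
        self.config = config or ProtocolConfig()

    @classmethod
    def from_directory(
        cls, data_dir: str | Path, config: ProtocolConfig | None = None
    ) -> "ValidityStudy":
        from .io import read_cohort

        return cls(read_cohort(data_dir), config=config)

    # -- feature extraction ------------------------------------------------

    def _eda_features(self, rec: PairedRecording, f: _ParticipantFeatures) -> None:
        cfg = self.config
        try:
            rd_raw, wd_raw = rec.require_channel("eda")
        except KeyError:
            return
        rd16 = resample_to(rd_raw, cfg.eda_fs)
        wd16 = resample_to(wd_raw, cfg.eda_fs)
        f.rd_eda_raw, f.wd_eda_raw = rd16, wd16
        f.rd_eda = eda.smooth_eda(rd16, cutoff=cfg.eda_smooth_cutoff)
        f.wd_eda = eda.smooth_eda(wd16, cutoff=cfg.eda_smooth_cutoff)
        kw = dict(
            threshold=cfg.scr_threshold,
            min_rise=cfg.scr_min_rise,
            max_rise=cfg.scr_max_rise,
        )
        f.rd_events = eda.detect_scrs_ttp(f.rd_eda, **kw)
        f.wd_events = eda.detect_scrs_ttp(f.wd_eda, **kw)
        for device, series, events in (
            ("rd", f.rd_eda, f.rd_events),
            ("wd", f.wd_eda, f.wd_events),
        ):
            flagged, reason = eda.flag_nonresponder(series, events)
            if flagged:
                f.nonresponder = True
                f.nonresponder_reason = f"{device}: {reason}"
                break

    def _beat_series(self, rec: PairedRecording, device: str) -> BeatSeries | None:
        cfg = self.config
        beats = rec.rd_beats if device == "rd" else rec.wd_beats
        channels = rec.rd if device == "rd" else rec.wd
        source = Channel.ECG if device == "rd" else Channel.PPG
        if beats is not None:
            return BeatSeries(beats, source=source)
        for name in ("ecg", "ppg"):
            if name in channels:
                x = resample_to(channels[name], cfg.cva_fs)
                band = cardio.PPG_BAND if name == "ppg" else (5.0, 15.0)
                bp = cardio.bandpass_cardiac(x, *band)
                detected = cardio.detect_beats(bp, refractory=cfg.refractory)
                return BeatSeries(detected.peak_times, source=Channel(name))
        return None

    def _cva_features(self, rec: PairedRecording, f: _ParticipantFeatures) -> None:
        cfg = self.config
        for device in ("rd", "wd"):
            b = self._beat_series(rec, device)
            if b is None:
                continue
            filtered = cardio.filter_intervals(
                b, lo=cfg.interval_min, hi=cfg.interval_max
            )
            self._count(f"intervals_deleted_{device}", filtered.n_removed)
            sqi = cardio.sqi_windows(
                None, filtered, window_len=cfg.sqi_window_len,
                span=rec.schedule.span,
            )
            if device == "rd":
                f.rd_beats, f.rd_sqi = filtered, sqi
            else:
                f.wd_beats, f.wd_sqi = filtered, sqi

    def _count(self, key: str, value: int = 1) -> None:
        self._exclusions[key] += value

    # -- level 1 -----------------------------------------------------------

    def _signal_level(self, feats: list[_ParticipantFeatures]) -> SignalVerdict | None:
        cfg = self.config
        results = []
        for f in feats:
            if f.rd_eda_raw is None or f.wd_eda_raw is None:
                continue
            try:
                x = znormalize(detrend_linear(f.rd_eda_raw))
                y = znormalize(detrend_linear(f.wd_eda_raw))
            except ValueError as exc:
                self._count("signal_level_skipped")
                log.warning(
                    "%s: signal level skipped (%s)",
                    f.recording.participant_id, exc,
                )
                continue
            results.append(
                cross_correlation_lags(
                    x, y, max_lag=cfg.max_lag,
                    participant_id=f.recording.participant_id,
                )
            )
        if not results:
            return None
        return cohort_signal_decision(results, threshold=cfg.corr_threshold)

    # -- level 2 -----------------------------------------------------------

    def _cva_params_whole(
        self, f: _ParticipantFeatures, device: str
    ) -> cardio.CVAParams | None:
        cfg = self.config
        b = f.rd_beats if device == "rd" else f.wd_beats
        sqi = f.rd_sqi if device == "rd" else f.wd_sqi
        if b is None or not sqi:
            return None
        good = [w for w in sqi if w.sqi >= cfg.sqi_long]
        coverage = len(good) / len(sqi)
        mask = np.zeros(len(b.intervals), dtype=bool)
        for w in good:
            mask |= (b.interval_starts >= w.start) & (b.interval_starts < w.end)
        kept = BeatSeries(
            peak_times=b.peak_times,
            source=b.source,
            intervals=b.intervals[mask],
            interval_starts=b.interval_starts[mask],
        )
        return cardio.cva_parameters(kept, coverage=coverage)

    def _parameter_level(
        self, feats: list[_ParticipantFeatures], channels: tuple[str, ...]
    ) -> dict[str, dict]:
        cfg = self.config
        rows: dict[Parameter, list[dict]] = {p: [] for p in Parameter}
        for f in feats:
            pid = f.recording.participant_id
            if "eda" in channels and f.rd_eda is not None and f.wd_eda is not None:
                vals = {}
                span = f.recording.schedule.span
                for device, series, events in (
                    ("rd", f.rd_eda, f.rd_events),
                    ("wd", f.wd_eda, f.wd_events),
                ):
                    p = eda.eda_parameters(series, events, window=span)
                    vals[device] = p
                rows[Parameter.SCL].append(
                    {"participant": pid, "rd": vals["rd"].scl_mean,
                     "wd": vals["wd"].scl_mean}
                )
                rows[Parameter.SCR_RATE].append(
                    {"participant": pid, "rd": vals["rd"].scr_per_min,
                     "wd": vals["wd"].scr_per_min}
                )
                # per-minute scale: the +-0.6 uS boundary derives from a
                # per-minute plausible range (up to ~0.3 uS x 20 SCRs/min)
                rows[Parameter.S_AMPL].append(
                    {"participant": pid,
                     "rd": vals["rd"].total_amplitude_per_min,
                     "wd": vals["wd"].total_amplitude_per_min}
                )
            if "cva" in channels:
                prd = self._cva_params_whole(f, "rd")
                pwd = self._cva_params_whole(f, "wd")
                if prd is None and pwd is None:
                    continue
                def _get(p, attr):
                    v = None if p is None else getattr(p, attr)
                    return np.nan if v is None else v
                rows[Parameter.HR].append(
                    {"participant": pid, "rd": _get(prd, "mean_hr"),
                     "wd": _get(pwd, "mean_hr")}
                )
                rows[Parameter.SD_INTERVAL].append(
                    {"participant": pid, "rd": _get(prd, "sd_interval"),
                     "wd": _get(pwd, "sd_interval")}
                )
                rows[Parameter.RMSSD].append(
                    {"participant": pid, "rd": _get(prd, "rmssd"),
                     "wd": _get(pwd, "rmssd")}
                )
        out: dict[str, dict] = {}
        wanted = []
        if "eda" in channels:
            wanted += list(EDA_PARAMETERS)
        if "cva" in channels:
            wanted += list(CVA_PARAMETERS)
        for param in wanted:
            data = rows[param]
            if not data:
                continue
            df = pd.DataFrame(data)
            lo, hi = cfg.plausible_ranges[param.value]
            boundary = derive_boundary(
                param, lo, hi,
                fraction=cfg.boundary_fraction,
                rounding=cfg.boundary_decimals,
            )
            try:
                result = bland_altman(
                    df, boundary,
                    transform_policy=cfg.transform_policy,
                    log_offset=cfg.log_offset,
                )
            except ValueError as exc:
                log.warning("parameter %s skipped: %s", param.value, exc)
                self._count(f"parameter_{param.value}_skipped")
                continue
            self._count("pairs_dropped_missing", result.n_dropped)
            out[param.value] = {
                "boundary": boundary,
                "result": result,
                "verdict": parameter_decision(result, boundary),
            }
        return out

    # -- level 3 -----------------------------------------------------------

    def _eda_task_windows(self, schedule: EventSchedule) -> dict[str, tuple[float, float]]:
        cfg = self.config
        by_label = {b.label: b for b in schedule.blocks}
        windows: dict[str, tuple[float, float]] = {}
        base = by_label.get("baseline")
        if base is not None:
            w = min(cfg.event_baseline_len, base.duration)
            windows["baseline"] = (base.offset - w, base.offset)
        for label in ("anticipation", "singing"):
            if label in by_label:
                b = by_label[label]
                windows[label] = (b.onset, b.offset)
        rec = by_label.get("recovery")
        if rec is not None:
            w = min(cfg.event_baseline_len, rec.duration)
            windows["recovery"] = (rec.onset, rec.onset + w)
        for beep in schedule.beeps:
            windows[beep.label] = (
                beep.onset + cfg.response_start,
                beep.onset + cfg.response_end,
            )
        return windows

    def _beep_scale_baseline(
        self, f: _ParticipantFeatures, events: list, schedule: EventSchedule
    ) -> float | None:
        """Mean total amplitude over response-window-length baseline slices."""
        cfg = self.config
        by_label = {b.label: b for b in schedule.blocks}
        base = by_label.get("baseline")
        if base is None:
            return None
        wlen = cfg.response_end - cfg.response_start
        vals = []
        t = base.onset
        while t + wlen <= base.offset + 1e-9:
            vals.append(
                sum(e.amplitude for e in events if t <= e.onset < t + wlen)
            )
            t += wlen
        return float(np.mean(vals)) if vals else None

    def _event_level_eda(
        self, feats: list[_ParticipantFeatures]
    ) -> tuple[dict, dict, dict]:
        cfg = self.config
        summaries: dict[str, dict] = {}
        values: dict[str, dict[str, dict[str, float]]] = {}
        beep_base: dict[str, dict[str, float]] = {"rd": {}, "wd": {}}
        for f in feats:
            if f.rd_eda is None:
                continue
            pid = f.recording.participant_id
            windows = self._eda_task_windows(f.recording.schedule)
            for device, events in (("rd", f.rd_events), ("wd", f.wd_events)):
                for task, (t0, t1) in windows.items():
                    v = sum(e.amplitude for e in events if t0 <= e.onset < t1)
                    values.setdefault(task, {}).setdefault(device, {})[pid] = v
                bb = self._beep_scale_baseline(f, events, f.recording.schedule)
                if bb is not None:
                    beep_base[device][pid] = bb
        if not values:
            return {}, {}, {}
        task_order = list(values)
        for task in task_order:
            summaries[task] = {
                device: TaskSummary(task, device, values[task].get(device, {}))
                for device in ("rd", "wd")
            }
        beep_base_summ = {
            device: TaskSummary("beep_baseline", device, beep_base[device])
            for device in ("rd", "wd")
        }
        return self._decide_events(
            summaries, beep_base_summ, channel="eda"
        )

    def _cva_task_value(
        self, f: _ParticipantFeatures, device: str, window: tuple[float, float],
        event: bool,
    ) -> float | None:
        cfg = self.config
        b = f.rd_beats if device == "rd" else f.wd_beats
        sqi = f.rd_sqi if device == "rd" else f.wd_sqi
        if b is None:
            return None
        gate = QualityGate(
            min_coverage=cfg.min_coverage,
            sqi_long=cfg.sqi_long,
            sqi_event=cfg.sqi_event,
        )
        accepted, _cov = cardio.gate_block(sqi, window, gate, event=event)
        if not accepted:
            self._count(f"cva_blocks_gated_out_{device}")
            return None
        params = cardio.cva_parameters(b, window)
        if params.mean_hr is None:
            self._count(f"cva_blocks_insufficient_{device}")
            return None
        return params.mean_hr

    def _event_level_cva(
        self, feats: list[_ParticipantFeatures]
    ) -> tuple[dict, dict, dict]:
        cfg = self.config
        values: dict[str, dict[str, dict[str, float]]] = {}
        for f in feats:
            if f.rd_beats is None and f.wd_beats is None:
                continue
            pid = f.recording.participant_id
            windows = self._eda_task_windows(f.recording.schedule)
            beep_labels = {b.label for b in f.recording.schedule.beeps}
            for task, (t0, t1) in windows.items():
                is_event = task in beep_labels
                for device in ("rd", "wd"):
                    v = self._cva_task_value(f, device, (t0, t1), is_event)
                    if v is not None:
                        values.setdefault(task, {}).setdefault(device, {})[pid] = v
                    else:
                        values.setdefault(task, {}).setdefault(device, {})
        if not values:
            return {}, {}, {}
        summaries = {
            task: {
                device: TaskSummary(task, device, values[task].get(device, {}))
                for device in ("rd", "wd")
            }
            for task in values
        }
        baseline = summaries.get("baseline")
        beep_base_summ = (
            {d: baseline[d] for d in ("rd", "wd")} if baseline else None
        )
        return self._decide_events(summaries, beep_base_summ, channel="cva")

    def _decide_events(
        self,
        summaries: dict[str, dict[str, TaskSummary]],
        beep_baseline: dict[str, TaskSummary] | None,
        channel: str,
    ) -> tuple[dict, dict, dict]:
        cfg = self.config
        comparisons: dict[str, EventComparison] = {}
        verdicts: dict[str, EventVerdict] = {}
        baseline = summaries.get("baseline")
        for task, devs in summaries.items():
            if task in ("baseline", "recovery"):
                continue
            is_beep = task.startswith("beep")
            base = beep_baseline if is_beep else baseline
            if base is None or base["rd"].n_available == 0:
                verdicts[task] = EventVerdict(
                    task, EventStatus.INCONCLUSIVE_DATA,
                    ["no baseline available"],
                )
                continue
            rd_eff = event_level.detect_effect(
                base["rd"], devs["rd"], cfg.se_multiplier
            )
            wd_eff = event_level.detect_effect(
                base["wd"], devs["wd"], cfg.se_multiplier
            )
            comparison = None
            if base["rd"].mean is not None and devs["rd"].mean is not None:
                ref = event_level.reference_effect(base["rd"], devs["rd"])
                diffs = {
                    pid: devs["wd"].per_participant[pid]
                    - devs["rd"].per_participant[pid]
                    for pid in devs["rd"].per_participant
                    if pid in devs["wd"].per_participant
                }
                comparison = EventComparison(task, diffs, ref_effect=ref)
                comparisons[task] = comparison
            verdicts[task] = event_level.event_decision(
                task, rd_eff, wd_eff, comparison
            )
        return summaries, comparisons, verdicts

    def _habituation(self, feats: list[_ParticipantFeatures]) -> dict:
        cfg = self.config
        fits: dict[str, HabituationFit | None] = {}
        for device in ("rd", "wd"):
            means = []
            any_schedule = None
            for f in feats:
                if f.rd_eda is None:
                    continue
                any_schedule = f.recording.schedule
                break
            if any_schedule is None or not any_schedule.beeps:
                fits[device] = None
                continue
            for beep in any_schedule.beeps:
                t0 = beep.onset + cfg.response_start
                t1 = beep.onset + cfg.response_end
                vals = []
                for f in feats:
                    if f.rd_eda is None:
                        continue
                    events = f.rd_events if device == "rd" else f.wd_events
                    vals.append(
                        sum(e.amplitude for e in events if t0 <= e.onset < t1)
                    )
                means.append(float(np.mean(vals)) if vals else np.nan)
            try:
                fits[device] = event_level.fit_habituation(
                    means, floor=cfg.habituation_floor
                )
            except ValueError:
                fits[device] = None
        return fits

    # -- fit ---------------------------------------------------------------

    def fit(
        self,
        levels: tuple[str, ...] = ("signal", "parameter", "event"),
        channels: tuple[str, ...] = ("eda", "cva"),
    ) -> ValidityResults:
        cfg = self.config
        self._exclusions: Counter = Counter()
        feats: list[_ParticipantFeatures] = []
        for rec in self.recordings:
            f = _ParticipantFeatures(recording=rec)
            if "eda" in channels:
                self._eda_features(rec, f)
            if "cva" in channels:
                self._cva_features(rec, f)
            feats.append(f)

        nonresponders = [
            f.recording.participant_id for f in feats if f.nonresponder
        ]
        for f in feats:
            if f.nonresponder:
                log.info(
                    "excluding %s (%s)",
                    f.recording.participant_id, f.nonresponder_reason,
                )
        self._exclusions["nonresponders"] = len(nonresponders)
        kept = [f for f in feats if not f.nonresponder]

        results = ValidityResults(
            config=cfg,
            n_recordings=len(self.recordings),
            levels=tuple(levels),
            channels=tuple(channels),
            nonresponders=nonresponders,
        )
        if not kept:
            raise ValueError("every participant was excluded as a nonresponder")

        if "signal" in levels and "eda" in channels:
            results.signal = self._signal_level(kept)
        if "parameter" in levels:
            results.parameters = self._parameter_level(kept, tuple(channels))
        if "event" in levels:
            if "eda" in channels:
                s, c, v = self._event_level_eda(kept)
                if s:
                    results.event_summaries["eda"] = s
                    results.event_comparisons["eda"] = c
                    results.event_verdicts["eda"] = v
                results.habituation = self._habituation(kept)
            if "cva" in channels:
                s, c, v = self._event_level_cva(kept)
                if s:
                    results.event_summaries["cva"] = s
                    results.event_comparisons["cva"] = c
                    results.event_verdicts["cva"] = v

        results.exclusions = self._exclusions
        param_verdicts = {
            name: entry["verdict"] for name, entry in results.parameters.items()
        }
        event_verdicts = {
            f"{channel}:{task}": ev
            for channel, verd in results.event_verdicts.items()
            for task, ev in verd.items()
        }
        if results.signal is not None or param_verdicts or event_verdicts:
            results.verdict = assemble_verdict(
                results.signal, param_verdicts, event_verdicts,
                config_hash=cfg.hash(),
            )
        return results
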