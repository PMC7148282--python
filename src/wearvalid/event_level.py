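"""Event-level agreement: stressor detection, difference analysis and
habituation fitting.

The event level asks whether the wearable detects the same physiological
change as the reference device.  Per task, a cohort summary (mean +- SE) is
formed for each device; an effect is "detected" when the baseline and task
error bars do not overlap.  When both devices detect the effect, the
per-participant differences (wearable - reference) are summarised and must
(a) cross zero within one SE and (b) stay inside the reference effect — the
baseline-to-task change measured by the reference device — for the task to
count as valid.  Repeated identical stimuli additionally yield a
habituation estimate: a log-linear fit of per-stimulus mean response
amplitude against stimulus index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats


class Effect(str, Enum):
    DETECTED = "detected"
    NOT_DETECTED = "not_detected"
    INCONCLUSIVE = "inconclusive"   # fewer than 3 participants


class EventStatus(str, Enum):
    VALID = "valid"
    INVALID = "invalid"
    INCONCLUSIVE = "inconclusive"             # RD shows no effect
    INCONCLUSIVE_DATA = "inconclusive_data"   # not enough wearable data


@dataclass
class TaskSummary:
    """Cohort mean +- SE of one parameter for one task and device."""

    task: str
    device: str                              # "rd" | "wd"
    per_participant: dict[str, float]
    mean: float | None = None
    se: float | None = None
    n_available: int = 0

    def __post_init__(self) -> None:
        vals = np.array(
            [v for v in self.per_participant.values() if v is not None and not np.isnan(v)],
            dtype=float,
        )
        self.n_available = len(vals)
        if self.n_available:
            self.mean = float(vals.mean())
            self.se = (
                float(vals.std(ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1
                else 0.0
            )

    def interval(self, k: float = 1.0) -> tuple[float, float]:
        return (self.mean - k * self.se, self.mean + k * self.se)


@dataclass
class EventComparison:
    """Wearable-minus-reference differences for one task."""

    task: str
    diffs: dict[str, float]
    ref_effect: float
    diff_mean: float | None = None
    diff_se: float | None = None
    crosses_zero: bool = False
    within_boundary: bool = False
    n: int = 0

    def __post_init__(self) -> None:
        vals = np.array(
            [v for v in self.diffs.values() if v is not None and not np.isnan(v)],
            dtype=float,
        )
        self.n = len(vals)
        if self.n:
            self.diff_mean = float(vals.mean())
            self.diff_se = (
                float(vals.std(ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1
                else 0.0
            )
            lo = self.diff_mean - self.diff_se
            hi = self.diff_mean + self.diff_se
            self.crosses_zero = lo <= 0 <= hi
            self.within_boundary = (
                -self.ref_effect <= lo and hi <= self.ref_effect
            )


@dataclass
class HabituationFit:
    """Per-stimulus exponential decay of the response amplitude."""

    decay_rate: float            # proportion lost per stimulus
    intercept: float             # fitted amplitude at the first stimulus
    n_stimuli: int
    ci: tuple[float, float]


@dataclass
class EventVerdict:
    task: str
    status: EventStatus
    reasons: list[str] = field(default_factory=list)


def detect_effect(
    baseline: TaskSummary, task: TaskSummary, se_multiplier: float = 1.0
) -> Effect:
    """Effect detected iff the mean +- SE bars of baseline and task are disjoint.

    Deliberately the protocol's informal criterion rather than a t-test;
    with fewer than 3 participants on either side the comparison is
    inconclusive.
    """
    if baseline.device != task.device:
        raise ValueError("summaries must come from the same device")
    if baseline.n_available < 3 or task.n_available < 3:
        return Effect.INCONCLUSIVE
    b_lo, b_hi = baseline.interval(se_multiplier)
    t_lo, t_hi = task.interval(se_multiplier)
    disjoint = t_lo > b_hi or t_hi < b_lo
    return Effect.DETECTED if disjoint else Effect.NOT_DETECTED


def reference_effect(baseline_rd: TaskSummary, task_rd: TaskSummary) -> float:
    """|task mean - baseline mean| on the reference device."""
    if baseline_rd.mean is None or task_rd.mean is None:
        raise ValueError("reference effect requires RD data on both sides")
    return abs(task_rd.mean - baseline_rd.mean)


def event_decision(
    task: str,
    rd_effect: Effect,
    wd_effect: Effect,
    comparison: EventComparison | None,
) -> EventVerdict:
    """Ordered decision rules for one task.

    1. RD shows no effect -> inconclusive (no further inferences possible).
    2. RD detects, wearable does not -> invalid.
    3. Both detect -> invalid if the difference bar misses zero or exceeds
       the reference effect, else valid.
    4. Insufficient wearable data -> inconclusive_data.
    """
    if rd_effect == Effect.INCONCLUSIVE:
        return EventVerdict(
            task,
            EventStatus.INCONCLUSIVE_DATA,
            ["insufficient reference-device data for this task"],
        )
    if rd_effect == Effect.NOT_DETECTED:
        return EventVerdict(
            task,
            EventStatus.INCONCLUSIVE,
            ["reference device shows no effect: no further inferences"],
        )
    if wd_effect == Effect.INCONCLUSIVE:
        return EventVerdict(
            task,
            EventStatus.INCONCLUSIVE_DATA,
            ["insufficient wearable data for this task"],
        )
    if wd_effect == Effect.NOT_DETECTED:
        return EventVerdict(
            task,
            EventStatus.INVALID,
            ["wearable misses the effect the reference device detects"],
        )
    if comparison is None or comparison.n < 3:
        return EventVerdict(
            task,
            EventStatus.INCONCLUSIVE_DATA,
            ["too few paired participants to compare devices"],
        )
    if not comparison.crosses_zero:
        return EventVerdict(
            task,
            EventStatus.INVALID,
            [
                "difference bar misses zero: devices disagree "
                f"(mean {comparison.diff_mean:.3g} +- {comparison.diff_se:.3g})"
            ],
        )
    if not comparison.within_boundary:
        return EventVerdict(
            task,
            EventStatus.INVALID,
            [
                "difference bar exceeds the reference effect "
                f"+-{comparison.ref_effect:.3g}"
            ],
        )
    return EventVerdict(
        task,
        EventStatus.VALID,
        ["both devices detect the effect and agree within the reference effect"],
    )


def fit_habituation(
    beep_means: list[float] | np.ndarray,
    floor: float = 1e-4,
    alpha: float = 0.05,
) -> HabituationFit:
    """Ordinary least squares of log amplitude on stimulus index.

    ``decay_rate = 1 - exp(slope)`` so a slope of log(0.96) corresponds to a
    4% loss per stimulus; the CI comes from the slope's standard error.
    Zero or negative means are floored before the log.
    """
    y = np.asarray(beep_means, dtype=float)
    y = y[~np.isnan(y)]
    if len(y) < 3:
        raise ValueError("habituation fit needs >= 3 stimulus means")
    y = np.maximum(y, floor)
    idx = np.arange(len(y), dtype=float)
    fit = stats.linregress(idx, np.log(y))
    tq = stats.t.ppf(1 - alpha / 2, len(y) - 2)
    lo_slope = fit.slope - tq * fit.stderr
    hi_slope = fit.slope + tq * fit.stderr
    ci = (1.0 - np.exp(hi_slope), 1.0 - np.exp(lo_slope))
    return HabituationFit(
        decay_rate=float(1.0 - np.exp(fit.slope)),
        intercept=float(np.exp(fit.intercept)),
        n_stimuli=len(y),
        ci=(float(ci[0]), float(ci[1])),
    )
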