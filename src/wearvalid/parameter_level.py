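"""Parameter-level agreement: a-priori boundaries and Bland-Altman analysis.

The acceptance boundary for each parameter is fixed *before* looking at the
data as 10% of its biologically plausible range (the heart-rate standard of
+-5 bpm is exactly 10% of the seated 60-110 bpm range; the same fraction is
extended to the other parameters).  Differences are taken wearable minus
reference, one point per participant; the limits of agreement are
mean +- 1.96 SD.  A parameter is judged valid when both limits of agreement
fall inside the a-priori boundary; an additional bias flag is raised when
the confidence interval of the mean difference excludes zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats


class Parameter(str, Enum):
    SCL = "scl"
    SCR_RATE = "scr_rate"
    S_AMPL = "s_ampl"
    HR = "hr"
    SD_INTERVAL = "sd_interval"
    RMSSD = "rmssd"


PARAMETER_UNITS = {
    Parameter.SCL: "uS",
    Parameter.SCR_RATE: "SCR/min",
    Parameter.S_AMPL: "uS",
    Parameter.HR: "bpm",
    Parameter.SD_INTERVAL: "s",
    Parameter.RMSSD: "s",
}


@dataclass(frozen=True)
class AgreementBoundary:
    """A-priori acceptance band: fraction x (plausible_max - plausible_min)."""

    parameter: Parameter
    plausible_min: float
    plausible_max: float
    fraction: float = 0.10
    boundary: float = 0.0
    rounding: int = 2


def _round_half_away(value: float, decimals: int) -> float:
    scale = 10**decimals
    return math.copysign(math.floor(abs(value) * scale + 0.5), value) / scale


def derive_boundary(
    parameter: Parameter | str,
    plausible_min: float,
    plausible_max: float,
    fraction: float = 0.10,
    rounding: int = 2,
) -> AgreementBoundary:
    """Boundary = round(fraction x plausible range width).

    Rounds half away from zero, matching the published boundary values
    (e.g. 10% of a 0-0.56 s range gives 0.056 -> 0.06 s).
    """
    parameter = Parameter(parameter)
    width = plausible_max - plausible_min
    if width <= 0:
        raise ValueError(
            f"{parameter.value}: plausible range has non-positive width"
        )
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    boundary = _round_half_away(fraction * width, rounding)
    if boundary <= 0:
        raise ValueError(f"{parameter.value}: derived boundary is not positive")
    return AgreementBoundary(
        parameter=parameter,
        plausible_min=plausible_min,
        plausible_max=plausible_max,
        fraction=fraction,
        boundary=boundary,
        rounding=rounding,
    )


@dataclass
class BlandAltmanResult:
    """Paired-difference statistics for one parameter."""

    parameter: Parameter
    pairs: pd.DataFrame           # participant, rd, wd, mean, diff
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pct_within_boundary: float
    pct_within_loa: float
    n: int
    n_dropped: int                # pairs missing on either side
    transform: str                # none | log
    normality_p_raw: float | None
    normality_p_transformed: float | None
    mean_diff_ci: tuple[float, float]


@dataclass
class ParameterVerdict:
    """valid / invalid plus an independent bias flag and diagnostics."""

    parameter: Parameter
    status: str                   # valid | invalid
    biased: bool
    reasons: list[str] = field(default_factory=list)
    slope: float | None = None
    slope_p: float | None = None


def _normality_p(diffs: np.ndarray) -> float | None:
    if len(diffs) < 3 or np.ptp(diffs) < 1e-12:
        return None
    if len(diffs) <= 5000:
        return float(stats.shapiro(diffs).pvalue)
    return float(stats.normaltest(diffs).pvalue)


def bland_altman(
    pairs: pd.DataFrame,
    boundary: AgreementBoundary,
    transform_policy: str = "auto",
    log_offset: float = 1e-3,
) -> BlandAltmanResult:
    """Bland-Altman construction on raw-scale differences (wearable - reference).

    ``pairs`` needs columns ``participant``, ``rd``, ``wd``; rows missing
    either side are dropped and counted.  Normality of the differences is
    assessed (Shapiro for n <= 5000, omnibus test beyond); when rejected
    and the policy allows, a log transform ``log(v + offset)`` is applied
    *for the normality report only* — the statistics and the verdict stay
    in raw units, because the a-priori boundaries are in raw units.
    """
    df = pairs.copy()
    total = len(df)
    df = df.dropna(subset=["rd", "wd"])
    n = len(df)
    if n < 3:
        raise ValueError(f"Bland-Altman requires >= 3 complete pairs, got {n}")
    diffs = (df["wd"] - df["rd"]).to_numpy(dtype=float)
    means = ((df["wd"] + df["rd"]) / 2.0).to_numpy(dtype=float)
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    loa_low = mean_diff - 1.96 * sd_diff
    loa_high = mean_diff + 1.96 * sd_diff
    pct_boundary = 100.0 * float(
        np.count_nonzero(np.abs(diffs) <= boundary.boundary + 1e-12)
    ) / n
    pct_loa = 100.0 * float(
        np.count_nonzero((diffs >= loa_low - 1e-12) & (diffs <= loa_high + 1e-12))
    ) / n
    p_raw = _normality_p(diffs)
    transform = "none"
    p_trans = None
    if (
        transform_policy == "auto"
        and p_raw is not None
        and p_raw < 0.05
    ):
        shift = min(df["rd"].min(), df["wd"].min())
        offset = log_offset + max(0.0, -shift)
        log_diffs = np.log(df["wd"] + offset) - np.log(df["rd"] + offset)
        p_trans = _normality_p(log_diffs.to_numpy(dtype=float))
        transform = "log"
    if n > 1 and sd_diff > 0:
        se = sd_diff / np.sqrt(n)
        tq = stats.t.ppf(0.975, n - 1)
        ci = (mean_diff - tq * se, mean_diff + tq * se)
    else:
        ci = (mean_diff, mean_diff)
    out = df.assign(mean=means, diff=diffs)
    return BlandAltmanResult(
        parameter=boundary.parameter,
        pairs=out,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        pct_within_boundary=pct_boundary,
        pct_within_loa=pct_loa,
        n=n,
        n_dropped=total - n,
        transform=transform,
        normality_p_raw=p_raw,
        normality_p_transformed=p_trans,
        mean_diff_ci=ci,
    )


def parameter_decision(
    result: BlandAltmanResult, boundary: AgreementBoundary
) -> ParameterVerdict:
    """Valid iff both limits of agreement lie inside [-boundary, +boundary].

    The bias flag is independent of validity: it is raised when the 95% CI
    of the mean difference excludes zero (systematic over/underestimation).
    A proportional-bias diagnostic (slope of difference vs mean) is reported
    but does not enter the verdict.
    """
    b = boundary.boundary
    within = -b <= result.loa_low and result.loa_high <= b
    status = "valid" if within else "invalid"
    lo, hi = result.mean_diff_ci
    biased = not (lo <= 0 <= hi)
    reasons = [
        f"limits of agreement ({result.loa_low:.3g}, {result.loa_high:.3g}) "
        f"{'inside' if within else 'outside'} a-priori boundary +-{b:g}"
    ]
    if biased:
        direction = "over" if result.mean_diff > 0 else "under"
        reasons.append(
            f"mean difference CI ({lo:.3g}, {hi:.3g}) excludes 0: "
            f"wearable {direction}estimates"
        )
    slope = slope_p = None
    if result.n >= 3 and np.ptp(result.pairs["mean"].to_numpy()) > 0:
        fit = stats.linregress(result.pairs["mean"], result.pairs["diff"])
        slope, slope_p = float(fit.slope), float(fit.pvalue)
        if slope_p < 0.05:
            reasons.append(
                f"difference grows with magnitude (slope {slope:.3g}, "
                f"p = {slope_p:.3g})"
            )
    return ParameterVerdict(
        parameter=result.parameter,
        status=status,
        biased=biased,
        reasons=reasons,
        slope=slope,
        slope_p=slope_p,
    )
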