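"""Signal-level agreement: lagged cross-correlation between paired signals.

Level 1 of the protocol compares the conditioned (resampled, detrended,
z-normalized) wearable and reference signals with a Pearson correlation at
every integer lag in ``[-max_lag, +max_lag]`` (default 8; at 16 Hz a lag of
8 is 0.5 s, covering the wrist-to-finger sympathetic conduction delay with
margin).  The cohort passes when every participant's best correlation
exceeds the criterion (default .80).  Correlation is computed explicitly on
the overlapping non-missing samples at each lag rather than via FFT, so
missing data and edge effects are handled transparently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import TimeSeries

MIN_OVERLAP = 10  # samples required for a lag to be evaluated


@dataclass
class CrossCorrResult:
    """Correlation-by-lag for one participant."""

    participant_id: str
    lags: np.ndarray
    r_by_lag: np.ndarray
    best_lag: int
    best_r: float
    fs: float


@dataclass
class SignalVerdict:
    """Cohort-level signal verdict: pass iff every best_r > threshold."""

    per_participant: list[CrossCorrResult]
    threshold: float
    systematic_lag: int | None
    passed: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class BiasReport:
    """Mean / variance bias between two signals judged similar."""

    mean_diff: float
    mean_diff_ci: tuple[float, float]
    variance_ratio: float
    variance_ratio_ci: tuple[float, float]
    n: int


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa = a - a.mean()
    sb = b - b.mean()
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0:
        return np.nan
    return float((sa @ sb) / denom)


def cross_correlation_lags(
    x: TimeSeries,
    y: TimeSeries,
    max_lag: int = 8,
    participant_id: str = "",
) -> CrossCorrResult:
    """Pearson correlation between ``x[t]`` and ``y[t + k]`` per lag ``k``.

    Lags with fewer than 10 overlapping non-missing pairs are marked
    not-available (NaN).  The best lag maximises r; ties break toward the
    smallest absolute lag, then toward the negative lag.
    """
    if not np.isclose(x.fs, y.fs):
        raise ValueError(f"sampling rates differ: {x.fs} vs {y.fs} Hz")
    xv, yv = x.values, y.values
    n = min(len(xv), len(yv))
    xv, yv = xv[:n], yv[:n]
    lags = np.arange(-max_lag, max_lag + 1)
    rs = np.full(len(lags), np.nan)
    for i, k in enumerate(lags):
        if k >= 0:
            a, b = xv[: n - k] if k else xv, yv[k:]
        else:
            a, b = xv[-k:], yv[: n + k]
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < MIN_OVERLAP:
            continue
        rs[i] = _pearson(a[ok], b[ok])
    if np.isnan(rs).all():
        raise ValueError("no lag had enough overlapping samples")
    best = np.nanmax(rs)
    tied = [int(k) for k, r in zip(lags, rs) if r == best]
    best_lag = min(tied, key=lambda k: (abs(k), k))
    return CrossCorrResult(
        participant_id=participant_id,
        lags=lags,
        r_by_lag=rs,
        best_lag=best_lag,
        best_r=float(best),
        fs=float(x.fs),
    )


def lag_duration(lag: int, fs: float) -> float:
    """Convert an integer lag to seconds: lag / fs."""
    if not fs > 0:
        raise ValueError("fs must be positive")
    return lag / fs


def cohort_signal_decision(
    results: list[CrossCorrResult], threshold: float = 0.80
) -> SignalVerdict:
    """Pass iff all best correlations exceed ``threshold``.

    A systematic lag is reported when more than half the participants share
    the same best lag; otherwise the optimal lag differs per participant
    and no correction is warranted.
    """
    if not results:
        raise ValueError("signal decision requires at least one participant")
    failing = [r for r in results if not r.best_r > threshold]
    passed = not failing
    lags = [r.best_lag for r in results]
    values, counts = np.unique(lags, return_counts=True)
    systematic = None
    top = counts.argmax()
    if counts[top] > 0.5 * len(lags):
        systematic = int(values[top])
    reasons = []
    if passed:
        reasons.append(
            f"all {len(results)} participants have best r > {threshold:.2f}"
        )
    else:
        worst = min(failing, key=lambda r: r.best_r)
        reasons.append(
            f"{len(failing)} of {len(results)} participants at or below "
            f"r = {threshold:.2f} (worst: {worst.participant_id} "
            f"r = {worst.best_r:.3f})"
        )
    if systematic is not None:
        reasons.append(f"systematic lag {systematic:+d} shared by majority")
    return SignalVerdict(
        per_participant=results,
        threshold=threshold,
        systematic_lag=systematic,
        passed=passed,
        reasons=reasons,
    )


def mean_bias_adjust(
    x: TimeSeries, y: TimeSeries, verdict: SignalVerdict, alpha: float = 0.05
) -> tuple[TimeSeries, BiasReport]:
    """Centre/rescale ``y`` onto ``x`` after a passing signal verdict.

    Reports the mean difference (y - x) with a t confidence interval and
    the variance ratio var(y)/var(x) with an F interval, then returns ``y``
    re-centred and re-scaled to x's mean and variance.  Refused when the
    cohort did not pass the correlation criterion: with low correlation the
    source of disagreement cannot be attributed to a simple bias.
    """
    if not verdict.passed:
        raise RuntimeError(
            "bias adjustment refused: the cohort did not pass the "
            "signal-level correlation criterion"
        )
    n = min(x.n, y.n)
    ok = (~np.isnan(x.values[:n])) & (~np.isnan(y.values[:n]))
    xv, yv = x.values[:n][ok], y.values[:n][ok]
    m = len(xv)
    diff = yv - xv
    mean_diff = float(diff.mean())
    se = diff.std(ddof=1) / np.sqrt(m) if m > 1 else np.nan
    tq = stats.t.ppf(1 - alpha / 2, m - 1) if m > 1 else np.nan
    ci = (mean_diff - tq * se, mean_diff + tq * se)
    vx, vy = xv.var(ddof=1), yv.var(ddof=1)
    ratio = float(vy / vx) if vx > 0 else np.inf
    fq_lo = stats.f.ppf(alpha / 2, m - 1, m - 1)
    fq_hi = stats.f.ppf(1 - alpha / 2, m - 1, m - 1)
    ratio_ci = (ratio / fq_hi, ratio / fq_lo)
    sd_y = yv.std(ddof=1)
    scale = xv.std(ddof=1) / sd_y if sd_y > 0 else 1.0
    adjusted = (y.values - yv.mean()) * scale + xv.mean()
    report = BiasReport(
        mean_diff=mean_diff,
        mean_diff_ci=ci,
        variance_ratio=ratio,
        variance_ratio_ci=ratio_ci,
        n=m,
    )
    return y.with_values(adjusted), report
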