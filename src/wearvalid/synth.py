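"""Synthetic paired-recording generator.

Emulates the validation experiment the protocol was designed for: a
sing-a-song stress test (four 40-s neutral messages as baseline, 30 s
anticipation, 30 s singing, 2 min recovery) followed by a noise task
(26 beeps of 200 ms in a 5-min block, onsets at least 7 s apart, 2 min
recovery).  The reference device records EDA at 256 Hz and ECG-derived
beat times; the wearable records EDA at 4 Hz and PPG-derived beat times.

EDA is tonic level + slow drift + trough-to-peak SCR kernels
(bi-exponential rise/decay) + Gaussian sensor noise.  Stress blocks
(anticipation, singing) multiply SCR rate and amplitude; each beep places a
response whose amplitude decays geometrically with stimulus index
(habituation).  The wearable sees the reference event stream thinned by a
per-SCR response probability (wrist sites register only a fraction of
finger SCRs), attenuated, optionally lagged, and independently re-noised.

Beat intervals follow an AR(1) process calibrated so the sample mean HR,
SD and RMSSD hit their targets; the singing block shifts HR by a
configurable delta.  The wearable beat stream is the reference stream plus
timing jitter, with burst dropouts covering a configurable fraction of the
recording (PPG signal loss).

All randomness flows from a single integer seed; identical seeds produce
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    Block,
    BlockKind,
    Channel,
    EventSchedule,
    PairedRecording,
    TimeSeries,
)

SCR_TAU_RISE = 0.75   # s, kernel rise time constant
SCR_TAU_DECAY = 2.0   # s, kernel decay time constant
EDA_COMPARISON_FS = 16.0  # Hz grid in which wearable_lag is counted


@dataclass
class EDAGenConfig:
    fs_rd: float = 256.0
    fs_wd: float = 4.0
    baseline_scl: float = 4.0          # uS, cohort mean tonic level
    scl_between_sd: float = 1.0        # uS, between-participant SD
    drift_amp: float = 0.3             # uS, slow tonic drift amplitude
    scr_rate_per_min: float = 3.0
    scr_refractory: float = 3.0        # s, minimum gap between SCR onsets
    scr_amp_mean: float = 0.4          # uS
    scr_amp_sd: float = 0.15           # uS
    wearable_attenuation: float = 0.5  # amplitude factor at the wrist
    wearable_lag: int = 0              # samples at 16 Hz (positive: wd later)
    noise_sd: float = 0.01             # uS
    nonresponder_fraction: float = 0.22
    response_prob: float = 0.3         # P(wrist registers a finger SCR)
    beep_attenuation: float | None = None   # defaults to wearable_attenuation
    beep_response_prob: float | None = None  # defaults to response_prob
    shared_tonic: bool = False         # wearable shares the reference drift


@dataclass
class CVAGenConfig:
    mean_hr: float = 70.0              # bpm
    hr_between_sd: float = 4.0         # bpm between participants
    sd_interval: float = 0.05          # s, target interval SD
    rmssd_target: float = 0.04         # s
    ppg_dropout_fraction: float = 0.45
    dropout_burst_len: float = 10.0    # s, mean burst length
    jitter_sd: float = 0.003           # s, wearable beat timing jitter


@dataclass
class EffectsConfig:
    ssst_ampl_multiplier: float = 2.2  # SCR rate and amplitude factor
    ssst_hr_delta: float = 19.8        # bpm added while singing
    beep_response_amp: float = 0.4     # uS, first-beep SCR amplitude
    habituation_rate: float = 0.04     # proportional decay per stimulus
    beep_delay: tuple[float, float] = (1.0, 2.0)  # s, onset after the beep
    beep_amp_cv: float = 0.3           # lognormal sigma of beep amplitudes


@dataclass
class ScheduleConfig:
    ssst_baseline: float = 160.0       # four 40-s neutral messages
    anticipation: float = 30.0
    singing: float = 30.0
    ssst_recovery: float = 120.0
    n_beeps: int = 26
    min_gap: float = 7.0               # s between beep onsets
    task_len: float = 300.0            # s, noise block
    noise_recovery: float = 120.0
    beep_duration: float = 0.2


@dataclass
class SynthConfig:
    seed: int
    n_participants: int = 60
    eda: EDAGenConfig = field(default_factory=EDAGenConfig)
    cva: CVAGenConfig = field(default_factory=CVAGenConfig)
    effects: EffectsConfig = field(default_factory=EffectsConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    with_eda: bool = True
    with_cva: bool = True


# ---------------------------------------------------------------------------
# presets for the verdict paths the protocol must distinguish
# ---------------------------------------------------------------------------


def e4_like(seed: int, n_participants: int = 60) -> SynthConfig:
    """Default: a wrist wearable with attenuated, thinned EDA and PPG dropouts."""
    return SynthConfig(seed=seed, n_participants=n_participants)


def perfect_agreement(seed: int, n_participants: int = 12) -> SynthConfig:
    """Degenerate condition: the wearable reproduces the reference exactly.

    Same grid, shared tonic, unit attenuation, zero lag/noise/jitter/
    dropout — the device-difference at every level is identically zero.
    """
    return SynthConfig(
        seed=seed,
        n_participants=n_participants,
        eda=EDAGenConfig(
            fs_wd=256.0,
            wearable_attenuation=1.0,
            wearable_lag=0,
            noise_sd=0.0,
            nonresponder_fraction=0.0,
            response_prob=1.0,
            shared_tonic=True,
        ),
        cva=CVAGenConfig(ppg_dropout_fraction=0.0, jitter_sd=0.0),
    )


def attenuated_beeps(seed: int, n_participants: int = 12) -> SynthConfig:
    """Wrist insensitive to small beep stimuli but faithful for block SCRs.

    Everything except the beep responses duplicates the reference exactly,
    isolating the event-level deficit: the wearable registers only ~30% of
    beep responses at a tenth of their amplitude.
    """
    return SynthConfig(
        seed=seed,
        n_participants=n_participants,
        eda=EDAGenConfig(
            fs_wd=256.0,
            wearable_attenuation=1.0,
            noise_sd=0.0,
            nonresponder_fraction=0.0,
            response_prob=1.0,
            beep_attenuation=0.1,
            beep_response_prob=0.3,
            shared_tonic=True,
        ),
        cva=CVAGenConfig(ppg_dropout_fraction=0.0, jitter_sd=0.0),
    )


def high_dropout(seed: int, n_participants: int = 12) -> SynthConfig:
    """Severe PPG signal loss on short blocks (event level starves)."""
    return SynthConfig(
        seed=seed,
        n_participants=n_participants,
        eda=EDAGenConfig(nonresponder_fraction=0.0),
        cva=CVAGenConfig(ppg_dropout_fraction=0.74),
    )


def calibration(seed: int, n_participants: int = 60) -> SynthConfig:
    """Stationary generator (stress effects off) for parameter recovery."""
    return SynthConfig(
        seed=seed,
        n_participants=n_participants,
        eda=EDAGenConfig(
            wearable_attenuation=1.0,
            nonresponder_fraction=0.0,
            response_prob=1.0,
            shared_tonic=True,
        ),
        cva=CVAGenConfig(ppg_dropout_fraction=0.0),
        effects=EffectsConfig(
            ssst_ampl_multiplier=1.0, ssst_hr_delta=0.0, beep_response_amp=0.0
        ),
    )


PRESETS = {
    "e4_like": e4_like,
    "perfect_agreement": perfect_agreement,
    "attenuated_beeps": attenuated_beeps,
    "high_dropout": high_dropout,
    "calibration": calibration,
}


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------


def generate_schedule(
    cfg: SynthConfig, rng: np.random.Generator, participant_id: str = ""
) -> EventSchedule:
    """SSST blocks followed by the noise task with randomized beep onsets.

    Beep onsets keep at least ``min_gap`` seconds between each other and
    leave room for the response window after the last beep; the remaining
    slack is spread Dirichlet-uniformly, giving irregular, pattern-free
    timing.  Infeasible constraints raise.
    """
    s = cfg.schedule
    lead, tail = 5.0, s.min_gap
    needed = (s.n_beeps - 1) * s.min_gap + lead + tail
    if needed >= s.task_len:
        raise ValueError(
            f"cannot place {s.n_beeps} beeps with gaps >= {s.min_gap} s in a "
            f"{s.task_len} s block ({needed:.0f} s needed)"
        )
    t = 0.0
    blocks: list[Block] = []

    def add(label: str, kind: BlockKind, dur: float) -> None:
        nonlocal t
        blocks.append(Block(label, kind, t, t + dur))
        t += dur

    add("baseline", BlockKind.BASELINE, s.ssst_baseline)
    add("anticipation", BlockKind.ANTICIPATION, s.anticipation)
    add("singing", BlockKind.STRESSOR, s.singing)
    add("recovery", BlockKind.RECOVERY, s.ssst_recovery)
    noise_start = t
    add("noise", BlockKind.STRESSOR, s.task_len)
    add("noise_recovery", BlockKind.RECOVERY, s.noise_recovery)

    slack = s.task_len - needed
    extra = rng.dirichlet(np.ones(s.n_beeps)) * slack
    onset = noise_start + lead + extra[0]
    for j in range(s.n_beeps):
        if j:
            onset += s.min_gap + extra[j]
        blocks.append(
            Block(
                f"beep_{j + 1:02d}",
                BlockKind.BEEP,
                onset,
                onset + s.beep_duration,
            )
        )
    return EventSchedule(participant_id=participant_id, blocks=blocks)


# ---------------------------------------------------------------------------
# EDA
# ---------------------------------------------------------------------------


def scr_kernel(t: np.ndarray) -> np.ndarray:
    """Bi-exponential SCR shape, unit peak amplitude, zero before onset."""
    tr, td = SCR_TAU_RISE, SCR_TAU_DECAY
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    out = np.where(t >= 0, (np.exp(-t / td) - np.exp(-t / tr)) / peak, 0.0)
    return out


def _render_eda(
    grid_start: float,
    fs: float,
    duration: float,
    tonic_level: float,
    drift_phase: tuple[float, float],
    drift_amp: float,
    events: list[tuple[float, float]],
    noise_sd: float,
    rng: np.random.Generator,
) -> TimeSeries:
    n = int(round(duration * fs))
    t = grid_start + np.arange(n) / fs
    p1, p2 = drift_phase
    v = tonic_level + drift_amp * (
        np.sin(2 * np.pi * t / 297.0 + p1)
        + 0.5 * np.sin(2 * np.pi * t / 131.0 + p2)
    )
    kernel_span = 12.0
    for onset, amp in events:
        i0 = max(int(np.ceil((onset - grid_start) * fs)), 0)
        i1 = min(int(np.ceil((onset - grid_start + kernel_span) * fs)), n)
        if i1 <= i0:
            continue
        v[i0:i1] += amp * scr_kernel(t[i0:i1] - onset)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=n)
    return TimeSeries(
        start_time=grid_start, fs=fs, values=v, units="uS", channel=Channel.EDA
    )


def _is_ssst_stress(block: Block, schedule: EventSchedule) -> bool:
    if block.kind == BlockKind.ANTICIPATION:
        return True
    if block.kind != BlockKind.STRESSOR:
        return False
    return not any(
        block.onset <= bp.onset < block.offset for bp in schedule.beeps
    )


def simulate_eda_pair(
    cfg: SynthConfig,
    schedule: EventSchedule,
    rng: np.random.Generator,
    nonresponder: bool = False,
    return_truth: bool = False,
):
    """One participant's paired EDA recordings (reference 256 Hz, wearable 4 Hz)."""
    e, fx = cfg.eda, cfg.effects
    span = schedule.span
    duration = span[1] - span[0] + 8.0
    scl = max(0.5, rng.normal(e.baseline_scl, e.scl_between_sd))
    # mean-one participant random effects
    rate_scale = rng.lognormal(-0.15**2 / 2, 0.15)
    amp_scale = rng.lognormal(-0.15**2 / 2, 0.15)
    phases = (rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi))
    wd_phases = (
        phases
        if e.shared_tonic
        else (rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi))
    )

    events: list[tuple[float, float, bool]] = []  # (onset, amplitude, is_beep)
    if not nonresponder:
        for block in schedule.blocks:
            if block.kind == BlockKind.BEEP:
                continue
            mult = fx.ssst_ampl_multiplier if _is_ssst_stress(block, schedule) else 1.0
            rate = e.scr_rate_per_min * rate_scale * mult / 60.0
            # renewal process with a refractory gap: responses closer than
            # the refractory superpose into compound SCRs that trough-to-peak
            # scoring cannot (and should not) resolve
            mean_gap = 1.0 / rate if rate > 0 else np.inf
            exp_mean = max(mean_gap - e.scr_refractory, 0.1)
            t_ev = block.onset + rng.exponential(exp_mean)
            while t_ev < block.offset:
                amp = max(
                    0.05, rng.normal(e.scr_amp_mean, e.scr_amp_sd)
                ) * amp_scale * mult
                events.append((float(t_ev), float(amp), False))
                t_ev += e.scr_refractory + rng.exponential(exp_mean)
        for j, beep in enumerate(schedule.beeps):
            if fx.beep_response_amp <= 0:
                break
            delay = rng.uniform(*fx.beep_delay)
            amp = (
                fx.beep_response_amp
                * (1.0 - fx.habituation_rate) ** j
                * amp_scale
                * rng.lognormal(0.0, fx.beep_amp_cv)
            )
            events.append((float(beep.onset + delay), float(amp), True))
    events.sort()

    beep_att = e.beep_attenuation if e.beep_attenuation is not None else e.wearable_attenuation
    beep_prob = e.beep_response_prob if e.beep_response_prob is not None else e.response_prob
    lag_s = e.wearable_lag / EDA_COMPARISON_FS
    wd_events = []
    for onset, amp, is_beep in events:
        prob = beep_prob if is_beep else e.response_prob
        if rng.uniform() < prob:
            att = beep_att if is_beep else e.wearable_attenuation
            wd_events.append((onset + lag_s, amp * att, is_beep))

    # sensor noise is white: per-sample sigma scales with sqrt(bandwidth),
    # so the slow wearable grid sees proportionally less sample noise
    wd_noise = e.noise_sd * float(np.sqrt(e.fs_wd / e.fs_rd))
    rd = _render_eda(
        span[0], e.fs_rd, duration, scl, phases, e.drift_amp,
        [(o, a) for o, a, _ in events], e.noise_sd, rng,
    )
    wd = _render_eda(
        span[0], e.fs_wd, duration, scl, wd_phases, e.drift_amp,
        [(o, a) for o, a, _ in wd_events], wd_noise, rng,
    )
    if return_truth:
        truth = {"rd_events": events, "wd_events": wd_events, "scl": scl}
        return rd, wd, truth
    return rd, wd


# ---------------------------------------------------------------------------
# CVA
# ---------------------------------------------------------------------------


def _target_interval(t: float, schedule: EventSchedule, hr: float, delta: float) -> float:
    for b in schedule.blocks:
        if b.label == "singing" and b.onset <= t < b.offset:
            return 60.0 / (hr + delta)
    return 60.0 / hr


def simulate_cva_pair(
    cfg: SynthConfig,
    schedule: EventSchedule,
    rng: np.random.Generator,
):
    """Paired beat-time arrays (reference ECG-like, wearable PPG-like).

    Intervals follow an AR(1) process: with autocorrelation
    phi = 1 - RMSSD^2 / (2 SD^2) the stationary SD and the expected RMSSD
    match their targets.  Wearable beats are the reference beats plus
    Gaussian timing jitter, thinned by exponential-length dropout bursts
    covering the configured fraction of the recording.
    """
    c, fx = cfg.cva, cfg.effects
    span = schedule.span
    duration = span[1] - span[0] + 5.0
    hr = max(45.0, rng.normal(c.mean_hr, c.hr_between_sd))
    var_scale = rng.lognormal(-0.10**2 / 2, 0.10)
    sd = c.sd_interval * var_scale
    rmssd = c.rmssd_target * var_scale
    phi = float(np.clip(1.0 - rmssd**2 / (2.0 * sd**2), 0.0, 0.999))
    e_sd = sd * np.sqrt(1.0 - phi**2)

    t = span[0] + rng.uniform(0.0, 1.0)
    mu_prev = _target_interval(t, schedule, hr, fx.ssst_hr_delta)
    x_prev = mu_prev
    beats = [t]
    while t < span[0] + duration:
        mu = _target_interval(t, schedule, hr, fx.ssst_hr_delta)
        x = mu + phi * (x_prev - mu_prev) + rng.normal(0.0, e_sd)
        x = float(np.clip(x, 0.35, 1.45))
        t += x
        beats.append(t)
        x_prev, mu_prev = x, mu
    rd_beats = np.array(beats)

    wd_beats = rd_beats.copy()
    if c.jitter_sd > 0:
        wd_beats = np.sort(wd_beats + rng.normal(0, c.jitter_sd, len(wd_beats)))
    if c.ppg_dropout_fraction > 0:
        f = c.ppg_dropout_fraction
        mean_bad = c.dropout_burst_len
        mean_good = mean_bad * (1.0 - f) / f
        keep = np.ones(len(wd_beats), dtype=bool)
        pos = span[0]
        bad = rng.uniform() < f
        while pos < span[0] + duration:
            seg = rng.exponential(mean_bad if bad else mean_good) + 0.5
            if bad:
                keep &= ~((wd_beats >= pos) & (wd_beats < pos + seg))
            pos += seg
            bad = not bad
        wd_beats = wd_beats[keep]
    return rd_beats, wd_beats


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def ecg_waveform(
    beat_times: np.ndarray,
    fs: float = 200.0,
    duration: float | None = None,
    start_time: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> TimeSeries:
    """Impulse-like R-wave train (narrow Gaussian spikes) for beat detection."""
    if duration is None:
        duration = float(beat_times[-1] - start_time + 1.0)
    n = int(round(duration * fs))
    t = start_time + np.arange(n) / fs
    v = np.zeros(n)
    width = 0.012
    for bt in beat_times:
        lo = max(int((bt - start_time - 5 * width) * fs), 0)
        hi = min(int((bt - start_time + 5 * width) * fs) + 1, n)
        v[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - bt) / width) ** 2)
    if noise_sd > 0 and rng is not None:
        v += rng.normal(0, noise_sd, n)
    return TimeSeries(start_time, fs, v, units="mV", channel=Channel.ECG)


def ppg_waveform(
    beat_times: np.ndarray,
    fs: float = 64.0,
    duration: float | None = None,
    start_time: float = 0.0,
    pulse_width: float = 0.35,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> TimeSeries:
    """Raised-cosine pulse train resembling a blood-volume-pulse signal."""
    if duration is None:
        duration = float(beat_times[-1] - start_time + 1.0)
    n = int(round(duration * fs))
    t = start_time + np.arange(n) / fs
    v = np.zeros(n)
    half = pulse_width / 2.0
    for bt in beat_times:
        lo = max(int((bt - start_time - half) * fs), 0)
        hi = min(int((bt - start_time + half) * fs) + 1, n)
        u = (t[lo:hi] - bt) / half
        v[lo:hi] += 0.5 * (1 + np.cos(np.pi * np.clip(u, -1, 1)))
    if noise_sd > 0 and rng is not None:
        v += rng.normal(0, noise_sd, n)
    return TimeSeries(start_time, fs, v, units="a.u.", channel=Channel.PPG)


def simulate_cohort(cfg: SynthConfig) -> list[PairedRecording]:
    """Generate the full cohort; all randomness flows from ``cfg.seed``."""
    if cfg.n_participants < 1:
        raise ValueError("need at least one participant")
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_participants + 2)
    sched_rng = np.random.default_rng(children[0])
    template = generate_schedule(cfg, sched_rng)
    pick_rng = np.random.default_rng(children[1])
    n_nonresp = int(round(cfg.eda.nonresponder_fraction * cfg.n_participants))
    nonresp = set(
        pick_rng.choice(cfg.n_participants, size=n_nonresp, replace=False)
    )
    recordings: list[PairedRecording] = []
    for i in range(cfg.n_participants):
        pid = f"p{i + 1:03d}"
        rng = np.random.default_rng(children[i + 2])
        schedule = EventSchedule(
            participant_id=pid, blocks=list(template.blocks)
        )
        rd: dict[str, TimeSeries] = {}
        wd: dict[str, TimeSeries] = {}
        rd_beats = wd_beats = None
        if cfg.with_eda:
            rd_eda, wd_eda = simulate_eda_pair(
                cfg, schedule, rng, nonresponder=i in nonresp
            )
            rd["eda"] = rd_eda
            wd["eda"] = wd_eda
        if cfg.with_cva:
            rd_beats, wd_beats = simulate_cva_pair(cfg, schedule, rng)
        recordings.append(
            PairedRecording(
                participant_id=pid,
                rd=rd,
                wd=wd,
                schedule=schedule,
                rd_beats=rd_beats,
                wd_beats=wd_beats,
            )
        )
    return recordings
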