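# Methods

## The protocol

`wearvalid` operationalises a three-level method-agreement protocol for
wearable physiological sensors. The levels are ordered by aggregation:
raw signals, per-participant parameters, cohort-level event responses.
Agreement at the signal level implies agreement below it, so a passing
signal level short-circuits the decision tree; a failing signal level does
*not* imply invalidity downstream (ECG and PPG, for example, are different
physical signals that can still yield the same heart rate), so the
parameter and event levels are then both assessed and the event level is
always reported even when parameters agree (a Bland–Altman aggregate can
hide compensating over/underestimation across conditions).

### Conditioning

- All comparisons use seconds from recording start on a shared clock;
  blocks are half-open `[onset, offset)` so adjacent blocks partition a
  recording exactly.
- EDA is brought to 16 Hz (reference down-sampled with a zero-phase
  Butterworth low-pass at 0.45 × target rate before linear interpolation to
  the coarser grid; wearable up-sampled by linear interpolation — the
  protocol names no interpolator, so the standard phase-preserving choice
  is used). Missing samples are explicit NaNs; an output sample whose
  neighbourhood was a gap stays NaN, and every exclusion is counted in the
  results, because hiding missingness would defeat the protocol's purpose.
- EDA smoothing is a zero-phase Gaussian kernel with its −3 dB point at
  1 Hz (configurable). A Gaussian was chosen over a Butterworth because its
  step response is monotone: filter overshoot on a tonic step would
  masquerade as a small SCR.
- Cardiac waveforms are brought to 200 Hz. ECG is band-passed 5–15 Hz (the
  QRS energy band) before adaptive-threshold peak picking on the squared
  signal with a 0.25 s refractory period; PPG is band-passed 0.5–8 Hz
  before local-maxima picking. The QRS band cannot be applied to the pulse
  wave: a raised-cosine pulse carries essentially no energy above 5 Hz, and
  filtering it there leaves only symmetric ringing in which no peak picker
  can find the beat.

### Signal level

Pearson correlation on the overlapping non-missing samples at each integer
lag in [−8, +8] — 17 explicit correlations rather than an FFT
cross-covariance, so missing data and edges are handled transparently. At
16 Hz, lag 8 is 0.5 s, a deliberately generous window for the
wrist-to-finger sympathetic conduction delay (~0.18 s). Ties for the best
lag break toward the smallest |lag|, then the negative one (an artifact
decision; ties are measure-zero in practice). The cohort passes when every
participant's best r exceeds .80 — only a very high correlation lets
residual disagreement be attributed to simple biases, which
`mean_bias_adjust` then reports (mean difference with a t interval,
variance ratio with an F interval) and corrects by re-centring and
re-scaling. A systematic lag is reported when more than half the cohort
shares one best lag.

### Parameter level

One point per participant. EDA parameters are computed over the full
schedule span: SCL (mean conductance), SCR rate per minute of *non-missing*
signal, and total SCR amplitude **per minute**. The per-minute scale for
S-AMPL keeps it commensurate with its ±0.6 µS boundary, which derives from
a per-minute plausible maximum (≈0.3 µS × 20 SCRs/min); event-level task
values stay raw per-window sums. CVA parameters use intervals from
windows with SQI ≥ 70 over the whole recording (the consecutive-coverage
rule applies to event blocks, not to whole-recording aggregates).

The a-priori boundary for every parameter is
`round(0.10 × (plausible_max − plausible_min))`, rounding half away from
zero at 2 decimals — the heart-rate standard of ±5 bpm is exactly 10% of
the seated 60–110 bpm range, and the same fraction extends to the other
parameters (ranges: SCL 0–16 µS, SCR rate 0–25/min, S-AMPL 0–6 µS/min,
interval SD 0–0.56 s, RMSSD 0–0.71 s). Differences are always
wearable − reference on the raw scale; when the Shapiro (n ≤ 5000) or
omnibus (beyond) test rejects normality and the policy allows, a
`log(v + 10⁻³)` transform is applied **for the normality report only** —
the printed boundaries are in raw units, so the verdict stays raw-scale.
Percent-within is reported against both the a-priori boundary and the
empirical limits; the verdict uses the a-priori boundary.

### Event level

Task values: total SCR amplitude (EDA) and mean instantaneous HR (CVA) per
task. SSST tasks use the block as given, except that the baseline is the
trailing 35 s of the baseline block and recovery the leading 35 s —
duration-matched to the 30 s stressor blocks, because total amplitude grows
with window length. Beep values use the 1–6 s post-onset response window,
and beep comparisons use a duration-matched baseline (the mean total
amplitude over 5-s baseline slices). CVA task values must pass the quality
gate (SQI ≥ 70 long blocks / ≥ 80 beep windows, longest consecutive good
run ≥ 50% of the block); gated-out blocks are missing and counted.

Effect detection is the protocol's deliberately informal criterion:
disjoint mean ± 1 SE bars, not a t-test, with n per task (not the full
cohort) in the SE. Fewer than 3 participants on either side makes the
comparison inconclusive. Decision rules, in order: (1) reference shows no
effect → inconclusive; (2) reference detects, wearable does not → invalid;
(3) both detect → invalid if the difference bar misses zero or leaves
±reference-effect, else valid; (4) insufficient wearable data →
inconclusive-data. A zero reference effect cannot divide anything because
rule (1) fires first.

A known property of rule (3): for a wearable that differs from the
reference by a *tiny but systematic* offset, the difference bar
(mean ± 1 SE) will miss zero even though the devices agree for any
practical purpose — the criterion tests "no detectable difference", not
"difference below a floor". The synthetic verdict-path cohorts therefore
use exact duplication where the scenario calls for agreement.

Habituation: cohort-level per-beep mean amplitudes are fitted by OLS of
log(mean) on stimulus index; `decay = 1 − exp(slope)` with a t-based CI
from the slope's standard error. Zero means are floored at 10⁻⁴ µS before
the log. Per-participant fits are available by calling `fit_habituation`
on per-participant series.

### Data quality

Participants with zero detected SCRs on either device are flagged as
nonresponders and excluded from all cohort analyses — an automated
surrogate for dual-rater visual screening. The SQI is pluggable: with a
raw waveform it is 100 × the mean correlation of each beat's waveform with
the window's average beat template, times a plausibility factor (zero when
the window HR leaves 40–180 bpm, the max/min interval ratio exceeds 2.2,
or any beatless stretch exceeds 1.8 s); with beat times only, the
plausibility factor alone. Windows with fewer than 3 beats score zero.

## SCR scoring (trough-to-peak)

Candidate peaks are local maxima of the smoothed signal with prominence at
least the SCR threshold (0.01 µS; an exploratory 0.001 µS is a config
option). The onset is anchored at the base of the final rise: the last
sample, within the preceding 5 s and after the previous accepted peak,
where the slope stays below 10% of the rise's steepest slope. Anchoring on
the deflection rather than the windowed minimum keeps onsets (and
amplitudes) correct when the tonic level drifts upward beneath a response.
Events require amplitude ≥ threshold and rise time in [0.5, 5] s, may not
share a trough, and are reported in time order. The rise-time floor and
the prominence requirement together reject slow tonic drift and smoothed
noise ripples.

## Synthetic data generator

The generator emulates the validation experiment end to end: an SSST-style
schedule (160 s baseline of four neutral messages, 30 s anticipation, 30 s
singing, 120 s recovery) followed by a noise task (26 beeps of 200 ms in
300 s, onsets ≥ 7 s apart with Dirichlet-spread slack — mean gap ≈ 11 s —
drawn once per seed and shared by the cohort) and a 120 s recovery.

EDA = tonic level (cohort mean 4 µS, between-participant SD 1 µS) + slow
sinusoidal drift (0.3 µS at ~5 and ~2 min periods) + bi-exponential SCR
kernels (rise 0.75 s, decay 2 s) + white sensor noise (0.01 µS at 256 Hz;
per-sample noise scales with √bandwidth on slower grids). Spontaneous SCRs
follow a renewal process with a 3 s refractory and a mean rate of 3/min
(amplitudes ~N(0.4, 0.15²) µS, floored at 0.05): responses closer than the
refractory superpose into compound SCRs that trough-to-peak scoring cannot
resolve, so a pure Poisson stream would make the configured rate
unrecoverable by construction. Anticipation and singing multiply rate and
amplitude by 2.2. Each beep adds a response 1–2 s after onset whose
amplitude starts at 0.4 µS and decays by 4% per stimulus (log-normal
amplitude noise, CV 0.3). The wearable sees the reference event stream
thinned by a response probability (default 0.3 — wrist sites register only
a minority of finger SCRs), attenuated (default 0.5), optionally lagged
(in 16 Hz samples), with its own tonic drift and re-drawn noise, at 4 Hz.

Beat intervals follow an AR(1) process with
`phi = 1 − RMSSD²/(2·SD²)`, so the stationary SD and expected RMSSD equal
their targets (defaults: 70 bpm, SD 0.05 s, RMSSD 0.04 s; singing adds
19.8 bpm). The wearable stream is the reference stream plus 3 ms timing
jitter, thinned by alternating good/bad segments with exponential lengths
calibrated to the dropout fraction (default 0.45; the severe-dropout
preset uses 0.74 with 10 s mean bursts). 22% of participants are emitted
as flat-EDA nonresponders by default.

Presets pin the canonical verdict paths: `perfect_agreement` (wearable
literally identical to the reference — same grid, shared tonic, no noise),
`attenuated_beeps` (identical except beep responses, isolating the
event-level deficit), `high_dropout` (74% PPG loss), `calibration`
(stress effects off, for parameter-recovery experiments — with the singing
delta active, whole-recording interval SD is inflated by design), and
`e4_like` (all deficits at realistic levels). All randomness flows from
one integer seed; identical seeds give bit-identical cohorts.

What the generator does **not** emulate: real ECG/PPG waveform morphology
beyond what beat detection needs, motion artifacts, electrode drift or
detachment, thermoregulatory sweating, or per-participant variance
structure beyond simple scale random effects (the source experiment
reports cohort effects only). Passing tests therefore demonstrate that the
pipeline recovers known structure under the protocol's assumptions — not
that any particular physical device is valid.

## Numerical and problem-size choices

- Sample statistics use ddof = 1 throughout; limits of agreement use the
  conventional 1.96 multiplier.
- Boundary rounding is half-away-from-zero at 2 decimals (reproducing the
  printed 0.06 / 0.07 values from 0.056 / 0.071).
- Cross-correlation lags with fewer than 10 overlapping pairs are
  not-available; an all-NaN lag table is an error.
- Degenerate inputs: zero-variance normalisation, all-missing detrend,
  sub-3-pair Bland–Altman, and sub-2-interval CVA windows raise or mark
  not-available — never silent zeros.
- Test and acceptance problem sizes — 60 participants for parameter
  recovery, 12 for verdict-path cohorts, 200 replicates for lag-recovery
  and habituation-coverage Monte-Carlo, 10 000 pairs for the Gaussian
  limits-of-agreement check — were chosen so Monte-Carlo error sits well
  inside the asserted tolerances while a full run stays in the minutes
  range on one CPU.

## Known limitations

- The SQI here is a self-contained template-correlation/plausibility score,
  not a reimplementation of any published SQI; thresholds (70/80, 50%
  consecutive coverage, 10 s windows) are exposed in the config.
- The "50% of the block" coverage rule counts window overlap seconds, and
  whether it should count samples or windows is an open choice.
- Frequency-domain HRV is out of scope (short stressor blocks cannot
  support it), as are regression-based limits of agreement, repeated-
  measures designs, dynamic time warping, and ECG-vs-PPG signal-level
  comparison (refused by design).
- The mean ± 1 SE event criterion has the false-alarm property described
  above; it reproduces the protocol as specified rather than a formal test.
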