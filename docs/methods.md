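# Methods

This note documents the models and numerical choices behind the package:
what is simulated, how the conditioning chain is realized, how the games
score, and what the statistics assume. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic surface EMG

Surface EMG at the phenomenological level is well described as
band-limited Gaussian noise whose instantaneous amplitude tracks muscle
activation. Per channel the electrode-referred signal is

    x(t) = n(t) · (σ_base + a(t) · σ_max),

where `n` is unit-variance Gaussian noise shaped to the sensor model's
`shaping_band` and `a(t) ∈ [0, 1]` is the activation envelope rendered
from an `ActivationScript` (piecewise-constant levels with linear
transitions of width `rise_s`, overlapping ramp tails merged by pointwise
maximum). The shaping filter is an 8th-order Butterworth band-pass; a
gentler filter leaves appreciable skirt power outside the nominal band,
whereas this choice keeps > 95 % of the rest+activation power inside it
(verified by periodogram integration in the tests). Motor-unit level
structure — recruitment, firing statistics, fatigue, electrode geometry —
is deliberately out of scope.

Defaults and their reasoning:

| parameter | default | meaning |
|---|---|---|
| `gain` | 500 V/V | in-board amplification of the emulated low-cost sensor |
| `supply_v` | 3.3 V | supply rail; signal centered at 1.65 V |
| `adc_bits` | 12 | ADC codes 0–4095; volts = counts · 3.3 / 4095 |
| `fs_hz` | 2000 Hz | sampling rate |
| `shaping_band` | 20–450 Hz | spectral support of the physiological signal |
| `baseline_sd_v` | 5 µV RMS | electrode-referred noise floor (free parameter; typical clean-skin surface recordings sit at a few µV) |
| `max_emg_sd_v` | 1 mV RMS | electrode-referred amplitude at full activation (upper end of forearm sEMG); post-gain SD 0.5 V fits the rail with rare saturation |
| `crosstalk` | 0 | linear pre-gain mixing fraction; a knob for robustness studies |

The front-end applies gain, offsets to mid-supply, saturates at the rails
(no wraparound, mirroring ADC behavior), and rounds to integer codes.
With a zero envelope and a zero noise floor the output is exactly the
midpoint code 2048. All randomness flows from one caller-supplied seed
through `numpy.random.SeedSequence` spawning; identical inputs and seed
give bit-identical recordings.

**Force coupling.** Grip force (fraction of MVC) is a weighted sum of
channel activations (default 0.5/0.5 — a power grip engages both
antagonists) through a first-order low-pass (τ = 0.1 s, exact zero-order-
hold discretization) plus Gaussian noise (SD 0.01 MVC), clipped at zero.
This is the simplest coupling that yields linear EMG–force behavior
during slow isometric ramps; it makes no claim about contraction
dynamics.

**Trial-to-trial variability.** In the ramp–hold validation simulator
each trial draws an independent per-channel activation gain
~ N(1, 0.15), clipped at zero. Voluntary isometric output is not
metronomic; amplitude CVs of 10–20 % are typical at moderate force, and
without this variability per-device calibration error would masquerade as
a systematic device difference with near-zero within-device variance —
an unrealistically easy target for a paired test. Training-session
simulations apply no jitter: their activation pairs are caller-supplied
ground truth for parameter-recovery checks.

## Envelope chain

Band-pass → rectify → normalize → smooth.

- **Filter**: 4th-order Butterworth band-pass, default 150–450 Hz. The
  band is deliberately high to suppress motion artifacts and crosstalk in
  unfiltered low-cost sensors; it also removes the DC offset. Realization
  is zero-phase (`sosfiltfilt`, reflect padding) offline and causal
  (`sosfilt`) in streaming mode.
- **Rectification**: absolute value (full-wave).
- **Calibration**: per channel, the *maximum* 250-ms moving-window
  average of the rectified filtered reference-grip recording. The mean
  over the recording is available as `stat="mean"` for recordings that
  consist mostly of grip. A channel is declared silent — and calibration
  fails loudly — when its peak is below 3× its windowed amplitude over a
  configurable rest interval (default the first 0.5 s; generated grip
  recordings lead with 1 s of rest). The rule is an automated stand-in
  for a clinician's visual signal-quality check.
- **Normalization**: division by the calibration amplitude. Values above
  1 are preserved; clipping would bias the extensor ratio. Because
  normalization divides like by like, counts and volts processing give
  identical envelopes.
- **Smoothing**: unity-DC-gain windows — 250-ms Hann for display, 1-s
  boxcar for slow isometric analysis, or none. Offline windows are
  centered (reflect padding); streaming windows are trailing and
  zero-initialized, so the first window length is a start-up transient
  and the causal envelope lags the zero-phase one by about half a
  window. `StreamingProcessor` carries filter state across chunks and is
  sample-for-sample identical to a one-shot causal run.
- **Display**: one envelope value per frame (last sample at or before
  each frame time) plus a color index `clip((v − lo)/(hi − lo), 0, 1)`
  with a clinician-adjustable dynamic range.

## Games

The control signal is the extensor ratio `ER = ext/(ext + flex)` of mean
normalized activities over a trial window (default the first 2 s of each
movement attempt, configurable — the same epoch is used online and in
offline re-analysis). ER is scale-invariant, bounded in [0, 1], and
equals 0.5 for any equal pair. When the summed activity falls below 1e-6
normalized units the ratio is undefined; such trials report ER 0.5,
score through the co-activation bin, and carry a `degenerate` flag so no
silent data enters summaries unnoticed.

**Ball-throw scoring** bins ER with lower-exclusive/upper-inclusive
edges; ER exactly 0 falls in the bottom bin, and the top bin is extended
from 0.99 to 1.0 so perfect individuation still scores. Default table
(points @ probability):

| ER bin | outcomes | expectation |
|---|---|---|
| (0, 0.2] | 0 @ 100 % | 0 |
| (0.2, 0.4] | 10 @ 20 %, 0 @ 80 % | 2 |
| (0.4, 0.6] | 20 @ 40 %, 10 @ 60 % | 14 |
| (0.6, 0.9] | 30 @ 40 %, 20 @ 60 % | 24 |
| (0.9, 1.0] | 30 @ 100 % | 30 |

Expected points rise monotonically with ER, so individuation is always
positively reinforced even though single-trial outcomes are stochastic.
Session score is the running cumulative sum, re-validated on log reload.

**Chance board**: nine slots (100, 500, 1000, 0, 10000, 0, 1000, 500,
100), ER mapped linearly to the start slot (0.5 → center). The drop is a
symmetric random walk: one ±half-slot step per peg row (default 8) with
reflecting walls. The physics is not otherwise specified by the design;
this choice reproduces "any path is possible" while admitting an exact
enumeration oracle that the tests check against Monte-Carlo frequencies.

## Protocols

Ramp–hold validation: 5 s linear ramp to 25 % MVC, 5 s hold, 7 s rest —
a 17-s sweep repeated 12 times with no extra inter-trial gap (the rest
phase is the gap). For analysis the first 0.5 s of each hold is trimmed
(configurable) to skip ramp overshoot. Training sessions: 5 blocks × 20
repetitions (100 trials), 2-s trial windows, 3 s between trials
(unspecified in the emulated protocol; configurable) and 90 s between
blocks.

## Statistics

- **Device comparison**: per-trial mean ER over hold epochs, paired
  across trial index (n = 12 pairs), classical paired Student t with
  n − 1 df. Pairing per-trial means rather than per-time-point samples
  avoids autocorrelation-inflated degrees of freedom; pointwise series
  remain available for distribution plots. Zero-variance differences
  raise a degenerate-data error rather than returning an unstable
  statistic.
- **EMG–force regression**: OLS of force on normalized activity pooled
  over ramp epochs, per muscle; slope, intercept, R².
- **Session summaries**: arithmetic means of per-trial extensor
  activity, flexor activity and ER (plus total score); sessions with
  missing data, failed calibration, or a rest-epoch envelope above a
  noise ceiling (default 0.02 normalized — about five times the clean
  simulated noise floor of ≈ 0.004) are excluded with a recorded reason,
  and excluded sessions never enter any trend.
- **Longitudinal trends**: Pearson correlation of a session field
  against session number over non-excluded sessions (≥ 3 required),
  two-sided p via the t transform. All p-values are two-sided and
  uncorrected.

## Problem sizes and determinism

Simulation-backed checks run at desk scale by choice: parameter-recovery
and drift studies use 12-trial sessions (40 sessions for the trend
recovery run), null calibration of the paired test uses 1000 synthetic
replicates of 12 pairs, score-table frequencies use 10⁵ draws, and the
100-replicate trend-direction check runs at the session-summary level
with drift 0.5 → 0.7 and noise SD 0.05. Every stochastic test and the
acceptance script are seeded; reported numbers are reproducible exactly.

## What the simulations do and do not show

The generator reproduces the second-order statistics the envelope chain
measures (band-limited amplitude-modulated noise, quantization, offset,
saturation, linear EMG–force coupling, trial-to-trial gain variability).
It does not model motion artifacts, mains interference, electrode lift,
spasticity-driven bursting, fatigue, or between-session electrode
placement variability. Passing parameter-recovery tests therefore shows
the pipeline is correct and well-calibrated *under the generative
model*; it does not certify performance on real recordings, where the
excluded noise sources dominate failure modes.
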