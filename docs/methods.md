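# Methods

## The paradigm and what the package models

A session consists of three 5-minute tasks separated by 1-minute gaps:
a low-demand baseline, a long-interval sighing task (a 2-s visual cue
every 30 s; 10 sighs), and a short-interval sighing task (a cue every
15 s; 20 sighs).  The inhalation is taken to peak half-way through the
cue.  Cues sit on a regular grid from each segment's onset; a 300-s
segment therefore holds `floor(300/interval)` cues.

The simulator composes an instantaneous RR-interval signal

```
RRI(t) = mean_rri
       + RSA(t)                 delayed coupling to the respiration phase
       + LF(t)                  ~0.1 Hz Mayer-type oscillation
       + Σ sigh dip(t − t_k)    negative Gaussian, minimum at peak inhalation
       + Σ rebound(t − t_k)     post-sigh heart-rate drop (RRI overshoot)
```

and generates beat times by integrate-to-threshold (IPFM): the
instantaneous rate 1/RRI(t) is integrated and a beat fires at each unit
crossing, so a constant RRI(t) yields exactly metronomic beats.  Per
beat, PTT is `baseline_ptt + Σ ptt kernels + noise` (Gaussian bump in
phase with the inhalation — transient vasodilation) and the systolic
value is `baseline_sbp + Σ bp kernels + Mayer and respiratory
components + noise`, where the pressure kernel is a gamma-like rise
peaking `bp_lag_beats` (2 or 3) beats after peak inhalation with
exponential recovery.  The pressure channel renders each beat as a
half-cosine upstroke from the previous end-diastolic value to the
systolic peak at exactly `R + PTT`, then an exponential decay
(τ = 0.18 s) toward diastolic pressure: the within-beat maximum is the
programmed peak, sharp on its falling side as in finger-cuff waveforms.
The ECG channel is a train of narrow Gaussian R-spikes (only R timing is
consumed downstream); respiration is a unit-amplitude eupneic sinusoid
plus a Gaussian bolus per sigh.

Choices that deserve justification:

* **Sigh dip width (σ = 2.5 s).**  The heart-rate acceleration spans
  the whole sigh breath.  A narrow dip would (a) push harmonic energy
  into the HF band, corrupting the HF-HRV task structure, and (b)
  flatten the attenuating-harmonic pattern of the group spectrum; the
  broad dip gives the observed fundamental-dominant comb.
* **Rebound at +4 s (120 ms, σ = 1 s).**  The post-sigh heart-rate drop
  must form an actual local maximum of RRI(t) clear of the dip's tail;
  this is what the per-sigh RSA proxy measures.  The eupneic RSA ripple
  is suppressed in a Gaussian window around each sigh (amplitude 0.85,
  σ = 2.5 s) because a sigh replaces the normal breath — without this
  the "next RRI-series peak" is an ill-conditioned ripple on the flat
  dip trough.
* **RSA ground truth.**  Baseline RSA delay is programmable exactly
  (the coupling lag, default 0.8 s).  The per-sigh delay is *derived*:
  the first local maximum of the noiseless RRI(t) after the inhalation
  peak, mirroring the measurement's definition.
* **Task modulation of RSA.**  `rsa_task_gain = (1.0, 1.0, 0.7)`
  attenuates respiratory coupling during rapid sighing, encoding the
  HF-HRV suppression the paradigm produces at a 15-s pace.
* **Pressure-peak lag timing.**  The bp kernel's crest is placed at
  `bp_lag_beats` × the *sigh-accelerated* beat interval
  (`mean_rri − 0.8 × dip amplitude`), since the lag is counted in actual
  (accelerated) beats.
* **Sex offsets** (cohort draws): females have shorter mean RRI (faster
  heart rate), lower LF oscillation amplitude, smaller PTT dispersion
  and smaller sigh-response amplitudes.  Directions are the modelled
  phenomenon; magnitudes are free parameters.
* **Cohort split.**  The female count is `round(n × fraction_female)`
  with round-half-even, so 250 subjects at 65 % female gives 162
  females.  Per-subject seeds are spawned from the master seed, making
  the whole cohort reproducible bit-for-bit.
* **Calibration gaps** are annotations (one configurable-length gap per
  task at a reproducible random position); the waveform itself is left
  intact.  They exist to exercise the exclusion rule, not to model the
  device's staircase artifact.

## Beat and breath processing

All event detection runs on the full session with time in seconds from
recording start; windows are half-open `[start, end)`.

* **Low-pass**: 4th-order Butterworth at 10 Hz, applied
  forward-backward (`sosfiltfilt`) so event times are not shifted by
  group delay.
* **R peaks**: local maxima above half of a robust spike-height
  estimate, 250-ms refractory period; times at sample resolution.
* **RRI**: `r_i − r_{i−1}` in ms; the first beat is undefined.
* **Artifact rule** (automated stand-in for manual editing): a beat is
  flagged when its RRI leaves [300, 2000] ms or deviates more than 30 %
  from the centered 5-beat running median; flagged values are linearly
  interpolated over beat index.  More than 20 % flagged beats rejects
  the record.  The rule is idempotent.
* **Systolic peaks**: the maximum of the *raw* pressure signal in
  `(R + 50 ms, next R)` — the offset skips R-synchronous artifacts, the
  upper edge guarantees the *subsequent* peak; ties break earliest.  The
  final beat has no closing R, so its peak is left undefined.
* **PTT** = (pressure-peak time − R time) × 1000, aligned to the
  pressure peak; negative values flag a detection inconsistency.
  **PWV** = arm length / PTT.
* **MAP**: per-beat time-average of the pressure signal over
  `[r_i, r_{i+1})` — the per-beat reduction is a convention of this
  package (a mean over the beat is the natural reading of extracting
  MAP "directly" from the continuous signal).
* **Calibration exclusion**: beats whose pressure peak falls inside a
  (merged) calibration gap keep their RRI but are excluded from every
  pressure-derived statistic (SBP, MAP, PTT, PWV, PTTv, BPV).
* **RSA proxy**: for each eligible breath (every breath at baseline;
  only sighs during sighing tasks), the delay to the next strict local
  maximum of the per-beat RRI series (the heart-rate trough), located at
  the raw beat index without interpolation; undefined if none arrives
  within one breath period (12 s for sighs).  Longer delay = stronger
  cardiorespiratory synchronisation.  Resolution is intrinsically one
  beat, and because each RRI value is attributed to the R time closing
  its interval, a crest falling mid-interval is found up to half a beat
  late: closure tests use 1 and 1.5 beat-spacing tolerances for
  baseline and per-sigh delays respectively.

## Spectral analysis

Beat series (RRI in ms; systolic values in mmHg, calibration beats
excluded) are cubic-spline interpolated onto a uniform 4-Hz grid over
`[first, last]` beat time.  Two estimators serve two purposes:

* **Band powers** (`welch_psd`): Welch's method with 60-s Hann windows,
  50 % overlap, per-segment linear detrend, zero-padded 2048-point FFT
  (a 300-s series gives 9 segments).  LF = 0.04–0.15 Hz,
  HF = 0.15–0.4 Hz, integrated trapezoidally with band edges
  interpolated (so a flat density integrates exactly), then natural-log
  transformed.  The VLF band (< 0.04 Hz) is never summarised: 5-minute
  tasks are too short for it.
* **Spectral graphs and signature peaks** (`signature_psd`): a single
  Hann-windowed, linearly detrended periodogram of the whole 5-min
  series, zero-padded to 2048 points (resolution 1/300 Hz).  This
  distinction is structural, not cosmetic: a 60-s Hann window tapers
  away all but one sigh per segment — a 30-s pacing comb has line
  spacing equal to the window's mainlobe half-width — so Welch spectra
  of the long-interval task form a smooth hump and cannot resolve the
  harmonics.  The full-segment periodogram resolves the attenuating
  comb (0.033, 0.066, 0.100 Hz) with troughs orders of magnitude below
  the peaks.  Peak reporting (`spectral_peaks`) requires a local
  maximum to exceed 3× the local background (median density in a
  ±0.02 Hz annulus) and starts at 0.02 Hz, because the bins next to DC
  hold only window-edge leakage after detrending.

Per-task summary rows: HR = 60000 / mean valid RRI; PTTv = SD (ddof 1)
of valid, non-calibration PTT; MAP = mean per-beat MAP; RSA = mean
eligible delay; PWV = arm length / mean PTT; ln band powers from the
RRI (HRV) and systolic (BPV) spectra.  Undefined components produce
missing cells; the row is still emitted.

## Mixed-model dissection

For each outcome in {HR, ln LF-HRV, ln HF-HRV, PTTv, MAP, ln LF-BPV,
ln HF-BPV} a linear mixed model is fitted by REML with fixed effects
`task * sex + covariates` (task reference = baseline) and a random
intercept per subject — three observations per subject cannot support
random slopes.  Covariate sets isolate each index: HR | PWV, RSA;
LF-HRV | RSA, HF-HRV; HF-HRV | RSA, LF-HRV; PTTv | HR; MAP | PWV, HR
(an alternate HR, PTTv set is a config switch, since the paradigm's
descriptions of the MAP adjustment differ between its methodological
and results-facing accounts); LF-BPV | RSA, HF-BPV; HF-BPV | RSA,
LF-BPV.  Covariates enter per task (time-varying), as main effects
only.

Inference: Wald F statistics for task, sex and task × sex with residual
denominator degrees of freedom (n_obs − fixed-effect rank) — software
packages differ in denominator-df conventions, and exact df matching
across packages is a non-goal.  Pairwise task contrasts are computed
regardless of omnibus significance (the scientific interest is the
graded dose-response), as marginal means weighting both sexes equally,
with uncorrected p-values — deliberately: raw pairwise p-values are the
paradigm's reporting convention, flagged here rather than silently
"fixed".  Sex × task contrasts are differences-in-change (male change −
female change).  By construction `(BL vs short) − (BL vs long) =
(long vs short)` exactly.

**Influence screening** holds the estimated variance components fixed
(the non-iterative scheme standard mixed-model software uses), whitens
the model by the implied error correlation (for a random intercept,
`(I + γJ)^{-1/2} = I − cJ` per subject with
`c = (1 − 1/√(1+mγ))/m`), and applies the exact closed-form
case-deletion formulas of the linear model: Cook's D for the fixed
effects, externally studentized residuals, and the restricted
likelihood distance (twice the drop in full-data restricted
log-likelihood at the deleted estimates).  Observations breaking
Cook's D > 1, RLD > 1.5 or |studentized| > 4 are removed in a single
pass and the model refitted once.  A subjective Q–Q-plot-based removal
step is deliberately not implemented.  For ordinary regression (γ = 0)
the diagnostics reduce to the textbook OLS formulas; tests verify both
cases against brute-force leave-one-out refits to 1e-8.

A fast summary-level generator (`simulate_summary_table`) draws
subject × task outcome tables directly from the mixed-model family
(baseline level by sex + task delta by sex + random intercept +
residual, covariates independent of task so the adjusted task effects
remain the programmed estimands).  It calibrates and validates the
statistical layer: effect recovery at n = 250, type-I error of the task
F test over 200 null replicates at n = 50, and recovery of the full
programmed direction pattern across all seven outcomes.  End-to-end
direction emergence through the waveform pipeline is additionally
exercised at smaller cohort sizes.

## What the synthetic data does and does not show

The generator reproduces the features the analysis depends on: cue-locked
response morphology with known lags, a protocol-locked spectral comb,
RSA/Mayer background structure, between-subject and sex-linked
variation, measurement noise, and calibration gaps.  It does **not**
model: full PQRST morphology or pressure-waveform detail (dicrotic
notch), baroreflex closed-loop dynamics (backgrounds are open-loop
oscillations), breath-to-breath variability of eupneic rate, ectopic
beats (artifacts are tested with constructed corruptions), or
cognitive-load effects of the counting task.  Passing tests therefore
demonstrate correctness of the measurement and inference chain under
known ground truth — not that real recordings satisfy the generator's
assumptions.  Reported magnitudes (e.g. band powers) are in the
simulator's scale; only directions and frequencies are meaningful
points of comparison with real cohorts.

## Numerical conventions and degenerate inputs

Sampling rate defaults to 250 Hz (configurable; detection tolerances
are expressed in samples).  Recording round trips use 12-significant-
digit CSV (absolute error < 1e-9 at pressure scale).  Flat ECG yields
an empty beat list with a warning; fewer than 4 valid beats cannot be
splined; series shorter than one Welch window raise; zero band power
has no logarithm and becomes a missing value with a warning; a
rank-deficient design (including a covariate identical to its outcome)
raises; a zero-variance random intercept is reported at the boundary
with a warning.  Simulation refuses parameter sets whose programmed PTT
reaches the next beat.

## Problem sizes

The test suite and the acceptance script use desk-scale sizes chosen as
defaults of this package: 20–24 simulated subjects for group spectra
(the spectral signature is protocol-locked and already exact at that
size), n = 250 summary-level cohorts for effect recovery, 200
replicates at n = 50 for type-I calibration.
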