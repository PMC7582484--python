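# Methods

`gaitq` implements a daily-life gait-quality pipeline for trunk
accelerometry in older adults: week-long tri-axial recordings (vertical VT,
mediolateral ML, anteroposterior AP; units of g; 100 Hz; ±6 g sensor range)
are reduced to walking bouts, 10-s epochs, per-epoch gait-quality
characteristics, weekly medians per subject, and finally to linear models
that relate those characteristics to a four-level physiological fall-risk
category (QuickScreen) with walking speed as a covariate. This note
documents the models, the defaults and the numerical choices.

## Pipeline model

1. **Orientation calibration.** The quasi-static gravity direction is the
   mean of the < 0.1 Hz low-passed signal; the axes are rotated so it lies
   on VT at +1 g. A mean magnitude outside [0.8, 1.2] g aborts (sensor not
   worn, or not in g units). Needs ≥ 60 s of signal.
2. **Wear-in exclusion.** The first six hours of a recording are dropped
   (transportation to/from the fitting visit); the window is a parameter.
3. **Locomotion detection.** Sliding 2-s windows (0.5-s hop) over VT are
   flagged as walking when the 0.5–3 Hz band fraction of (DC-removed)
   power ≥ 0.5 **and** the window SD ≥ 0.08 g. Flagged windows are merged,
   gaps ≤ 1 s bridged, one window length trimmed from each flank (flags
   overhang bout edges because windows fire on partial overlap), and only
   bouts ≥ 10 s are kept. On labeled synthetic days the detector reaches
   per-sample sensitivity and specificity ≥ 0.99. This transparent detector
   replaces the proprietary classifier shipped with commercial trunk
   sensors; fidelity to any particular black-box product is not claimed.
4. **Epoching.** Each bout is cut into consecutive non-overlapping 10-s
   epochs (1000 samples at 100 Hz) from the bout start; the remainder is
   discarded. Indices are 0-based, intervals half-open.
5. **Per-epoch characteristics** (below), then **weekly medians** per
   subject over all epochs pooled across the week (even counts: mean of the
   central two). Undefined epoch values are skipped per characteristic —
   never zero-filled — and a characteristic with no defined epochs stays
   undefined. Subjects with < 4 days or < 10 epochs are flagged, not
   dropped; both thresholds are configuration.
6. **Association models** (below).

## Gait-quality characteristics

All estimators return `NaN` as an explicit undefined-marker when their
preconditions fail; no estimator raises on degenerate *data* (only on
contract violations such as too-short input).

**Sample entropy** (regularity; computed on VT and ML).
SampEn(m, r) = −ln(A/B), where B counts ordered template pairs of length
`m` (i ≠ j, Chebyshev distance ≤ r, both indices ≤ n−m−1 so the count
basis is identical at both lengths) and A the same at length m+1. Defaults
m = 5, r = 0.3·SD(signal), in line with daily-life gait work that uses
longer templates and wider tolerances than the classic (2, 0.2) heart-rate
settings; both are configurable. SD-relative tolerance makes the estimate
invariant to affine scaling. A constant signal with positive tolerance
gives exactly 0; zero counts give the undefined-marker, never a division
error.

**Logarithmic rate of divergence per stride** (local dynamic stability,
maximal Lyapunov exponent in the Rosenstein sense; VT, ML, AP). The signal
is delay-embedded (dimension 5, delay 10 samples = 0.1 s); each point is
paired with its nearest neighbour at temporal separation > 1 stride; the
mean ln distance between paired trajectories is followed for 0.5 stride,
and the least-squares slope of that curve (nats/sample) is converted to
nats/stride via the epoch's mean stride time. Distances are floored at
1e-12 before the log so exactly periodic signals yield a finite ~0 slope.
At least 20 valid neighbour pairs are required. A noiseless periodic gait
signal gives |λ| < 1e-10; stride-to-stride phase jitter raises the estimate
monotonically.

**Spectral conventions.** The dominant VT/AP oscillation during gait is at
*step* frequency, ML at *stride* frequency; stride frequency = step/2.
Dominant peaks are located on a Hann-windowed, zero-padded (2^14) amplitude
spectrum inside 1.2–4.0 Hz (step-frequency band); a peak must exceed 12×
the in-band median power, otherwise the epoch's frequency is undefined
(rest noise never passes). Zero-padding interpolates the 0.1 Hz natural
resolution of a 10-s epoch to ~0.006 Hz.

* **RMS of ML** — root mean square of the mean-removed signal, g.
* **Index of harmonicity of ML** — periodogram power at the stride
  frequency divided by the summed power at the fundamental plus its first
  5 harmonics (±0.15 Hz bands); 1 for a pure sinusoid.
* **Dominant amplitude of AP** — amplitude-spectrum magnitude at AP's
  dominant frequency, scaled so a sine of amplitude A reads A.
* **Autocorrelation at the dominant period of VT** — biased-normalized
  autocorrelation at lag round(fs/f_dom); the biased normalization keeps it
  in [−1, 1] but shrinks values by ~lag/n on a 10-s epoch (a pure sine at
  2.5 Hz reads ≈ 0.96, not 1).

**Walking speed.** Compass-gait (inverted-pendulum) model: step length
= 2·√(2lh − h²) from leg length l (clinical table) and vertical trunk
excursion h; stride length = 2 steps; walking speed = stride frequency ×
stride length, an exact identity in the code. h is estimated by converting
VT to m/s² (g = 9.80665 m/s²), double-integrating, and measuring the mean
per-step peak-to-trough displacement. Drift control uses mean removal plus
a linear detrend after each integration and a per-stride-window linear
detrend before measurement, with edge strides discarded; a high-pass filter
at the nominal 0.1 Hz drift corner is ill-conditioned on 1000-sample
windows (the corner is below the epoch's frequency resolution), so
detrending does that job here. On clean synthetic gait the commanded h is
recovered within ~3%, and commanded speed within 5% across a 3×3 grid of
(step frequency, excursion); subjects without a valid leg length get an
undefined speed rather than a guess.

**Gait-quality composite.** Weighted sum of the four spectral/amplitude
measures (RMS-ML, index of harmonicity ML, dominant AP amplitude, VT
autocorrelation), each z-scored against a supplied normalization and
sign-oriented so higher = better gait (RMS enters with −1: more
mediolateral sway is worse). Defaults: equal weights 0.25 and
cohort-internal normalization, which makes the cohort mean exactly 0. The
weight vector, orientation and normalization basis are all configuration so
externally fitted weights or a reference population can be dropped in; the
original composite's fitted weights are not public, so the default is the
package's own neutral choice.

## QuickScreen scoring

Eight binary risk factors (fall history; polypharmacy; psychoactive
medication; impaired visual acuity; impaired tactile sensitivity; failed
sit-to-stand, near-tandem stand, alternate stepping). The count maps to
very low (0–1), low (2–3), moderate (4), high (≥ 5) risk. Raw measurements
are thresholded into booleans by config cut-offs; the shipped values are
**placeholders** at clinically plausible magnitudes (e.g. ≥ 4 medications,
5×-sit-to-stand > 12 s) and must be replaced with the validated instrument
cut-offs for real administrations. Missing items raise by name; there is no
silent imputation.

## Association models

Per gait characteristic: OLS of the weekly median on the risk category
(dummy-coded, very-low reference), with walking speed as covariate in the
adjusted models and without it in the unadjusted ones. All six pairwise
contrasts and SEs come from the coefficient covariance matrix (so
anti-symmetry and releveling-equivalence hold exactly); the overall
category effect is the partial (Type II) F of the three dummy terms — the
sum-of-squares type is our choice, as the category term is the only
non-covariate term. Listwise deletion with the dropped count recorded.
Residual df is n − 5 adjusted (n − 4 unadjusted); published analyses of
this design sometimes print n − 6-style denominators that we cannot
reconstruct, and we report our own df. Descriptive group comparisons:
linear-regression F (≡ one-way ANOVA) for continuous measures,
Kruskal–Wallis for age and GDS, chi-square for sex and fall history;
post-hoc pairwise decisions use a Bonferroni threshold α/k (0.05/6 ≈ 0.008).
No multiplicity correction is applied to the model contrasts by default;
a config flag/threshold helper enables it.

Monte-Carlo calibration (also exercised by the acceptance script): under a
null synthetic cohort the partial F rejects at 5% within Monte-Carlo error,
and 95% CIs for the pairwise contrasts cover the generating truth at ~95%.

## Synthetic data

The generator exists so every stage has known ground truth.

* **Walking signal.** Vertical trunk trajectory z(t) = (h/2)·cos(2π f_step
  t + φ); VT = 1 g + z''/g; ML is a sinusoid at stride frequency, AP at
  step frequency; white sensor noise on all channels; samples clipped to
  ±6 g. Stride-to-stride variability: the per-stride phase offset follows a
  random walk (increment SD `phase_jitter_sd`, default 0.05 rad) — timing
  errors accumulate as in real gait, which is what makes the divergence
  estimator respond monotonically — plus independent per-stride amplitude
  factors (SD 5%). Defaults (step 1.9 Hz, h = 3.5 cm, l = 0.90 m) give a
  compass-gait speed of 0.94 m/s, matching the ~0.93 m/s daily-life median
  reported for community-dwelling older cohorts; the default cohort
  category mix (22.6/59.1/11.5/6.8%) and per-category speed distributions
  follow the same published descriptive scale.
* **Days and weeks.** Bouts are embedded at scheduled times in otherwise
  quiet days (gravity + rest noise); ground-truth bout labels are returned.
  Per-day random substreams derive deterministically from one seed.
* **Cohort tables.** Category ~ multinomial; speed ~ N(mean_c, sd_c) per
  category; each characteristic = intercept + category shift + β_speed ×
  speed + Gaussian residual, with all coefficients returned as ground
  truth. Default shifts and intercepts sit at the scale of published
  cohort summaries (e.g. VT divergence shifts 0.03/0.14/0.19 vs very-low).

**What the generator does not emulate:** turning, stairs, dual-tasking,
posture transitions, sensor re-orientation over the week, non-wear periods,
and the broadband messiness of real daily-life signals. Passing tests
therefore demonstrate internal consistency and estimator correctness, not
validated performance on real wear data.

## Problem sizes

Desk-scale sizes are used throughout, as the package's own choice: demo
"days" are fractional-hour days with a few 45–300 s bouts; calibration
simulations use cohorts of n = 120–200 with 800–1500 replicates; week-long
100 Hz recordings (≈ 60 M samples) are never materialized. All sizes are
parameters.

## Clinical CSV columns

`subject_id` (unique string); `age` years; `sex` (F/M); `body_height` cm;
`body_weight` kg; `leg_length` m (required for speed; missing ⇒ flagged);
`fall_history` boolean (12-month); `mmse`, `gds` scores; `grip_strength`
kg; `knee_torque` Nm; the eight QuickScreen item booleans (or the raw
measurements thresholded via `quickscreen.items_from_measurements`).
Unknown columns pass through untouched.

## Known limitations

* The locomotion detector is amplitude/band-power based and tuned on
  synthetic gait; real shuffling or very slow gait near the 0.08 g activity
  threshold may be missed.
* The divergence estimate depends on embedding settings; values are
  comparable within a configuration, not across publications that used
  different (often unstated) settings.
* Composite weights and QuickScreen item cut-offs ship as documented
  placeholders, not validated constants.
* The biased autocorrelation's lag/n shrinkage on 10-s epochs is inherent
  to the estimator choice.
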