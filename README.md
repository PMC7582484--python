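# gaitq

Daily-life gait quality from trunk accelerometry, and its association with
physiological fall risk in older adults.

Falls are the leading injury cause in people over 65, and how someone walks
in daily life carries information about their risk. `gaitq` turns week-long
tri-axial trunk acceleration recordings (vertical VT, mediolateral ML,
anteroposterior AP; 100 Hz; ±6 g) into a small set of gait-quality
characteristics and relates them to a physiological fall-risk profile:

* **segmentation** — orientation calibration, wear-in exclusion, detection
  of walking bouts ≥ 10 s, 10-s epochs;
* **characteristics per epoch** — sample entropy (regularity, VT/ML), the
  logarithmic rate of divergence per stride λ (local dynamic stability /
  Lyapunov exponent; VT/ML/AP), RMS of ML, index of harmonicity of ML,
  dominant-period amplitude (AP) and autocorrelation (VT), a weighted
  z-scored gait-quality composite, and walking speed
  v = f_stride · 2·2√(2lh − h²) from the compass-gait (inverted-pendulum)
  model with leg length l and vertical trunk excursion h;
* **aggregation** — weekly medians over all epochs per subject, plus
  walking exposure (min/day);
* **QuickScreen** — eight binary physiological risk factors, counted and
  mapped to very-low (0–1), low (2–3), moderate (4) and high (≥ 5) risk;
* **stats** — per characteristic, OLS on risk category with walking speed
  as covariate (ANCOVA), all six pairwise contrasts from the coefficient
  covariance, partial F for the overall category effect, descriptive group
  comparisons (regression F / Kruskal–Wallis / chi-square) with Bonferroni
  post-hoc thresholds;
* **synthetic data** — a compass-gait trunk-signal generator and a cohort
  generator with fully known ground truth, so every stage is testable
  without access to clinical recordings.

The library API is the main interface (`examples/` has one narrative script
per capability); a thin `gaitq` CLI wraps the simulate/extract/analyze
pipeline for shell use.

## Worked example

```python
from gaitq import GaitModelParams, generate_walking_accel
from gaitq.features import dominant_frequency, stride_length, vertical_excursion

params = GaitModelParams(step_frequency=1.9, vertical_excursion=0.035, leg_length=0.90)
rec = generate_walking_accel(params, duration=60.0, seed=1)

vt = rec.vt[:1000]                                # one 10-s epoch
f_step = dominant_frequency(vt, rec.sampling_rate)  # spectral step frequency
h = vertical_excursion(vt, f_step, rec.sampling_rate)
speed = (f_step / 2) * stride_length(h, params.leg_length)
```

prints (via `python examples/01_simulate_walking.py`):

```
commanded: step 1.90 Hz, excursion 3.5 cm, speed 0.944 m/s
estimated: step 1.90 Hz, excursion 3.4 cm, speed 0.928 m/s
```

The generator's commanded speed is analytically known from the compass-gait
formula; the estimate recovers it within ~2% from the raw signal alone.
At cohort level (`examples/05_cohort_models.py`), a 279-subject synthetic
cohort with known category shifts yields, for the VT divergence rate,

```
log divergence VT ~ category + speed: F(3, 274) = 6.29, p = 0.0004
  high vs very_low: beta = +0.357 (SE 0.085), p = 0.000  [truth +0.190]
```

i.e. the speed-adjusted model recovers the generating contrasts within two
standard errors, and higher-risk groups show higher divergence (less stable
gait) — the pattern this kind of analysis is designed to detect.

`docs/methods.md` documents the estimators, their defaults and the
numerical choices; `examples/06_full_pipeline.py` runs the whole chain.

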