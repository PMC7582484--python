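"""Synthetic trunk-accelerometry and cohort generation with known ground truth.

The walking generator is a deliberately simple compass-gait (inverted
pendulum) trunk model: the vertical trunk trajectory is a sinusoid at step
frequency whose peak-to-trough excursion, together with leg length, fixes
step length via ``2*sqrt(2*l*h - h^2)``; the VT acceleration channel is
gravity plus the second derivative of that trajectory. ML sways at stride
frequency (half the step frequency), AP oscillates at step frequency.
Stride-to-stride variability enters as a per-stride random walk on phase
plus independent per-stride amplitude factors, so regularity/stability
estimators see structured variability, not just white noise. Every commanded
quantity (speed, stride frequency, excursion, bout times, regression
coefficients) is therefore analytically known and recoverable downstream.

The cohort generator produces the tabular side: fall-risk categories,
walking speed drawn per category, and gait characteristics that are linear
in category and speed with Gaussian residuals — the exact data-generating
process assumed by the downstream regression models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .recording import G, SENSOR_RANGE_G, AccelRecording

__all__ = [
    "GaitModelParams",
    "DaySchedule",
    "CohortSimSpec",
    "generate_walking_accel",
    "generate_daily_recording",
    "generate_cohort",
    "FEATURE_NAMES",
]

#: the six gait-quality characteristics modelled at cohort level
FEATURE_NAMES = (
    "sample_entropy_vt",
    "sample_entropy_ml",
    "composite",
    "log_divergence_vt",
    "log_divergence_ml",
    "log_divergence_ap",
)

CATEGORIES = ("very_low", "low", "moderate", "high")


@dataclass(frozen=True)
class GaitModelParams:
    """Parameters of the compass-gait trunk model.

    Defaults are calibrated to an older community-dwelling walker: step
    frequency 1.9 Hz and a 3.5 cm vertical excursion with 0.9 m legs give a
    compass-gait walking speed of ~0.94 m/s.

    Attributes
    ----------
    leg_length : float
        Pendulum (leg) length in m.
    step_frequency : float
        Steps per second, Hz. Stride frequency is half this.
    vertical_excursion : float
        Peak-to-trough vertical trunk displacement per step, m.
    ml_sway_amplitude, ap_amplitude : float
        Acceleration amplitudes of the ML (stride-frequency) and AP
        (step-frequency) oscillations, g.
    phase_jitter_sd : float
        SD of the per-stride phase random-walk increment, radians. Models
        stride-to-stride timing variability.
    amplitude_jitter_sd : float
        SD of the per-stride multiplicative amplitude perturbation
        (fraction, e.g. 0.05 = 5%).
    sensor_noise_sd : float
        White measurement noise SD on every channel, g.
    sampling_rate : float
        Hz; the wear protocol's 100 Hz by default.
    gravity_offset : float
        Constant offset on VT, g (1 g for a correctly oriented sensor).
    """

    leg_length: float = 0.90
    step_frequency: float = 1.9
    vertical_excursion: float = 0.035
    ml_sway_amplitude: float = 0.12
    ap_amplitude: float = 0.10
    phase_jitter_sd: float = 0.05
    amplitude_jitter_sd: float = 0.05
    sensor_noise_sd: float = 0.02
    sampling_rate: float = 100.0
    gravity_offset: float = 1.0

    def __post_init__(self) -> None:
        if self.leg_length <= 0:
            raise ValueError("leg_length must be positive")
        if not 0 < self.vertical_excursion < 2 * self.leg_length:
            raise ValueError("vertical_excursion must be in (0, 2*leg_length)")
        if not 0.5 < self.step_frequency < 4.0:
            raise ValueError("step_frequency must lie in (0.5, 4.0) Hz")
        if self.sampling_rate <= 2 * self.step_frequency:
            raise ValueError("sampling_rate must exceed twice the step frequency")
        for name in ("phase_jitter_sd", "amplitude_jitter_sd", "sensor_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def stride_frequency(self) -> float:
        return self.step_frequency / 2.0

    @property
    def step_length(self) -> float:
        """Compass-gait step length 2*sqrt(2*l*h - h^2), m."""
        l, h = self.leg_length, self.vertical_excursion
        return 2.0 * np.sqrt(2.0 * l * h - h * h)

    @property
    def walking_speed(self) -> float:
        """Commanded speed = stride frequency * stride length, m/s."""
        return self.stride_frequency * 2.0 * self.step_length


@dataclass(frozen=True)
class DaySchedule:
    """Walking bouts placed inside one simulated day.

    ``bout_specs`` is a list of ``(start_s, duration_s, GaitModelParams)``;
    bouts must be disjoint and fit in ``day_length`` hours. Non-bout time is
    quiet rest: gravity on VT plus white noise everywhere.
    """

    bout_specs: tuple = ()
    day_length: float = 24.0
    rest_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        day_s = self.day_length * 3600.0
        intervals = []
        for start, dur, params in self.bout_specs:
            if dur <= 0:
                raise ValueError("bout duration must be positive")
            if start < 0 or start + dur > day_s:
                raise ValueError("bout must lie within the day")
            if not isinstance(params, GaitModelParams):
                raise TypeError("third element of a bout spec must be GaitModelParams")
            intervals.append((start, start + dur))
        intervals.sort()
        for (_, e0), (s1, _) in zip(intervals, intervals[1:]):
            if s1 < e0:
                raise ValueError("bouts overlap")


def _stride_modulation(
    t: np.ndarray, stride_time: float, rng: np.random.Generator,
    phase_sd: float, amp_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-stride phase offset (random walk) and amplitude factor, sampled
    piecewise-constant over stride windows."""
    n_strides = int(np.floor(t[-1] / stride_time)) + 1 if t.size else 1
    # phase errors accumulate stride to stride, like real timing variability
    phase = np.cumsum(rng.normal(0.0, phase_sd, size=n_strides))
    amp = 1.0 + rng.normal(0.0, amp_sd, size=n_strides)
    amp = np.clip(amp, 0.1, None)
    idx = np.minimum((t / stride_time).astype(int), n_strides - 1)
    return phase[idx], amp[idx]


def generate_walking_accel(
    params: GaitModelParams, duration: float, seed: int
) -> AccelRecording:
    """Simulate steady-state walking for ``duration`` seconds.

    Deterministic given ``seed``. With all three noise SDs zero the output
    is exactly periodic with period ``1/step_frequency`` on VT/AP and
    ``2/step_frequency`` on ML. Samples are clipped to the ±6 g sensor range.
    """
    if duration < 1.0:
        raise ValueError("duration must be at least 1 s")
    rng = np.random.default_rng(seed)
    fs = params.sampling_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    f_step = params.step_frequency
    stride_time = 2.0 / f_step
    phase_off, amp = _stride_modulation(
        t, stride_time, rng, params.phase_jitter_sd, params.amplitude_jitter_sd
    )

    # vertical trunk trajectory z(t) = (h/2) cos(2π f_step t + φ); VT channel
    # carries gravity + z''(t) expressed in g
    w = 2.0 * np.pi * f_step
    arg = w * t + phase_off
    z_acc_g = -(params.vertical_excursion / 2.0) * w * w * np.cos(arg) / G
    vt = params.gravity_offset + amp * z_acc_g
    ml = amp * params.ml_sway_amplitude * np.sin(arg / 2.0)
    ap = amp * params.ap_amplitude * np.sin(arg)

    samples = np.column_stack([vt, ml, ap])
    if params.sensor_noise_sd > 0:
        samples = samples + rng.normal(0.0, params.sensor_noise_sd, size=samples.shape)
    np.clip(samples, -SENSOR_RANGE_G, SENSOR_RANGE_G, out=samples)
    return AccelRecording(sampling_rate=fs, samples=samples)


def generate_daily_recording(
    schedule: DaySchedule,
    n_days: int,
    seed: int,
    sampling_rate: float = 100.0,
    subject_id: str = "",
) -> tuple[AccelRecording, list[dict]]:
    """Simulate ``n_days`` days of wear following ``schedule``.

    Returns the recording and a ground-truth label list, one dict per
    embedded bout with keys ``day``, ``start_s``, ``end_s``, ``start_sample``,
    ``end_sample`` (absolute, half-open). Per-day random substreams are
    derived deterministically from ``seed``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    fs = sampling_rate
    day_samples = int(round(schedule.day_length * 3600.0 * fs))
    root = np.random.SeedSequence(seed)
    day_seeds = root.spawn(n_days)

    chunks, labels = [], []
    for day in range(n_days):
        day_rng = np.random.default_rng(day_seeds[day])
        samples = day_rng.normal(
            0.0, schedule.rest_noise_sd, size=(day_samples, 3)
        )
        samples[:, 0] += 1.0  # gravity on VT at rest
        for start_s, dur_s, params in schedule.bout_specs:
            p = replace(params, sampling_rate=fs)
            bout_seed = int(day_rng.integers(0, 2**31 - 1))
            bout = generate_walking_accel(p, dur_s, bout_seed)
            i0 = int(round(start_s * fs))
            i1 = i0 + bout.n_samples
            samples[i0:i1] = bout.samples
            labels.append(
                {
                    "day": day,
                    "start_s": day * schedule.day_length * 3600.0 + start_s,
                    "end_s": day * schedule.day_length * 3600.0 + start_s + dur_s,
                    "start_sample": day * day_samples + i0,
                    "end_sample": day * day_samples + i1,
                }
            )
        chunks.append(samples)

    all_samples = np.vstack(chunks)
    np.clip(all_samples, -SENSOR_RANGE_G, SENSOR_RANGE_G, out=all_samples)
    rec = AccelRecording(
        sampling_rate=fs, samples=all_samples, subject_id=subject_id
    )
    return rec, labels


# ---------------------------------------------------------------------------
# cohort-level simulation

#: Table-style defaults: category mix, per-category walking speed (m/s),
#: per-feature intercepts at the cohort's typical scale, category shifts
#: relative to the very-low reference, speed slopes and residual SDs.
_DEFAULT_CATEGORY_P = (0.226, 0.591, 0.115, 0.068)
_DEFAULT_SPEED_MEAN = {"very_low": 0.98, "low": 0.93, "moderate": 0.88, "high": 0.77}
_DEFAULT_SPEED_SD = {"very_low": 0.21, "low": 0.18, "moderate": 0.21, "high": 0.13}
_DEFAULT_INTERCEPT = {
    "sample_entropy_vt": 0.24,
    "sample_entropy_ml": 0.34,
    "composite": 0.71,
    "log_divergence_vt": 1.63,
    "log_divergence_ml": 1.96,
    "log_divergence_ap": 1.79,
}
_DEFAULT_SHIFTS = {
    # (low, moderate, high) additive shifts vs the very-low reference
    "sample_entropy_vt": (0.00, -0.01, -0.03),
    "sample_entropy_ml": (-0.01, -0.02, -0.03),
    "composite": (0.03, -0.11, 0.17),
    "log_divergence_vt": (0.03, 0.14, 0.19),
    "log_divergence_ml": (0.03, 0.09, 0.19),
    "log_divergence_ap": (0.04, 0.15, 0.22),
}
_DEFAULT_BETA_SPEED = {
    "sample_entropy_vt": 0.05,
    "sample_entropy_ml": 0.06,
    "composite": 2.0,
    "log_divergence_vt": -0.5,
    "log_divergence_ml": -0.4,
    "log_divergence_ap": -0.4,
}
_DEFAULT_RESIDUAL_SD = {
    "sample_entropy_vt": 0.035,
    "sample_entropy_ml": 0.045,
    "composite": 0.75,
    "log_divergence_vt": 0.35,
    "log_divergence_ml": 0.28,
    "log_divergence_ap": 0.28,
}
#: probability of a 12-month fall history, per category
_DEFAULT_FALL_P = {"very_low": 0.048, "low": 0.552, "moderate": 0.813, "high": 0.842}


def _as_feature_dict(value, default: dict) -> dict:
    if value is None:
        return dict(default)
    out = dict(default)
    out.update(value)
    return out


@dataclass
class CohortSimSpec:
    """Data-generating process for a cohort table.

    Each subject receives a fall-risk category (multinomial with
    ``category_probabilities``), a walking speed drawn from the category's
    normal distribution, and, per gait characteristic,
    ``intercept + shift[category] + beta_speed * speed + N(0, residual_sd)``.
    Covariates (age, sex, GDS, fall history) get category-dependent
    distributions so descriptive comparisons have something to find.
    """

    n_subjects: int = 279
    category_probabilities: tuple = _DEFAULT_CATEGORY_P
    beta_feature_by_category: dict | None = None
    beta_speed: dict | None = None
    speed_mean_by_category: dict | None = None
    speed_sd_by_category: dict | None = None
    intercepts: dict | None = None
    residual_sd: dict | None = None
    fall_history_p: dict | None = None
    on_empty_category: str = "resample"  # or "error"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 8:
            raise ValueError("n_subjects must be >= 8 (>=2 per category attainable)")
        p = np.asarray(self.category_probabilities, dtype=float)
        if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("category_probabilities must be 4 nonnegative values summing to 1")
        rs = _as_feature_dict(self.residual_sd, _DEFAULT_RESIDUAL_SD)
        if any(v <= 0 for v in rs.values()):
            raise ValueError("residual_sd must be positive")
        if self.on_empty_category not in ("resample", "error"):
            raise ValueError("on_empty_category must be 'resample' or 'error'")


def generate_cohort(spec: CohortSimSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table and return it with its ground-truth coefficients.

    Returns
    -------
    cohort : DataFrame
        One row per subject: ``subject_id``, ``category``,
        ``risk_factor_count``, ``walking_speed``, the six gait
        characteristics, and covariates ``age``, ``sex``, ``gds``,
        ``fall_history``.
    truth : dict
        All coefficients of the generating model, keyed per feature:
        ``intercept``, ``shifts`` (low/moderate/high vs very_low),
        ``beta_speed``, ``residual_sd``; plus the category probabilities.
    """
    shifts = _as_feature_dict(spec.beta_feature_by_category, _DEFAULT_SHIFTS)
    beta_speed = _as_feature_dict(spec.beta_speed, _DEFAULT_BETA_SPEED)
    intercepts = _as_feature_dict(spec.intercepts, _DEFAULT_INTERCEPT)
    resid = _as_feature_dict(spec.residual_sd, _DEFAULT_RESIDUAL_SD)
    sp_mean = _as_feature_dict(spec.speed_mean_by_category, _DEFAULT_SPEED_MEAN)
    sp_sd = _as_feature_dict(spec.speed_sd_by_category, _DEFAULT_SPEED_SD)
    fall_p = _as_feature_dict(spec.fall_history_p, _DEFAULT_FALL_P)

    rng = np.random.default_rng(spec.seed)
    p = np.asarray(spec.category_probabilities, dtype=float)

    cat_idx = rng.choice(4, size=spec.n_subjects, p=p)
    tries = 0
    while len(np.unique(cat_idx)) < 4:
        if spec.on_empty_category == "error":
            missing = [CATEGORIES[i] for i in range(4) if i not in cat_idx]
            raise ValueError(f"empty category after draw: {missing}")
        tries += 1
        if tries > 1000:
            raise RuntimeError("could not populate all categories in 1000 redraws")
        cat_idx = rng.choice(4, size=spec.n_subjects, p=p)

    cats = np.array(CATEGORIES)[cat_idx]
    speed = np.array(
        [rng.normal(sp_mean[c], sp_sd[c]) for c in cats]
    )
    speed = np.clip(speed, 0.2, None)

    # QuickScreen risk-factor counts consistent with the category bins
    count_range = {"very_low": (0, 1), "low": (2, 3), "moderate": (4, 4), "high": (5, 8)}
    counts = np.array(
        [rng.integers(count_range[c][0], count_range[c][1] + 1) for c in cats]
    )

    data = {
        "subject_id": [f"S{i:04d}" for i in range(spec.n_subjects)],
        "category": cats,
        "risk_factor_count": counts,
        "walking_speed": speed,
    }
    shift_full = {
        f: {"very_low": 0.0, "low": s[0], "moderate": s[1], "high": s[2]}
        for f, s in shifts.items()
    }
    for f in FEATURE_NAMES:
        cat_shift = np.array([shift_full[f][c] for c in cats])
        data[f] = (
            intercepts[f]
            + cat_shift
            + beta_speed[f] * speed
            + rng.normal(0.0, resid[f], size=spec.n_subjects)
        )

    age_mean = {"very_low": 69.5, "low": 70.8, "moderate": 74.5, "high": 78.0}
    data["age"] = np.array([rng.normal(age_mean[c], 4.5) for c in cats])
    data["sex"] = np.where(rng.random(spec.n_subjects) < 0.695, "F", "M")
    data["gds"] = np.round(
        np.clip(
            np.array([rng.normal({"very_low": 5.2, "low": 5.3, "moderate": 5.6, "high": 6.0}[c], 1.2) for c in cats]),
            0, 15,
        )
    )
    data["fall_history"] = np.array(
        [rng.random() < fall_p[c] for c in cats]
    )
    data["leg_length"] = np.clip(rng.normal(0.9, 0.05, size=spec.n_subjects), 0.7, 1.1)

    cohort = pd.DataFrame(data)
    truth = {
        "category_probabilities": tuple(p),
        "features": {
            f: {
                "intercept": intercepts[f],
                "shifts": shift_full[f],
                "beta_speed": beta_speed[f],
                "residual_sd": resid[f],
            }
            for f in FEATURE_NAMES
        },
        "speed_mean_by_category": sp_mean,
        "speed_sd_by_category": sp_sd,
    }
    return cohort, truth
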