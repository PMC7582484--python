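"""End-to-end orchestration: simulate -> extract -> aggregate -> analyze.

Drives the full chain on synthetic data with a single reproducible
configuration: per-subject recordings are simulated with category-dependent
gait parameters, segmented into walking bouts and 10-s epochs, reduced to
per-epoch characteristics and weekly medians, joined with QuickScreen
categories, and fed to the speed-adjusted and unadjusted category models.

The simulated "week" is deliberately scaled down (fractional-hour days, a
few bouts per day) so a full run stays desk-sized; every size is in
:class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as ft
from . import quickscreen as qs
from . import segmentation as seg
from . import stats as st
from .aggregation import AggregationConfig, median_over_epochs
from .recording import AccelRecording
from .synthetic import DaySchedule, GaitModelParams, generate_daily_recording

__all__ = ["RunConfig", "SimOutput", "simulate", "extract", "build_cohort", "analyze", "run_all"]

#: per-category gait-model presets: target speed (m/s) and stride-to-stride
#: phase jitter (rad) increase the physiological precariousness with risk
CATEGORY_GAIT = {
    "very_low": {"speed": 0.98, "phase_jitter_sd": 0.03},
    "low": {"speed": 0.93, "phase_jitter_sd": 0.05},
    "moderate": {"speed": 0.88, "phase_jitter_sd": 0.08},
    "high": {"speed": 0.77, "phase_jitter_sd": 0.12},
}


@dataclass
class RunConfig:
    """All pipeline knobs; every default is echoed into the run log."""

    seed: int = 0
    n_subjects: int = 8
    n_days: int = 3
    day_length_h: float = 0.2
    bouts_per_day: int = 2
    bout_duration_s: float = 60.0
    exclude_hours: float = 0.0
    category_probabilities: tuple = (0.25, 0.35, 0.2, 0.2)
    leg_length_mean: float = 0.9
    leg_length_sd: float = 0.05
    step_frequency: float = 1.9
    detector: seg.DetectorConfig = field(default_factory=seg.DetectorConfig)
    features: ft.FeatureConfig = field(default_factory=ft.FeatureConfig)
    aggregation: AggregationConfig = field(default_factory=AggregationConfig)
    alpha: float = 0.05
    bonferroni_k: int = 6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.name == "detector":
                v = seg.DetectorConfig(**v)
            elif f.name == "features":
                v = ft.FeatureConfig(**v)
            elif f.name == "aggregation":
                v = AggregationConfig(**v)
            elif f.name == "category_probabilities":
                v = tuple(v)
            kwargs[f.name] = v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["detector"]["band"] = list(d["detector"]["band"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class SimOutput:
    recordings: dict
    bout_labels: dict
    clinical: pd.DataFrame


def _params_for_speed(speed: float, leg_length: float, step_frequency: float,
                      phase_jitter_sd: float) -> GaitModelParams:
    """Invert the compass-gait speed formula: the vertical excursion that
    yields ``speed`` at the given leg length and step frequency."""
    step_len = speed / step_frequency
    h = leg_length - np.sqrt(max(leg_length**2 - step_len**2 / 4.0, 1e-9))
    return GaitModelParams(
        leg_length=leg_length,
        step_frequency=step_frequency,
        vertical_excursion=float(h),
        phase_jitter_sd=phase_jitter_sd,
    )


def simulate(config: RunConfig, seed: int | None = None) -> SimOutput:
    """Simulate recordings plus a clinical table for a small cohort.

    Each subject draws a fall-risk category; gait speed and stride-timing
    variability follow the category presets; QuickScreen items are drawn
    consistently with the category so the downstream scoring recovers it.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    p = np.asarray(config.category_probabilities, dtype=float)
    cats = rng.choice(st.CATEGORY_LEVELS, size=config.n_subjects, p=p)
    for _ in range(1000):  # all four categories must be populated downstream
        if len(set(cats)) == 4:
            break
        cats = rng.choice(st.CATEGORY_LEVELS, size=config.n_subjects, p=p)
    count_range = {"very_low": (0, 1), "low": (2, 3), "moderate": (4, 4), "high": (5, 8)}

    recordings, labels, rows = {}, {}, []
    day_s = config.day_length_h * 3600.0
    for i, cat in enumerate(cats):
        sid = f"S{i:03d}"
        leg = float(np.clip(rng.normal(config.leg_length_mean, config.leg_length_sd), 0.7, 1.1))
        preset = CATEGORY_GAIT[cat]
        speed = float(max(rng.normal(preset["speed"], 0.05), 0.4))
        params = _params_for_speed(speed, leg, config.step_frequency, preset["phase_jitter_sd"])

        slots = np.linspace(0, day_s - config.bout_duration_s - 1, config.bouts_per_day + 2)[1:-1]
        bouts = tuple((float(s), config.bout_duration_s, params) for s in slots)
        schedule = DaySchedule(bout_specs=bouts, day_length=config.day_length_h)
        rec, lab = generate_daily_recording(
            schedule, config.n_days, seed=int(rng.integers(0, 2**31 - 1)),
            subject_id=sid,
        )
        recordings[sid] = rec
        labels[sid] = lab

        count = int(rng.integers(*[b + o for b, o in zip(count_range[cat], (0, 1))]))
        item_flags = dict.fromkeys(qs.ITEMS, False)
        for name in rng.permutation(qs.ITEMS)[:count]:
            item_flags[name] = True
        rows.append(
            {
                "subject_id": sid,
                "age": float(rng.normal(72, 5)),
                "sex": "F" if rng.random() < 0.695 else "M",
                "leg_length": leg,
                "gds": float(np.clip(np.round(rng.normal(5.4, 1.2)), 0, 15)),
                "fall_history": bool(rng.random() < 0.5),
                "true_category": cat,
                "true_speed": speed,
                **item_flags,
            }
        )
    return SimOutput(recordings, labels, pd.DataFrame(rows))


def extract(
    sim: SimOutput, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signal chain per subject: calibrate, exclude wear-in, detect bouts,
    epoch, compute characteristics, take weekly medians.

    Returns (epoch-level table, subject-summary table). A subject whose
    recording is shorter than the exclusion window, or yields no episodes,
    is recorded with an ``error`` note and NaN summaries; the run continues.
    """
    clinical = sim.clinical.set_index("subject_id")
    epoch_rows, summary_rows = [], []
    for sid, rec in sim.recordings.items():
        leg = float(clinical.loc[sid, "leg_length"])
        try:
            cal, _ = seg.calibrate_orientation(rec)
            cal = seg.exclude_initial_hours(cal, config.exclude_hours)
        except ValueError as exc:
            summary_rows.append({"subject_id": sid, "error": str(exc)})
            continue
        episodes = seg.detect_locomotion(cal, config.detector)
        sub_epochs = []
        for eid, ep in enumerate(episodes):
            for epoch in seg.split_epochs(ep, cal, episode_id=eid):
                row = ft.compute_epoch_features(cal, epoch, leg_length=leg, config=config.features)
                row.update(subject_id=sid, episode=eid, epoch_start=epoch.start_sample)
                sub_epochs.append(row)
        if not sub_epochs:
            summary_rows.append({"subject_id": sid, "error": "no locomotion episodes"})
            continue
        epoch_df = pd.DataFrame(sub_epochs)
        epoch_rows.append(epoch_df)
        n_days = cal.duration / (config.day_length_h * 3600.0)
        summary = median_over_epochs(
            epoch_df,
            subject_id=sid,
            n_days=n_days,
            time_walking=seg.time_spent_walking(episodes, n_days),
            config=config.aggregation,
        )
        summary_rows.append(summary.as_row())

    epochs = pd.concat(epoch_rows, ignore_index=True) if epoch_rows else pd.DataFrame()
    return epochs, pd.DataFrame(summary_rows)


def build_cohort(summaries: pd.DataFrame, clinical: pd.DataFrame,
                 config: RunConfig | None = None) -> pd.DataFrame:
    """Join gait summaries with QuickScreen categories into the cohort table.

    Adds the gait-quality composite from the four z-scored components
    (cohort-internal normalization by default).
    """
    cfg = config or RunConfig()
    scored = []
    for _, row in clinical.iterrows():
        a = qs.assess({k: row[k] for k in qs.ITEMS})
        scored.append(
            {
                "subject_id": row["subject_id"],
                "risk_factor_count": a.risk_factor_count,
                "category": str(a.category),
            }
        )
    cohort = summaries.merge(pd.DataFrame(scored), on="subject_id")
    cohort = cohort.merge(
        clinical.drop(columns=[c for c in qs.ITEMS if c in clinical.columns]),
        on="subject_id",
    )
    comp_cols = list(ft.COMPOSITE_COMPONENTS)
    if all(c in cohort.columns for c in comp_cols):
        norm = ft.cohort_normalization(cohort[comp_cols].dropna())
        cohort["composite"] = [
            ft.composite_score(
                {c: row[c] for c in comp_cols},
                weights=cfg.features.composite_weights,
                normalization=norm,
                orientation=cfg.features.composite_orientation,
            )
            for _, row in cohort.iterrows()
        ]
    return cohort


def analyze(cohort: pd.DataFrame, config: RunConfig | None = None,
            dependents: tuple | None = None) -> dict:
    """Fit adjusted and unadjusted category models for every characteristic
    present, plus descriptive group comparisons.

    Returns a dict with ``adjusted`` / ``unadjusted`` ModelResult lists, the
    rendered contrast tables, the descriptives table and the Bonferroni
    threshold used for post-hoc decisions.
    """
    cfg = config or RunConfig()
    if dependents is None:
        candidates = (
            "sample_entropy_vt", "sample_entropy_ml", "composite",
            "log_divergence_vt", "log_divergence_ml", "log_divergence_ap",
        )
        dependents = tuple(c for c in candidates if c in cohort.columns)
    populated = cohort["category"].value_counts()
    missing = [c for c in st.CATEGORY_LEVELS if populated.get(c, 0) == 0]
    if len(st.CATEGORY_LEVELS) - len(missing) < 2:
        raise ValueError("fewer than 2 fall-risk categories populated")

    out = {"adjusted": [], "unadjusted": []}
    for dep in dependents:
        out["adjusted"].append(st.fit_gait_model(cohort, dep, adjust_speed=True))
        out["unadjusted"].append(st.fit_gait_model(cohort, dep, adjust_speed=False))
    out["table_adjusted"] = st.format_results_tables(out["adjusted"], cohort, cfg.alpha)
    out["table_unadjusted"] = st.format_results_tables(out["unadjusted"], cohort, cfg.alpha)
    out["contrasts_adjusted"] = st.contrast_table(out["adjusted"])
    out["contrasts_unadjusted"] = st.contrast_table(out["unadjusted"])
    out["descriptives"] = st.descriptive_comparisons(cohort)
    out["bonferroni_threshold"] = cfg.alpha / cfg.bonferroni_k
    return out


def run_all(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """simulate -> extract -> aggregate -> analyze; optionally write CSVs.

    Every emitted table gets a provenance header (config hash + seed) in a
    JSON run log next to the CSVs.
    """
    sim = simulate(config)
    epochs, summaries = extract(sim, config)
    ok = summaries
    if "walking_speed" in ok.columns:
        ok = ok.dropna(subset=["walking_speed"])
    cohort = build_cohort(ok, sim.clinical, config)
    results = analyze(cohort, config)
    out = {"sim": sim, "epochs": epochs, "summaries": summaries,
           "cohort": cohort, "results": results}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        epochs.to_csv(outdir / "epoch_features.csv", index=False)
        summaries.to_csv(outdir / "subject_summaries.csv", index=False)
        cohort.to_csv(outdir / "cohort.csv", index=False)
        results["contrasts_adjusted"].to_csv(outdir / "contrasts_adjusted.csv", index=False)
        results["contrasts_unadjusted"].to_csv(outdir / "contrasts_unadjusted.csv", index=False)
        results["table_adjusted"].to_csv(outdir / "table_adjusted.csv", index=False)
        results["table_unadjusted"].to_csv(outdir / "table_unadjusted.csv", index=False)
        results["descriptives"].to_csv(outdir / "descriptives.csv", index=False)
        log = {
            "config": config.to_dict(),
            "config_hash": config.digest(),
            "seed": config.seed,
            "n_subjects_analyzed": int(len(cohort)),
        }
        (outdir / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    return out
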