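"""Reading and writing accelerometry CSV files and clinical tables.

On-disk time-series format: a long CSV with columns ``time_s, vt_g, ml_g,
ap_g`` plus a JSON sidecar (``<name>.json``) carrying sampling rate, subject
id and calendar start time. Units are g on disk; conversion to m/s^2 happens
only where integration requires it. The clinical table is an ordinary CSV
with one row per subject; its column dictionary is documented in
docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import AccelRecording

__all__ = [
    "AccelReadConfig",
    "read_accel_csv",
    "write_accel_csv",
    "read_clinical_csv",
    "write_episode_csv",
]

_REQUIRED_COLS = ("time_s", "vt_g", "ml_g", "ap_g")


@dataclass
class AccelReadConfig:
    """Validation policy for :func:`read_accel_csv`.

    ``allow_gaps``: tolerate sampling gaps > 1.5 sample intervals, recording
    them in ``AccelRecording.gaps``; otherwise a gap is an error.
    ``rate_tolerance``: maximal relative deviation of the realized sampling
    rate from the declared one.
    """

    allow_gaps: bool = False
    rate_tolerance: float = 0.01


def write_accel_csv(rec: AccelRecording, path: str | Path) -> None:
    """Write a recording as CSV + JSON sidecar, lossless to ~1e-10 g."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": rec.times,
            "vt_g": rec.vt,
            "ml_g": rec.ml,
            "ap_g": rec.ap,
        }
    )
    df.to_csv(path, index=False, float_format="%.10f")
    sidecar = {
        "sampling_rate": rec.sampling_rate,
        "subject_id": rec.subject_id,
        "start_time": rec.start_time,
        "n_samples": rec.n_samples,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_accel_csv(
    path: str | Path, config: AccelReadConfig | None = None
) -> AccelRecording:
    """Read a recording, validating columns, monotone time and sampling rate.

    The declared sampling rate comes from the JSON sidecar next to ``path``
    (falling back to the median sample interval if no sidecar exists).
    """
    config = config or AccelReadConfig()
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    t = df["time_s"].to_numpy(dtype=float)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    declared_rate = float(meta.get("sampling_rate", 0.0))
    dt = np.diff(t)
    if len(dt) == 0:
        raise ValueError("recording must contain at least 2 samples")
    nominal_dt = 1.0 / declared_rate if declared_rate else float(np.median(dt))

    dup = np.flatnonzero(dt <= 0)
    if dup.size:
        raise ValueError(
            f"non-monotone or duplicated timestamps at row(s) {dup[0] + 1}"
            + ("" if dup.size == 1 else f" (+{dup.size - 1} more)")
        )

    gaps = []
    gap_rows = np.flatnonzero(dt > 1.5 * nominal_dt)
    if gap_rows.size:
        if not config.allow_gaps:
            raise ValueError(
                f"sampling gap at row {gap_rows[0] + 1} "
                f"(dt = {dt[gap_rows[0]]:.4f} s vs nominal {nominal_dt:.4f} s)"
            )
        gaps = [(int(i) + 1, float(dt[i])) for i in gap_rows]

    regular = dt[dt <= 1.5 * nominal_dt]
    realized_rate = 1.0 / float(np.mean(regular))
    if declared_rate and abs(realized_rate - declared_rate) / declared_rate > config.rate_tolerance:
        bad = np.flatnonzero(np.abs(dt - nominal_dt) > config.rate_tolerance * nominal_dt)
        lo = int(bad[0]) if bad.size else 0
        hi = int(bad[-1]) if bad.size else len(dt)
        raise ValueError(
            f"realized sampling rate {realized_rate:.3f} Hz deviates >"
            f"{config.rate_tolerance:.0%} from declared {declared_rate:g} Hz "
            f"(offending rows {lo + 1}..{hi + 1})"
        )

    return AccelRecording(
        sampling_rate=declared_rate or realized_rate,
        samples=df[["vt_g", "ml_g", "ap_g"]].to_numpy(dtype=float),
        subject_id=str(meta.get("subject_id", "")),
        start_time=str(meta.get("start_time", "2000-01-01T00:00:00")),
        gaps=gaps,
    )


#: columns expected in a clinical CSV; extra columns pass through untouched
CLINICAL_NUMERIC = (
    "age",
    "body_height",
    "body_weight",
    "leg_length",
    "mmse",
    "gds",
    "grip_strength",
    "knee_torque",
)


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    """Read the per-subject clinical table.

    Validates unique ``subject_id`` and numeric parsability; rows with a
    missing or non-positive ``leg_length`` get ``leg_length_valid = False``
    (walking-speed estimation refuses them later) rather than being dropped.
    """
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError("missing required column(s): subject_id")
    df["subject_id"] = df["subject_id"].astype(str)
    dup = df.loc[df["subject_id"].duplicated(), "subject_id"].unique()
    if dup.size:
        raise ValueError(f"duplicate subject_id: {', '.join(dup)}")
    for col in CLINICAL_NUMERIC:
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise ValueError(f"column {col!r} is not numeric: {exc}") from exc
    if "fall_history" in df.columns:
        df["fall_history"] = df["fall_history"].astype(bool)
    if "leg_length" in df.columns:
        df["leg_length_valid"] = df["leg_length"].notna() & (df["leg_length"] > 0)
    return df


def write_episode_csv(episodes, sampling_rate: float, path: str | Path, subject_id: str = "") -> None:
    """Serialize locomotion episodes as an interval table (subject, start_s, end_s)."""
    rows = [
        {
            "subject_id": subject_id,
            "start_s": ep.start_sample / sampling_rate,
            "end_s": ep.end_sample / sampling_rate,
        }
        for ep in episodes
    ]
    pd.DataFrame(rows, columns=["subject_id", "start_s", "end_s"]).to_csv(path, index=False)
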