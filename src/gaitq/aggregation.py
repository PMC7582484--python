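"""Per-subject weekly summaries: the median over all epochs of the week.

The weekly median over all walking epochs is the subject-level
representation of daily-life gait quality. Undefined epoch values (NaN) are
skipped per characteristic — never zero-filled — and a characteristic with
no defined epochs stays undefined. Subjects with too little data are
flagged, not dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AggregationConfig", "SubjectGaitSummary", "median_over_epochs"]

#: epoch-table columns that are summarized by median
FEATURE_COLUMNS = (
    "sample_entropy_vt",
    "sample_entropy_ml",
    "log_divergence_vt",
    "log_divergence_ml",
    "log_divergence_ap",
    "rms_ml",
    "index_harmonicity_ml",
    "dominant_amplitude_ap",
    "autocorr_dominant_vt",
    "stride_frequency",
    "stride_length",
    "walking_speed",
)


@dataclass(frozen=True)
class AggregationConfig:
    """Data-sufficiency thresholds; failing them flags a subject."""

    min_days: int = 4
    min_epochs: int = 10


@dataclass
class SubjectGaitSummary:
    """Weekly medians plus walking exposure for one subject."""

    subject_id: str
    medians: dict
    n_epochs: dict
    n_epochs_total: int
    n_days: float
    time_walking: float  # min/day
    flagged: bool
    flag_reason: str = ""

    def as_row(self) -> dict:
        row = {"subject_id": self.subject_id, **self.medians}
        row["n_epochs"] = self.n_epochs_total
        row["n_days"] = self.n_days
        row["time_walking"] = self.time_walking
        row["flagged"] = self.flagged
        return row


def median_over_epochs(
    epoch_features: pd.DataFrame,
    subject_id: str = "",
    n_days: float = 7.0,
    time_walking: float = float("nan"),
    config: AggregationConfig | None = None,
) -> SubjectGaitSummary:
    """Reduce a per-epoch feature table to one subject summary.

    Medians use the even-count convention (mean of the central two) and
    ignore NaN entries per characteristic; a characteristic with zero
    defined epochs yields NaN. Order of epochs is irrelevant.
    """
    cfg = config or AggregationConfig()
    medians, n_def = {}, {}
    for col in FEATURE_COLUMNS:
        if col not in epoch_features.columns:
            continue
        vals = epoch_features[col].to_numpy(dtype=float)
        defined = vals[np.isfinite(vals)]
        n_def[col] = int(defined.size)
        medians[col] = float(np.median(defined)) if defined.size else float("nan")

    n_total = len(epoch_features)
    flagged, reason = False, ""
    if n_total < cfg.min_epochs:
        flagged, reason = True, f"only {n_total} epochs (< {cfg.min_epochs})"
    elif n_days < cfg.min_days:
        flagged, reason = True, f"only {n_days:g} days (< {cfg.min_days})"

    return SubjectGaitSummary(
        subject_id=subject_id,
        medians=medians,
        n_epochs=n_def,
        n_epochs_total=n_total,
        n_days=n_days,
        time_walking=time_walking,
        flagged=flagged,
        flag_reason=reason,
    )
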