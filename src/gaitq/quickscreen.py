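"""QuickScreen physiological fall-risk scoring.

The QuickScreen counts eight binary risk factors spanning five domains —
fall history, medications (total count and psychoactive use), vision,
peripheral sensation, and strength/reaction/balance (sit-to-stand, near
tandem stand, alternate stepping). The risk-factor count maps onto four
risk categories: very low (0–1), low (2–3), moderate (4), high (>= 5).

Raw item measurements are thresholded into booleans by configurable
cut-offs; the defaults below are placeholders at clinically plausible
values and should be replaced with the validated instrument cut-offs for
any real administration.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping

__all__ = [
    "ITEMS",
    "RiskCategory",
    "QuickScreenAssessment",
    "count_risk_factors",
    "categorize",
    "assess",
    "items_from_measurements",
    "DEFAULT_CUTOFFS",
]

ITEMS = (
    "previous_falls",
    "polypharmacy",
    "psychoactive_medication",
    "impaired_visual_acuity",
    "impaired_tactile_sensitivity",
    "sit_to_stand_fail",
    "near_tandem_stand_fail",
    "alternate_step_fail",
)


class RiskCategory(IntEnum):
    """Four-level physiological fall-risk category (ordered)."""

    very_low = 0
    low = 1
    moderate = 2
    high = 3

    def __str__(self) -> str:  # cohort tables carry the lowercase names
        return self.name


@dataclass(frozen=True)
class QuickScreenAssessment:
    """Eight scored risk factors with their count and derived category."""

    items: dict
    risk_factor_count: int
    category: RiskCategory


def count_risk_factors(items: Mapping) -> int:
    """Number of present risk factors (0–8). Errors name any missing item."""
    missing = [k for k in ITEMS if k not in items or items[k] is None]
    if missing:
        raise ValueError(f"missing QuickScreen item(s): {', '.join(missing)}")
    return sum(bool(items[k]) for k in ITEMS)


def categorize(count: int) -> RiskCategory:
    """Map a risk-factor count to its category.

    0–1 -> very low, 2–3 -> low, 4 -> moderate, >= 5 -> high.
    """
    if not 0 <= count <= 8:
        raise ValueError(f"risk-factor count {count} outside [0, 8]")
    if count <= 1:
        return RiskCategory.very_low
    if count <= 3:
        return RiskCategory.low
    if count == 4:
        return RiskCategory.moderate
    return RiskCategory.high


def assess(items: Mapping) -> QuickScreenAssessment:
    """Score one subject: validated items -> count -> category."""
    count = count_risk_factors(items)
    return QuickScreenAssessment(
        items={k: bool(items[k]) for k in ITEMS},
        risk_factor_count=count,
        category=categorize(count),
    )


#: PLACEHOLDER cut-offs for thresholding raw measurements into items; the
#: validated instrument cut-offs should be substituted for real use.
DEFAULT_CUTOFFS = {
    "n_medications_min": 4,        # >= 4 medications -> polypharmacy
    "visual_acuity_max": 0.5,      # decimal acuity below this -> impaired
    "tactile_threshold_max": 4.0,  # monofilament log-units above -> impaired
    "sit_to_stand_max_s": 12.0,    # 5x sit-to-stand slower -> fail
    "near_tandem_min_s": 10.0,     # held shorter than this -> fail
    "alternate_step_max_s": 10.0,  # slower than this -> fail
}


def items_from_measurements(row: Mapping, cutoffs: Mapping | None = None) -> dict:
    """Threshold raw clinical measurements into the eight boolean items.

    Expects keys: ``previous_falls`` (bool), ``n_medications``,
    ``psychoactive_medication`` (bool), ``visual_acuity``,
    ``tactile_threshold``, ``sit_to_stand_s``, ``near_tandem_s``,
    ``alternate_step_s``.
    """
    c = dict(DEFAULT_CUTOFFS)
    if cutoffs:
        c.update(cutoffs)
    return {
        "previous_falls": bool(row["previous_falls"]),
        "polypharmacy": row["n_medications"] >= c["n_medications_min"],
        "psychoactive_medication": bool(row["psychoactive_medication"]),
        "impaired_visual_acuity": row["visual_acuity"] < c["visual_acuity_max"],
        "impaired_tactile_sensitivity": row["tactile_threshold"] > c["tactile_threshold_max"],
        "sit_to_stand_fail": row["sit_to_stand_s"] > c["sit_to_stand_max_s"],
        "near_tandem_stand_fail": row["near_tandem_s"] < c["near_tandem_min_s"],
        "alternate_step_fail": row["alternate_step_s"] > c["alternate_step_max_s"],
    }
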