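"""Association models between gait characteristics and fall-risk category.

Each gait characteristic is regressed on the four-level fall-risk category
(dummy-coded against the very-low reference), optionally adjusted for
walking speed (ANCOVA). All six pairwise category contrasts and their
standard errors come from the coefficient covariance matrix; the overall
category effect is the partial F test of the three dummy terms. Descriptive
group comparisons use linear-regression F for continuous measures,
Kruskal–Wallis for skewed scores (age, GDS) and chi-square for proportions
(sex, fall history), with a Bonferroni-corrected threshold for post-hoc
pairwise comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as spstats

__all__ = [
    "CATEGORY_LEVELS",
    "ModelResult",
    "fit_gait_model",
    "descriptive_comparisons",
    "bonferroni_adjust",
    "percent",
    "contrast_table",
    "format_results_tables",
]

CATEGORY_LEVELS = ("very_low", "low", "moderate", "high")

#: the 6 pairwise contrasts, each (reference, comparison)
PAIRS = tuple(itertools.combinations(CATEGORY_LEVELS, 2))


@dataclass
class ModelResult:
    """One fitted category model for one gait characteristic.

    ``contrasts[(a, b)]`` holds ``(beta, se, p)`` for level b minus level a;
    anti-symmetry beta(a,b) = -beta(b,a) with identical SE holds by
    construction since both come from the same covariance matrix.
    """

    dependent: str
    adjusted: bool
    n: int
    coef: dict
    contrasts: dict
    f_stat: float
    df_num: int
    df_den: int
    f_pvalue: float
    n_dropped: int = 0
    speed_beta: float | None = None

    def contrast(self, a: str, b: str):
        """(beta, se, p) for level ``b`` vs reference level ``a``."""
        if (a, b) in self.contrasts:
            return self.contrasts[(a, b)]
        beta, se, p = self.contrasts[(b, a)]
        return (-beta, se, p)


def _design(df: pd.DataFrame, adjust_speed: bool) -> tuple[np.ndarray, list[str]]:
    cols = ["intercept"] + [f"cat_{c}" for c in CATEGORY_LEVELS[1:]]
    X = [np.ones(len(df))]
    for c in CATEGORY_LEVELS[1:]:
        X.append((df["category"] == c).to_numpy(dtype=float))
    if adjust_speed:
        X.append(df["walking_speed"].to_numpy(dtype=float))
        cols.append("walking_speed")
    return np.column_stack(X), cols


def fit_gait_model(
    cohort: pd.DataFrame, dependent: str, adjust_speed: bool = True
) -> ModelResult:
    """OLS of ``dependent`` on fall-risk category (+ walking speed).

    Listwise deletion of rows with missing dependent/covariate values; the
    number dropped is recorded. Raises on a singular design, naming the
    cause (an empty category level or constant walking speed).
    """
    needed = [dependent, "category"] + (["walking_speed"] if adjust_speed else [])
    df = cohort.dropna(subset=[c for c in needed if c in cohort.columns])
    n_dropped = len(cohort) - len(df)

    present = set(df["category"])
    empty = [c for c in CATEGORY_LEVELS if c not in present]
    if len(present) < 2:
        raise ValueError("need subjects in at least 2 fall-risk categories")
    if empty:
        raise ValueError(f"singular design: empty category level(s) {', '.join(empty)}")
    if adjust_speed and df["walking_speed"].nunique() == 1:
        raise ValueError("singular design: walking_speed is constant")

    X, cols = _design(df, adjust_speed)
    y = df[dependent].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()

    level_vec = {}
    for c in CATEGORY_LEVELS:
        v = np.zeros(X.shape[1])
        if c != "very_low":
            v[cols.index(f"cat_{c}")] = 1.0
        level_vec[c] = v

    contrasts = {}
    for a, b in PAIRS:
        L = level_vec[b] - level_vec[a]
        tt = res.t_test(L)
        contrasts[(a, b)] = (
            float(np.squeeze(tt.effect)),
            float(np.squeeze(tt.sd)),
            float(np.squeeze(tt.pvalue)),
        )

    R = np.zeros((3, X.shape[1]))
    for i, c in enumerate(CATEGORY_LEVELS[1:]):
        R[i, cols.index(f"cat_{c}")] = 1.0
    ft = res.f_test(R)

    return ModelResult(
        dependent=dependent,
        adjusted=adjust_speed,
        n=len(df),
        coef=dict(zip(cols, res.params)),
        contrasts=contrasts,
        f_stat=float(np.squeeze(ft.fvalue)),
        df_num=int(ft.df_num),
        df_den=int(ft.df_denom),
        f_pvalue=float(np.squeeze(ft.pvalue)),
        n_dropped=n_dropped,
        speed_beta=float(res.params[cols.index("walking_speed")]) if adjust_speed else None,
    )


# ---------------------------------------------------------------------------
# descriptives


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Percentage with half-up rounding to ``decimals`` (as printed in
    descriptive tables)."""
    if total <= 0:
        raise ValueError("total must be positive")
    x = 100.0 * count / total
    q = 10.0**decimals
    return float(np.floor(x * q + 0.5) / q)


def descriptive_comparisons(
    cohort: pd.DataFrame,
    kruskal_vars: tuple = ("age", "gds"),
    chi2_vars: tuple = ("sex", "fall_history"),
    regression_vars: tuple | None = None,
) -> pd.DataFrame:
    """Compare descriptive characteristics between the four risk groups.

    Returns one row per variable with per-group summaries (mean (SD) for
    regression variables, median (IQR) for Kruskal–Wallis variables,
    N (%) for categorical ones), the overall test used, its statistic and
    p value.
    """
    groups = {c: cohort[cohort["category"] == c] for c in CATEGORY_LEVELS}
    if regression_vars is None:
        skip = set(kruskal_vars) | set(chi2_vars) | {
            "subject_id", "category", "risk_factor_count", "leg_length",
        }
        regression_vars = tuple(
            c for c in cohort.columns
            if c not in skip and pd.api.types.is_numeric_dtype(cohort[c])
            and cohort[c].dtype != bool
        )

    rows = []
    for var in regression_vars:
        vals = [g[var].dropna().to_numpy(dtype=float) for g in groups.values()]
        if any(len(v) < 2 for v in vals):
            continue
        f, p = spstats.f_oneway(*vals)  # equals the regression overall F
        rows.append(
            {
                "variable": var,
                "test": "linear_regression_F",
                "statistic": float(f),
                "p": float(p),
                **{
                    f"{c}_summary": f"{np.mean(v):.2f} ({np.std(v, ddof=1):.2f})"
                    for c, v in zip(groups, vals)
                },
            }
        )
    for var in kruskal_vars:
        if var not in cohort.columns:
            continue
        vals = [g[var].dropna().to_numpy(dtype=float) for g in groups.values()]
        h, p = spstats.kruskal(*vals)
        rows.append(
            {
                "variable": var,
                "test": "kruskal_wallis",
                "statistic": float(h),
                "p": float(p),
                **{
                    f"{c}_summary": (
                        f"{np.median(v):.1f} "
                        f"({np.percentile(v, 25):.1f}-{np.percentile(v, 75):.1f})"
                    )
                    for c, v in zip(groups, vals)
                },
            }
        )
    for var in chi2_vars:
        if var not in cohort.columns:
            continue
        table = pd.crosstab(cohort["category"], cohort[var])
        chi2, p, _, expected = spstats.chi2_contingency(table)
        if np.any(expected < 1):
            p = float("nan") if np.any(expected == 0) else p
        rows.append(
            {
                "variable": var,
                "test": "chi_square",
                "statistic": float(chi2),
                "p": float(p),
                **{
                    f"{c}_summary": f"n={len(groups[c])}" for c in groups
                },
            }
        )
    return pd.DataFrame(rows)


def chi2_on_counts(positives: list[int], totals: list[int]) -> tuple[float, float]:
    """Chi-square test of equal proportions given per-group counts."""
    table = np.array([positives, [t - p for p, t in zip(positives, totals)]]).T
    chi2, p, _, _ = spstats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def bonferroni_adjust(
    p_values, k: int | None = None, alpha: float = 0.05
) -> tuple[float, np.ndarray]:
    """Bonferroni-corrected per-comparison threshold and decisions.

    Returns ``(alpha / k, p < alpha / k)``; with the canonical alpha = 0.05
    and k = 6 pairwise group comparisons the threshold is 0.00833.
    """
    p = np.asarray(p_values, dtype=float)
    if k is None:
        k = p.size
    if k < 1:
        raise ValueError("k must be >= 1")
    threshold = alpha / k
    return threshold, p < threshold


# ---------------------------------------------------------------------------
# result tables


def contrast_table(results: list[ModelResult]) -> pd.DataFrame:
    """Long-format numeric table of every pairwise contrast of every model.

    Round-trips losslessly through CSV; the rendered lower-triangle view in
    :func:`format_results_tables` is derived from this.
    """
    rows = []
    for r in results:
        for (a, b), (beta, se, p) in r.contrasts.items():
            rows.append(
                {
                    "dependent": r.dependent,
                    "adjusted": r.adjusted,
                    "reference": a,
                    "group": b,
                    "beta": beta,
                    "se": se,
                    "p": p,
                    "n": r.n,
                    "F": r.f_stat,
                    "df_num": r.df_num,
                    "df_den": r.df_den,
                    "F_p": r.f_pvalue,
                }
            )
    return pd.DataFrame(rows)


def format_results_tables(
    results: list[ModelResult], cohort: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Lower-triangle rendering of the contrast grid, one block per
    dependent variable.

    Rows are the non-reference groups, columns the reference groups; each
    cell is "beta (SE), p" with a significance flag column instead of bold
    type. A "mean (SD)" column summarizes the whole-sample distribution of
    the dependent when a cohort table is supplied.
    """
    blocks = []
    for r in results:
        mean_sd = ""
        if cohort is not None and r.dependent in cohort.columns:
            v = cohort[r.dependent].dropna()
            mean_sd = f"{v.mean():.2f} ({v.std(ddof=1):.2f})"
        for b in CATEGORY_LEVELS[1:]:
            row = {
                "dependent": r.dependent,
                "adjusted": r.adjusted,
                "group": b,
                "mean_sd_total": mean_sd,
            }
            any_sig = False
            for a in CATEGORY_LEVELS[:-1]:
                if (a, b) not in r.contrasts:
                    row[f"vs_{a}"] = ""
                    continue
                beta, se, p = r.contrasts[(a, b)]
                row[f"vs_{a}"] = f"{beta:.2f} ({se:.2f}), {p:.2f}"
                any_sig |= p < alpha
            row["significant"] = any_sig
            blocks.append(row)
    return pd.DataFrame(blocks)
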