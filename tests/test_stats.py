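"""Category association models, descriptive comparisons and corrections."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from gaitq.synthetic import CohortSimSpec, generate_cohort
from gaitq.stats import (
    CATEGORY_LEVELS,
    bonferroni_adjust,
    chi2_on_counts,
    contrast_table,
    descriptive_comparisons,
    fit_gait_model,
    format_results_tables,
    percent,
)

from _oracles import chi2_permutation_p


@pytest.fixture(scope="module")
def cohort():
    c, _ = generate_cohort(CohortSimSpec(n_subjects=250, seed=17))
    return c


class TestFitGaitModel:
    def test_exact_fit_on_noiseless_design(self):
        # y constructed exactly linear in dummies + speed: residuals vanish
        rows = []
        truth = {"very_low": 0.0, "low": 0.2, "moderate": 0.5, "high": 0.9}
        speeds = [0.7, 0.8, 0.9, 1.0, 1.1]
        for cat in CATEGORY_LEVELS:
            for s in speeds:
                rows.append(
                    {"category": cat, "walking_speed": s, "y": 1.0 + truth[cat] - 0.4 * s}
                )
        res = fit_gait_model(pd.DataFrame(rows), "y", adjust_speed=True)
        assert res.coef["intercept"] == pytest.approx(1.0, abs=1e-10)
        assert res.speed_beta == pytest.approx(-0.4, abs=1e-10)
        for (a, b), (beta, _, _) in res.contrasts.items():
            assert beta == pytest.approx(truth[b] - truth[a], abs=1e-10)

    def test_contrast_equals_releveled_refit(self, cohort):
        res = fit_gait_model(cohort, "log_divergence_vt", adjust_speed=True)
        # independent route: formula API with 'low' as the reference level
        m = smf.ols(
            "log_divergence_vt ~ C(category, Treatment('low')) + walking_speed",
            data=cohort,
        ).fit()
        beta_ref = m.params["C(category, Treatment('low'))[T.moderate]"]
        beta, _, _ = res.contrast("low", "moderate")
        assert beta == pytest.approx(beta_ref, abs=1e-10)

    def test_contrast_antisymmetry(self, cohort):
        res = fit_gait_model(cohort, "sample_entropy_ml", adjust_speed=True)
        for (a, b), (beta, se, p) in res.contrasts.items():
            rb, rse, rp = res.contrast(b, a)
            assert rb == pytest.approx(-beta)
            assert rse == se and rp == p

    def test_residual_df_is_n_minus_five_when_adjusted(self, cohort):
        res = fit_gait_model(cohort, "composite", adjust_speed=True)
        assert res.df_num == 3
        assert res.df_den == res.n - 5
        res_u = fit_gait_model(cohort, "composite", adjust_speed=False)
        assert res_u.df_den == res_u.n - 4

    def test_adjusted_and_unadjusted_differ(self, cohort):
        a = fit_gait_model(cohort, "log_divergence_vt", adjust_speed=True)
        u = fit_gait_model(cohort, "log_divergence_vt", adjust_speed=False)
        assert a.adjusted and not u.adjusted
        assert a.contrasts[("very_low", "high")][0] != pytest.approx(
            u.contrasts[("very_low", "high")][0]
        )

    def test_empty_category_named(self, cohort):
        sub = cohort[cohort["category"] != "moderate"]
        with pytest.raises(ValueError, match="moderate"):
            fit_gait_model(sub, "composite", adjust_speed=True)

    def test_constant_speed_named(self, cohort):
        c = cohort.copy()
        c["walking_speed"] = 0.9
        with pytest.raises(ValueError, match="walking_speed"):
            fit_gait_model(c, "composite", adjust_speed=True)

    def test_listwise_deletion_logged(self, cohort):
        c = cohort.copy()
        c.loc[c.index[:7], "composite"] = np.nan
        res = fit_gait_model(c, "composite", adjust_speed=True)
        assert res.n == len(c) - 7
        assert res.n_dropped == 7


class TestDescriptives:
    def test_chi_square_matches_permutation_oracle(self):
        # faller counts per risk group from a descriptive table of printed
        # counts: 3/63, 91/165, 26/32, 16/19
        positives = [3, 91, 26, 16]
        totals = [63, 165, 32, 19]
        chi2, p = chi2_on_counts(positives, totals)
        stat_perm, p_perm = chi2_permutation_p(positives, totals, n_perm=20000, seed=5)
        assert chi2 == pytest.approx(stat_perm, abs=1e-8)
        # both p-values are far below any conventional level; agreement
        # within Monte-Carlo error means the permutation never exceeds it
        assert p < 1e-10
        assert p_perm <= 1 / 20000 * 2

    def test_kruskal_identical_groups_null(self):
        df = pd.DataFrame(
            {
                "category": np.repeat(CATEGORY_LEVELS, 30),
                "age": np.tile(np.arange(30, dtype=float), 4),
                "gds": np.tile(np.arange(30, dtype=float), 4),
                "walking_speed": 1.0,
            }
        )
        out = descriptive_comparisons(df, chi2_vars=())
        kw = out[out["test"] == "kruskal_wallis"]
        assert (kw["statistic"] < 1e-8).all()
        assert (kw["p"] > 0.99).all()

    def test_regression_f_null_uniform_p(self):
        # equal group means: p-values should not pile up near zero
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            df = pd.DataFrame(
                {
                    "category": rng.choice(CATEGORY_LEVELS, 120),
                    "body_weight": rng.normal(75, 12, 120),
                }
            )
            out = descriptive_comparisons(
                df, kruskal_vars=(), chi2_vars=(), regression_vars=("body_weight",)
            )
            ps.append(float(out["p"].iloc[0]))
        assert 0.02 < np.mean(np.array(ps) < 0.05) < 0.10

    def test_group_summaries_present(self, cohort):
        out = descriptive_comparisons(cohort)
        assert {"age", "gds", "sex", "fall_history"} <= set(out["variable"])
        assert "very_low_summary" in out.columns


class TestBonferroni:
    def test_six_pairwise_threshold(self):
        thr, _ = bonferroni_adjust([0.01] * 6, k=6)
        assert thr == pytest.approx(0.05 / 6)
        assert round(thr, 3) == 0.008

    def test_k_one_is_alpha(self):
        thr, dec = bonferroni_adjust([0.04], k=1)
        assert thr == 0.05 and dec[0]

    def test_threshold_logic(self):
        _, dec6 = bonferroni_adjust([0.01], k=6)
        _, dec2 = bonferroni_adjust([0.01], k=2)
        assert not dec6[0] and dec2[0]


class TestPercent:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(63, 279, 22.6), (165, 279, 59.1), (32, 279, 11.5), (19, 279, 6.8),
         (194, 279, 69.5), (26, 32, 81.3)],
    )
    def test_half_up_to_one_decimal(self, count, total, expected):
        assert percent(count, total) == expected


class TestTables:
    @pytest.fixture()
    def results(self, cohort):
        deps = ("sample_entropy_vt", "log_divergence_vt", "composite")
        return [fit_gait_model(cohort, d, adjust_speed=True) for d in deps]

    def test_block_structure(self, results, cohort):
        table = format_results_tables(results, cohort)
        assert len(table) == 3 * 3  # three dependents x three non-reference groups
        assert {"vs_very_low", "vs_low", "vs_moderate"} <= set(table.columns)
        # lower triangle: low group has no moderate column entry
        low_row = table[(table["group"] == "low")].iloc[0]
        assert low_row["vs_moderate"] == "" and low_row["vs_very_low"] != ""

    def test_adjusted_unadjusted_same_shape(self, cohort):
        a = format_results_tables(
            [fit_gait_model(cohort, "composite", adjust_speed=True)], cohort
        )
        u = format_results_tables(
            [fit_gait_model(cohort, "composite", adjust_speed=False)], cohort
        )
        assert list(a.columns) == list(u.columns)
        assert len(a) == len(u)

    def test_numeric_table_round_trips_csv(self, results, tmp_path):
        long = contrast_table(results)
        path = tmp_path / "contrasts.csv"
        long.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(
            back, long, check_exact=False, rtol=0, atol=1e-12
        )
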