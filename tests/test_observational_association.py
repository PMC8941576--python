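import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from suamr.errors import InsufficientDataError, InvalidParameterError, SeparationError
from suamr.observational_association import (
    AdjustmentSet,
    Covariate,
    QuartileScheme,
    adjustment_set,
    compute_quartile_scheme,
    fit_per_unit_or,
    fit_quartile_or,
    stratified_analysis,
)

UNADJ = adjustment_set("univariate")


def quartile_table(counts):
    """Build a one-sex table with given (cases, noncases) per quartile.

    Uses the fixed scheme male:(2,3,4) with representative values
    1.5/2.5/3.5/4.5 so assignment is unambiguous.
    """
    rows = []
    values = {1: 1.5, 2: 2.5, 3: 3.5, 4: 4.5}
    for k, (cases, noncases) in counts.items():
        for y, m in ((1, cases), (0, noncases)):
            rows.extend({"sex": "male", "sua": values[k], "nafld_followup": y} for _ in range(m))
    return pd.DataFrame(rows), QuartileScheme({"male": (2.0, 3.0, 4.0)})


def cross_product_or(cases_k, noncases_k, cases_1, noncases_1):
    return (cases_k * noncases_1) / (noncases_k * cases_1)


class TestQuartileScheme:
    def test_linear_interpolation_cutoffs(self):
        t = pd.DataFrame({"sex": "male", "sua": np.arange(1.0, 9.0)})
        scheme = compute_quartile_scheme(t)
        assert scheme.cutoffs["male"] == pytest.approx((2.75, 4.5, 6.25))

    def test_identical_values_raise(self):
        t = pd.DataFrame({"sex": "male", "sua": [5.0] * 10})
        with pytest.raises(InsufficientDataError):
            compute_quartile_scheme(t)

    def test_small_stratum_raises(self):
        t = pd.DataFrame({"sex": ["male"] * 3, "sua": [1.0, 2.0, 3.0]})
        with pytest.raises(InsufficientDataError):
            compute_quartile_scheme(t)

    def test_published_male_cutoffs(self):
        # the study's published male cutoffs: <4.47, >=4.47, >=5.23, >=6.10
        scheme = QuartileScheme({"male": (4.47, 5.23, 6.10)})
        assert scheme.assign([5.0], ["male"])[0] == 2
        assert scheme.assign([4.46], ["male"])[0] == 1
        assert scheme.assign([4.47], ["male"])[0] == 2  # left-closed
        assert scheme.assign([6.10], ["male"])[0] == 4

    def test_non_increasing_cutoffs_rejected(self):
        with pytest.raises(InvalidParameterError):
            QuartileScheme({"male": (5.0, 5.0, 6.0)})

    def test_nan_maps_to_unassigned(self):
        scheme = QuartileScheme({"male": (1.0, 2.0, 3.0)})
        assert scheme.assign([np.nan], ["male"])[0] == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_group_sizes_balanced_for_distinct_values(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 200))
        t = pd.DataFrame({"sex": "female", "sua": rng.permutation(np.arange(n)) + rng.random(n) * 0.5})
        scheme = compute_quartile_scheme(t)
        sizes = np.bincount(scheme.assign_frame(t), minlength=5)[1:]
        assert sizes.max() - sizes.min() <= 1


class TestFitQuartileOr:
    def test_2x2_cross_product_oracle(self):
        counts = {1: (20, 80), 2: (25, 75), 3: (30, 70), 4: (40, 60)}
        t, scheme = quartile_table(counts)
        res = fit_quartile_or(t, "nafld_followup", scheme, UNADJ)
        for k in (2, 3, 4):
            expected = cross_product_or(counts[k][0], counts[k][1], counts[1][0], counts[1][1])
            assert res.estimates[k].odds_ratio == pytest.approx(expected, rel=1e-6)

    def test_null_trend_p_roughly_uniform(self):
        rng = np.random.default_rng(7)
        pvals = []
        scheme = QuartileScheme({"male": (2.0, 3.0, 4.0)})
        for _ in range(200):
            n = 400
            t = pd.DataFrame(
                {
                    "sex": "male",
                    "sua": rng.uniform(1, 5, n),
                    "nafld_followup": rng.integers(0, 2, n),
                }
            )
            res = fit_quartile_or(t, "nafld_followup", scheme, UNADJ)
            pvals.append(res.trend_p)
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert 0.01 < frac < 0.11
        for e in res.estimates.values():
            assert 0.5 < e.odds_ratio < 2.0

    def test_monotone_ors_in_causal_cohort(self, causal_cohort):
        df, _ = causal_cohort
        scheme = compute_quartile_scheme(df)
        res = fit_quartile_or(df, "nafld_followup", scheme, UNADJ)
        ors = [res.estimates[k].odds_ratio for k in (2, 3, 4)]
        assert ors[0] < ors[1] < ors[2]
        assert res.trend_p < 0.001

    def test_constant_outcome_separation_error(self):
        t, scheme = quartile_table({1: (10, 0), 2: (10, 0), 3: (10, 0), 4: (10, 0)})
        with pytest.raises(SeparationError):
            fit_quartile_or(t, "nafld_followup", scheme, UNADJ)

    def test_trend_by_median_option(self):
        counts = {1: (20, 80), 2: (25, 75), 3: (30, 70), 4: (40, 60)}
        t, scheme = quartile_table(counts)
        res = fit_quartile_or(t, "nafld_followup", scheme, UNADJ, trend="median")
        assert 0 <= res.trend_p <= 1
        with pytest.raises(InvalidParameterError):
            fit_quartile_or(t, "nafld_followup", scheme, UNADJ, trend="rank")

    def test_wald_ci_brackets_estimate(self):
        counts = {1: (20, 80), 2: (25, 75), 3: (30, 70), 4: (40, 60)}
        t, scheme = quartile_table(counts)
        res = fit_quartile_or(t, "nafld_followup", scheme, UNADJ)
        for e in res.estimates.values():
            assert e.ci_low <= e.odds_ratio <= e.ci_high
            assert e.se > 0
            assert 0 <= e.p <= 1


class TestFitPerUnitOr:
    def test_unit_consistency_identity(self, causal_cohort):
        df, _ = causal_cohort
        mg = fit_per_unit_or(df, "nafld_followup", UNADJ, unit="mg_per_dl")
        um = fit_per_unit_or(df, "nafld_followup", UNADJ, unit="umol_per_l")
        assert mg.odds_ratio == pytest.approx(um.odds_ratio**59.5, rel=1e-10)

    def test_printed_umol_exponentiation(self):
        # 1.003 per umol/l corresponds to 1.003**59.5 ~ 1.195 per mg/dl
        assert 1.003**59.5 == pytest.approx(1.1953, abs=1e-3)

    def test_null_exposure_or_near_one(self):
        rng = np.random.default_rng(3)
        n = 4000
        t = pd.DataFrame(
            {
                "sex": "male",
                "sua": rng.normal(5, 1, n),
                "nafld_followup": rng.integers(0, 2, n),
            }
        )
        est = fit_per_unit_or(t, "nafld_followup", UNADJ)
        assert est.ci_low <= 1.0 <= est.ci_high

    def test_unknown_unit_raises(self, causal_cohort):
        df, _ = causal_cohort
        with pytest.raises(InvalidParameterError):
            fit_per_unit_or(df, "nafld_followup", UNADJ, unit="mmol_per_l")

    def test_independent_covariate_leaves_or_stable(self, causal_cohort):
        df, _ = causal_cohort
        df = df.copy()
        rng = np.random.default_rng(0)
        df["noise_cov"] = rng.normal(size=len(df))
        crude = fit_per_unit_or(df, "nafld_followup", UNADJ)
        adj = fit_per_unit_or(
            df, "nafld_followup", AdjustmentSet("noise", (Covariate("noise_cov"),))
        )
        assert adj.beta == pytest.approx(crude.beta, abs=2 * crude.se / 10)


class TestStratifiedAnalysis:
    def test_single_stratum_matches_unstratified(self, causal_cohort):
        df, _ = causal_cohort
        males = df[df["sex"] == "male"]
        res = stratified_analysis(males, "sex", fit_per_unit_or, UNADJ, outcome="nafld_followup")
        direct = fit_per_unit_or(males, "nafld_followup", UNADJ)
        assert res["male"].beta == pytest.approx(direct.beta)

    def test_bmi_strata_sizes_sum(self, causal_cohort):
        df, _ = causal_cohort
        res = stratified_analysis(
            df, "bmi_category", fit_per_unit_or, adjustment_set("model1"), outcome="nafld_followup"
        )
        assert sum(e.n for e in res.values()) == len(df)

    def test_stratification_variable_dropped_from_adjustment(self, causal_cohort):
        df, _ = causal_cohort
        adj = adjustment_set("model1")
        res = stratified_analysis(
            df, "sex", fit_quartile_or, adj,
            outcome="nafld_followup", scheme=compute_quartile_scheme(df),
        )
        for block in res.values():
            assert "sex" not in block.covariate_names

    def test_sex_strata_within_2se_of_pooled_when_no_sex_effect(self, causal_cohort):
        df, _ = causal_cohort
        pooled = fit_per_unit_or(df, "nafld_followup", UNADJ)
        res = stratified_analysis(df, "sex", fit_per_unit_or, UNADJ, outcome="nafld_followup")
        for est in res.values():
            assert abs(est.beta - pooled.beta) < 2 * est.se

    def test_missing_column_raises(self, causal_cohort):
        df, _ = causal_cohort
        with pytest.raises(InvalidParameterError):
            stratified_analysis(df.drop(columns=["bmi_category"]), "bmi_category", fit_per_unit_or, UNADJ)


class TestAdjustmentSets:
    def test_nesting_invariant(self):
        a = set(adjustment_set("age_sex").names)
        m1 = set(adjustment_set("model1").names)
        m2 = set(adjustment_set("model2").names)
        assert a <= m1 <= m2

    def test_unknown_name_raises(self):
        with pytest.raises(InvalidParameterError):
            adjustment_set("model3")

    def test_drop_and_plus(self):
        m1 = adjustment_set("model1")
        assert "sex" not in m1.drop("sex").names
        assert "waist" in m1.plus(Covariate("waist")).names
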