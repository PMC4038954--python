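import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hrrlab.errors import (
    InsufficientDataError,
    RankDeficiencyError,
    ValidationError,
)
from hrrlab.stats import (
    anova_bonferroni,
    backward_eliminate,
    fisher_exact,
    linear_regression,
    normality_gate,
    rank_tests,
    run_model1,
    run_model2,
    t_test_independent,
    table1_summary,
)


def fisher_two_sided_oracle(table):
    """Independent oracle: enumerate the hypergeometric distribution over all
    tables with the observed margins; sum probabilities <= P(observed)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def p_of(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = p_of(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = p_of(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


class TestNormalityGate:
    def test_normal_draws_pass(self):
        passes = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(0, 1, 50)
            passes += normality_gate(x) == "normal"
        assert passes >= 90

    def test_lognormal_draws_fail(self):
        fails = 0
        for seed in range(100):
            x = np.random.default_rng(seed).lognormal(0, 1.5, 50)
            fails += normality_gate(x) == "non-normal"
        assert fails >= 90

    def test_constant_vector_degenerate(self):
        assert normality_gate([5.0] * 10) == "non-normal"

    def test_small_n_rejected(self):
        with pytest.raises(InsufficientDataError):
            normality_gate([1.0, 2.0])


class TestTTest:
    def test_hand_computed_example(self):
        res = t_test_independent([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == 4
        assert res.p_value == pytest.approx(0.2878, abs=1e-4)

    def test_identical_groups(self):
        res = t_test_independent([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_huge_shift_tiny_variance(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.01, 10)
        res = t_test_independent(a, a + 100.0)
        assert res.p_value < 1e-6

    def test_degenerate_equal_constants(self):
        res = t_test_independent([2.0, 2.0], [2.0, 2.0])
        assert res.degenerate and res.p_value == 1.0


class TestAnovaBonferroni:
    def test_identical_groups(self):
        g = {"a": [1.0, 2, 3], "b": [1.0, 2, 3], "c": [1.0, 2, 3]}
        res = anova_bonferroni(g)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert all(p == pytest.approx(1.0) for p in res.pairwise.values())

    def test_one_shifted_group(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 30)
        g = {"a": base, "b": base + rng.normal(0, 1, 30) * 0.01, "c": base + 50}
        res = anova_bonferroni(g)
        assert res.pairwise[("a", "b")] > 0.9
        assert res.pairwise[("a", "c")] < 1e-6
        assert res.pairwise[("b", "c")] < 1e-6

    def test_bonferroni_cap(self):
        # raw pairwise p around 0.5 -> adjusted capped at 1.0
        rng = np.random.default_rng(2)
        g = {k: rng.normal(0, 1, 10) for k in "abc"}
        res = anova_bonferroni(g)
        assert all(p <= 1.0 for p in res.pairwise.values())


class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact([[1, 1], [1, 1]]).p_value == pytest.approx(1.0)

    def test_sex_distribution_table(self):
        # men/women split in controls vs patients: significant, and equal to
        # the full hypergeometric enumeration
        res = fisher_exact([[9, 9], [36, 5]])
        assert res.p_value == pytest.approx(fisher_two_sided_oracle([[9, 9], [36, 5]]), rel=1e-9)
        assert res.p_value < 0.05

    def test_perfect_separation(self):
        res = fisher_exact([[0, 10], [10, 0]])
        assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_matches_enumeration_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            res = fisher_exact(t)
            assert res.p_value == pytest.approx(
                fisher_two_sided_oracle(t.tolist()), rel=1e-9, abs=1e-12
            )

    def test_empty_margin_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact([[0, 0], [5, 3]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact([[1.5, 2], [3, 4]])


class TestRankTests:
    def test_identical_small_groups(self):
        res = rank_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_small_groups_exact(self):
        # U = 0; all 20 arrangements -> two-sided p = 2/20 = 0.1
        res = rank_tests([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.1)
        assert "exact" in res.test

    def test_exact_vs_asymptotic_agreement_n25(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            a = rng.normal(0, 1, 25)
            b = rng.normal(0.4, 1, 25)
            ours = rank_tests(a, b)  # asymptotic path at n=25
            exact = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(float(exact.pvalue), abs=0.02)

    def test_kruskal_three_groups(self):
        rng = np.random.default_rng(6)
        res = rank_tests(rng.normal(0, 1, 20), rng.normal(0, 1, 20), rng.normal(3, 1, 20))
        assert res.test == "kruskal_wallis"
        assert res.p_value < 0.001

    def test_all_tied_degenerate(self):
        res = rank_tests([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.degenerate and res.p_value == 1.0


class TestLinearRegression:
    def test_perfect_fit(self):
        x = np.arange(10, dtype=float)
        y = 3 + 2 * x
        model = linear_regression(y, pd.DataFrame({"x": x}))
        assert model.coefficients["x"]["b"] == pytest.approx(2.0)
        assert model.coefficients["const"]["b"] == pytest.approx(3.0)
        assert model.r_squared == pytest.approx(1.0)

    def test_ci_contains_estimate(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 50)
        y = 1 + 0.5 * x + rng.normal(0, 1, 50)
        model = linear_regression(y, pd.DataFrame({"x": x}))
        c = model.coefficients["x"]
        assert c["ci_low"] <= c["b"] <= c["ci_high"]

    def test_duplicate_column_rank_deficiency(self):
        x = np.arange(10, dtype=float)
        X = pd.DataFrame({"x1": x, "x2": x})
        with pytest.raises(RankDeficiencyError) as err:
            linear_regression(x * 2, X)
        assert set(err.value.columns) & {"x1", "x2"}

    def test_too_few_rows(self):
        with pytest.raises(InsufficientDataError):
            linear_regression([1.0, 2.0], pd.DataFrame({"x": [1.0, 2.0]}))


class TestBackwardEliminate:
    @staticmethod
    def strong_design(rng, n=59):
        X = pd.DataFrame(
            {
                "x1": rng.uniform(0, 10, n),
                "x2": rng.uniform(0, 10, n),
            }
        )
        y = 2 + 3 * X["x1"] - 2 * X["x2"] + rng.normal(0, 1, n)
        return y.to_numpy(), X

    def test_all_significant_unchanged(self):
        y, X = self.strong_design(np.random.default_rng(8))
        model = backward_eliminate(y, X)
        assert model.retained == ["x1", "x2"]
        assert model.eliminated == []

    def test_noise_covariate_removed_first(self):
        removed_first = 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y, X = self.strong_design(rng)
            X = X.copy()
            X["noise"] = rng.normal(0, 1, len(X))
            model = backward_eliminate(y, X)
            if model.eliminated and model.eliminated[0] == "noise":
                removed_first += 1
            elif not model.eliminated and "noise" not in model.retained:
                removed_first += 1
        assert removed_first >= 0.9 * n_seeds

    def test_threshold_one_keeps_everything(self):
        rng = np.random.default_rng(9)
        y, X = self.strong_design(rng)
        X = X.copy()
        X["noise"] = rng.normal(0, 1, len(X))
        model = backward_eliminate(y, X, threshold=1.0)
        assert model.retained == ["x1", "x2", "noise"]

    def test_forced_covariate_survives(self):
        rng = np.random.default_rng(10)
        y, X = self.strong_design(rng)
        X = X.copy()
        X["noise"] = rng.normal(0, 1, len(X))
        model = backward_eliminate(y, X, forced=("noise",))
        assert "noise" in model.retained

    def test_order_invariance_with_distinct_p(self):
        rng = np.random.default_rng(11)
        y, X = self.strong_design(rng)
        X = X.copy()
        X["noise_a"] = rng.normal(0, 1, len(X))
        X["noise_b"] = rng.normal(0, 5, len(X))
        m1 = backward_eliminate(y, X)
        m2 = backward_eliminate(y, X[list(reversed(X.columns))])
        assert set(m1.retained) == set(m2.retained)


def synthetic_model_frame(rng, n_control=18, n_patients=41, signal=True):
    """Pooled frame where HR at 1 min depends only on peak HR and disease."""
    n = n_control + n_patients
    is_patient = np.array([0.0] * n_control + [1.0] * n_patients)
    frame = pd.DataFrame(
        {
            "is_patient": is_patient.astype(bool),
            "sex": rng.choice(["male", "female"], n),
            "age": rng.normal(45, 12, n),
            "bmi": rng.normal(27, 4, n),
            "hr_peak": rng.normal(160, 20, n),
            "peak_vo2": rng.normal(28, 7, n),
        }
    )
    noise = rng.normal(0, 4, n)
    if signal:
        y = 10 + 0.8 * frame["hr_peak"] + 8.0 * is_patient + noise
    else:
        y = rng.normal(120, 10, n)
    frame["hr_at_60"] = y
    frame["hr_at_120"] = y + rng.normal(0, 1, n)
    frame["hr_at_180"] = y + rng.normal(0, 1, n)
    return frame


class TestModel1:
    def test_recovers_planted_structure(self):
        # planted predictors always retained; exact-set recovery is capped by
        # the per-covariate false-retention rate (~1 - 0.95^4), so it is only
        # asserted at a level the threshold admits
        recovered = exact = 0
        n_seeds = 20
        for seed in range(n_seeds):
            frame = synthetic_model_frame(np.random.default_rng(seed))
            model = run_model1(frame)["hr_at_60"]
            if {"hr_peak", "is_patient"} <= set(model.retained):
                recovered += 1
            if set(model.retained) == {"hr_peak", "is_patient"}:
                exact += 1
        assert recovered >= 0.9 * n_seeds
        assert exact >= 0.6 * n_seeds

    def test_pure_noise_mostly_intercept_only(self):
        empty = 0
        n_seeds = 20
        for seed in range(100, 100 + n_seeds):
            frame = synthetic_model_frame(np.random.default_rng(seed), signal=False)
            model = run_model1(frame)["hr_at_60"]
            if len(model.retained) <= 1:
                empty += 1
        assert empty >= 0.6 * n_seeds

    def test_single_group_rank_deficiency(self):
        frame = synthetic_model_frame(np.random.default_rng(0), n_control=0)
        with pytest.raises(RankDeficiencyError):
            run_model1(frame)


def synthetic_patient_frame(rng, n=41, gradient_effect=0.15):
    frame = pd.DataFrame(
        {
            "is_patient": [True] * n,
            "sex": rng.choice(["male", "female"], n),
            "hr_peak": rng.normal(150, 20, n),
            "e_eprime_lateral": rng.normal(9, 3, n),
            "la_size": rng.normal(44, 6, n),
            "ef": rng.normal(67, 8, n),
            "mwt": rng.normal(18, 3, n),
            "lvot_gradient_peak": rng.lognormal(np.log(30), 1.0, n),
        }
    )
    y = 40 + 0.45 * frame["hr_peak"] + gradient_effect * frame["lvot_gradient_peak"]
    frame["hr_at_180"] = y + rng.normal(0, 3, n)
    frame["hr_at_60"] = rng.normal(120, 10, n)
    frame["hr_at_120"] = rng.normal(115, 10, n)
    return frame


class TestModel2:
    def test_gradient_effect_recovered(self):
        rng = np.random.default_rng(42)
        frame = synthetic_patient_frame(rng)
        reports = run_model2(frame, responses=("hr_at_180",))
        rep = reports["hr_at_180"]
        assert "lvot_gradient_peak" in rep.screen_passed
        b = rep.stage2.coefficients["lvot_gradient_peak"]["b"]
        assert b == pytest.approx(0.15, abs=0.08)

    def test_null_gradient_usually_screened_out(self):
        rejected = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            frame = synthetic_patient_frame(rng, gradient_effect=0.0)
            rep = run_model2(frame, responses=("hr_at_180",))["hr_at_180"]
            if "lvot_gradient_peak" not in rep.screen_passed:
                rejected += 1
        assert rejected >= 0.8 * n_seeds

    def test_forced_model1_covariates_survive(self):
        rng = np.random.default_rng(1)
        frame = synthetic_patient_frame(rng)
        from hrrlab.stats import RegressionModel

        model1 = {
            "hr_at_180": RegressionModel(
                response="hr_at_180",
                coefficients={},
                n=59,
                retained=["hr_peak", "is_patient"],
            )
        }
        rep = run_model2(frame, model1, responses=("hr_at_180",))["hr_at_180"]
        assert "hr_peak" in rep.stage2.retained

    def test_control_rows_rejected(self):
        rng = np.random.default_rng(2)
        frame = synthetic_patient_frame(rng)
        frame.loc[0, "is_patient"] = False
        with pytest.raises(ValidationError):
            run_model2(frame)


class TestTable1Summary:
    @staticmethod
    def small_cohort_frame(rng, n=15):
        groups = ["control"] * n + ["nonobstructive"] * n + ["obstructive"] * n
        m = len(groups)
        frame = pd.DataFrame(
            {
                "group": groups,
                "sex": rng.choice(["male", "female"], m),
                "age": rng.normal(45, 10, m),
                "hr_rest": rng.normal(78, 12, m),
                "hr_peak": rng.normal(160, 18, m),
            }
        )
        frame["delta_hr"] = frame["hr_peak"] - frame["hr_rest"]
        return frame

    def test_identical_subjects_zero_sd(self):
        frame = pd.DataFrame(
            {
                "group": ["control"] * 5 + ["nonobstructive"] * 5 + ["obstructive"] * 5,
                "sex": ["male"] * 15,
                "age": [40.0] * 15,
            }
        )
        table = table1_summary(frame)
        age_row = table[table["variable"] == "Age (yrs)"].iloc[0]
        assert "40.0" in age_row["control"]

    def test_delta_hr_linearity_identity(self):
        frame = self.small_cohort_frame(np.random.default_rng(3))
        for group in ("control", "nonobstructive", "obstructive"):
            sub = frame[frame["group"] == group]
            assert sub["delta_hr"].mean() == pytest.approx(
                sub["hr_peak"].mean() - sub["hr_rest"].mean(), rel=1e-12
            )

    def test_group_columns_present(self):
        frame = self.small_cohort_frame(np.random.default_rng(4))
        table = table1_summary(frame)
        assert {"control", "all_patients", "nonobstructive", "obstructive"} <= set(
            table.columns
        )
        assert (table["variable"] == "Men").any()
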