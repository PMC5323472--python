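"""Cohort statistics against hand calculations and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from osteodose.cohort import (
    baseline_comparison,
    cox_multivariable,
    dichotomize,
    fisher_response_test,
    km_logrank,
    max_change_from_baseline,
    pearson_log,
)


def surv_frame(times, events, groups=None, **cov):
    df = pd.DataFrame({"survival_months": times, "event": events})
    if groups is not None:
        df["grp"] = groups
    for k, v in cov.items():
        df[k] = v
    return df


class TestPearsonLog:
    def test_exact_linear_relation(self):
        x = np.array([1.0, 2.0, 5.0, 10.0, 20.0])
        res = pearson_log(x, 2.0 * np.log(x))
        assert res.r == pytest.approx(1.0)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 1, 10_000)
        res = pearson_log(x, rng.normal(size=10_000))
        assert abs(res.r) < 0.03

    def test_hand_table_matches_textbook_formula(self):
        """Five-point table against the direct sum formula for r."""
        x = np.array([1.5, 3.0, 7.0, 12.0, 40.0])
        y = np.array([2.1, 1.3, 4.4, 3.9, 5.0])
        lx = np.log(x)
        n = 5
        r_direct = (n * np.sum(lx * y) - lx.sum() * y.sum()) / np.sqrt(
            (n * np.sum(lx**2) - lx.sum() ** 2) * (n * np.sum(y**2) - y.sum() ** 2)
        )
        res = pearson_log(x, y)
        assert res.r == pytest.approx(r_direct, abs=1e-12)
        assert res.ci_low < res.r < res.ci_high

    def test_nonpositive_x_rejected(self):
        with pytest.raises(ValueError, match="log"):
            pearson_log([1.0, 0.0, 2.0], [1.0, 2.0, 3.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_log([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestMaxChange:
    def test_decline_to_nadir(self):
        assert max_change_from_baseline([100.0, 80.0, 40.0, 60.0]) == pytest.approx(0.60)

    def test_rising_marker_non_positive(self):
        assert max_change_from_baseline([100.0, 120.0, 150.0]) <= 0.0

    def test_hand_example(self):
        assert max_change_from_baseline([200.0, 180.0, 90.0, 120.0]) == pytest.approx(0.55)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            max_change_from_baseline([np.nan, 50.0])


class TestKaplanMeierLogrank:
    def test_identical_groups_no_difference(self):
        df = surv_frame([1, 2, 3, 4] * 2, [1] * 8, ["a"] * 4 + ["b"] * 4)
        res = km_logrank(df, "grp")
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.logrank_p == pytest.approx(1.0)

    def test_product_limit_hand_oracle(self):
        """Six subjects, one censored at 2.5: S = 5/6, 2/3, 4/9, 2/9, 0 at
        the event times 1, 2, 3, 4, 5 (hand product-limit calculation)."""
        times = [1.0, 2.0, 2.5, 3.0, 4.0, 5.0]
        events = [1, 1, 0, 1, 1, 1]
        df = surv_frame(times * 2, events * 2, ["a"] * 6 + ["b"] * 6)
        res = km_logrank(df, "grp")
        curve = res.curves["a"].set_index("time")["survival"]
        expected = {1.0: 5 / 6, 2.0: 2 / 3, 3.0: 4 / 9, 4.0: 2 / 9, 5.0: 0.0}
        for t, s in expected.items():
            assert curve.loc[t] == pytest.approx(s, abs=1e-12)
        assert res.median_os["a"] == pytest.approx(3.0)

    def test_censoring_never_decreases_km(self):
        """Converting an event to censored cannot lower later estimates."""
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        with_event = surv_frame(times * 2, [1, 1, 1, 1, 1, 1] * 2, ["a"] * 6 + ["b"] * 6)
        with_censor = surv_frame(times * 2, [1, 1, 0, 1, 1, 1] * 2, ["a"] * 6 + ["b"] * 6)
        s_event = km_logrank(with_event, "grp").curves["a"].set_index("time")["survival"]
        s_censor = km_logrank(with_censor, "grp").curves["a"].set_index("time")["survival"]
        common = s_event.index.intersection(s_censor.index)
        assert np.all(s_censor.loc[common] >= s_event.loc[common] - 1e-12)

    def test_zero_event_group_flags_hr(self):
        df = surv_frame([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0], ["a"] * 3 + ["b"] * 3)
        with pytest.warns(UserWarning, match="zero events"):
            res = km_logrank(df, "grp")
        assert not res.hr_defined
        assert np.isnan(res.hazard_ratio)

    def test_hr_recovery_from_exponential_groups(self):
        """True HR 0.4 between exponential groups is recovered inside the
        interval (0.3, 0.53) at n=500 (single seeded draw)."""
        rng = np.random.default_rng(12)
        n = 250
        t_a = rng.exponential(1.0, n)
        t_b = rng.exponential(1.0 / 0.4, n)  # hazard 0.4
        df = surv_frame(
            np.concatenate([t_a, t_b]), [1] * (2 * n), ["a"] * n + ["b"] * n
        )
        res = km_logrank(df, "grp")
        assert 0.3 < res.hazard_ratio < 0.53
        assert res.hr_ci[0] < res.hazard_ratio < res.hr_ci[1]
        assert res.logrank_p < 0.001


class TestCoxMultivariable:
    def test_binary_covariate_matches_km_hr(self):
        rng = np.random.default_rng(5)
        n = 120
        grp = np.repeat([0.0, 1.0], n // 2)
        times = rng.exponential(1.0 / np.exp(0.7 * grp))
        df = surv_frame(times, [1] * n, np.where(grp > 0, "b", "a"), binary=grp)
        km = km_logrank(df, "grp")
        cox = cox_multivariable(df, ["binary"])
        assert cox.hazard_ratios["binary"] == pytest.approx(km.hazard_ratio, rel=1e-6)

    def test_duplicated_covariate_flagged(self):
        rng = np.random.default_rng(6)
        n = 60
        x = rng.normal(size=n)
        df = surv_frame(rng.exponential(1, n), [1] * n, None, x1=x, x2=x)
        with pytest.raises(ValueError, match="rank-deficient"):
            cox_multivariable(df, ["x1", "x2"])

    def test_few_events_warns(self):
        rng = np.random.default_rng(7)
        n = 20
        df = surv_frame(
            rng.exponential(1, n), [1] * 5 + [0] * 15, None,
            x1=rng.normal(size=n), x2=rng.normal(size=n),
        )
        with pytest.warns(UserWarning, match="events"):
            res = cox_multivariable(df, ["x1", "x2"])
        assert res.warnings_

    def test_coefficient_recovery_within_2se(self):
        """log-hazard 0.8 per unit ln(volume): the fitted coefficient lands
        within 2 standard errors (single seeded cohort, n=300)."""
        from osteodose.synthetic import CohortModel, generate_cohort

        table = generate_cohort(CohortModel(n_patients=300, log_hazard_per_log_volume=0.8, seed=21))
        table["ln_disease_volume"] = np.log(table.disease_volume_ml)
        res = cox_multivariable(table, ["ln_disease_volume"])
        coef = res.coefficients["ln_disease_volume"]
        se = res.standard_errors["ln_disease_volume"]
        assert abs(coef - 0.8) < 2 * se

    def test_summary_table_shape(self):
        rng = np.random.default_rng(9)
        n = 100
        df = surv_frame(rng.exponential(1, n), [1] * n, None, x=rng.normal(size=n))
        summary = cox_multivariable(df, ["x"]).summary()
        assert list(summary.columns) == ["coef", "se", "HR", "HR 95% low", "HR 95% high", "p"]


class TestDichotomize:
    def test_median_split_even(self):
        df = pd.DataFrame({"v": np.arange(1.0, 11.0)})
        labels = dichotomize(df, "v", "median")
        assert (labels == "below").sum() == 5
        assert (labels == "above").sum() == 5

    def test_fixed_cutpoint(self):
        df = pd.DataFrame({"v": [2.5, 3.1, 5.0, 5.0]})
        labels = dichotomize(df, "v", "fixed_cutpoint", cutpoint=3.5)
        assert (labels == "below").sum() == 2
        assert (labels == "above").sum() == 2

    def test_odd_n_median_value_goes_below(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        labels = dichotomize(df, "v", "median")
        assert labels.tolist() == ["below", "below", "above"]

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            dichotomize(pd.DataFrame({"v": [2.0, 2.0, 2.0]}), "v", "median")


from tests_oracles import fisher_two_sided_oracle, mannwhitney_two_sided_oracle


class TestFisherExact:
    def test_symmetric_table_p_one(self):
        assert fisher_response_test([[5, 5], [5, 5]]) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [[[3, 7], [8, 2]], [[1, 9], [5, 5]], [[0, 4], [6, 2]]])
    def test_matches_enumeration_oracle(self, table):
        assert fisher_response_test(table) == pytest.approx(
            fisher_two_sided_oracle(table), abs=1e-12
        )

    def test_transpose_invariance(self):
        t = [[3, 7], [8, 2]]
        tt = [[3, 8], [7, 2]]
        assert fisher_response_test(t) == pytest.approx(fisher_response_test(tt), abs=1e-12)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_response_test([[0, 0], [3, 4]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_response_test([[1.5, 2.0], [3.0, 4.0]])


class TestBaselineComparison:
    def test_identical_groups_p_one(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        group = pd.Series(["a"] * 3 + ["b"] * 3)
        p, method = baseline_comparison(df, "v", group)
        assert p > 0.99

    def test_shifted_normals_detected(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 200)
        b = rng.normal(2, 1, 200)
        df = pd.DataFrame({"v": np.concatenate([a, b])})
        group = pd.Series(["a"] * 200 + ["b"] * 200)
        p, _ = baseline_comparison(df, "v", group)
        assert p < 0.001

    def test_4v4_exact_mannwhitney_matches_enumeration(self):
        a = np.array([1.2, 3.4, 5.6, 7.8])
        b = np.array([2.1, 4.3, 9.9, 11.1])
        df = pd.DataFrame({"v": np.concatenate([a, b])})
        group = pd.Series(["a"] * 4 + ["b"] * 4)
        p, method = baseline_comparison(df, "v", group, force_method="mann-whitney")
        assert method == "mann-whitney"
        assert p == pytest.approx(mannwhitney_two_sided_oracle(a, b), abs=1e-12)

    def test_small_group_rejected(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        group = pd.Series(["a", "a", "b"])
        with pytest.raises(ValueError, match="n >= 2"):
            baseline_comparison(df, "v", group)
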