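"""Cohort cleaning, KM estimation, log-rank / O-E hazard ratio, subgroups."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from lncnet import simulate, survival
from lncnet.survival import (
    analyze_cohort,
    clean_cohort,
    km_curve,
    logrank,
    split_by_expression,
    subgroup_analysis,
)


def cohort_of(times, events, expression, **covs):
    return pd.DataFrame(
        {"sample": [f"p{i}" for i in range(len(times))],
         "time": times, "event": events, "expression": expression, **covs}
    )


class TestCleanCohort:
    def test_both_rules_drop_and_report(self):
        cohort = cohort_of(
            times=[100, 20, 200, 300, 400],
            events=[1, 1, 0, 1, 0],
            expression=[1.0, 2.0, 0.0, 3.0, 4.0],
        )
        kept, report = clean_cohort(cohort)
        assert len(kept) == 3
        assert report == {"zero_expression": 1, "short_followup": 1, "retained": 3}

    def test_clean_is_identity_without_offenders(self, null_cohort):
        kept, report = clean_cohort(null_cohort)
        assert len(kept) == len(null_cohort)
        assert report["zero_expression"] == report["short_followup"] == 0

    def test_record_failing_both_rules_counted_twice_dropped_once(self):
        cohort = cohort_of([20, 100], [1, 1], [0.0, 1.0])
        kept, report = clean_cohort(cohort)
        assert len(kept) == 1
        assert report["zero_expression"] == 1 and report["short_followup"] == 1


class TestSplit:
    def test_even_median_split(self):
        cohort = cohort_of([100] * 10, [1] * 10, list(range(1, 11)))
        labels = split_by_expression(cohort)
        assert (labels == "high").sum() == 5 and (labels == "low").sum() == 5

    def test_odd_n_median_record_goes_low(self):
        cohort = cohort_of([100] * 5, [1] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])
        labels = split_by_expression(cohort)
        assert labels[cohort["expression"] == 3.0].item() == "low"
        assert (labels == "high").sum() == 2

    def test_constant_expression_rejected(self):
        cohort = cohort_of([100] * 4, [1] * 4, [2.0] * 4)
        with pytest.raises(ValueError, match="split"):
            split_by_expression(cohort)


class TestKaplanMeier:
    def test_hand_computed_steps(self):
        curve = km_curve([1, 2, 3], [1, 1, 0])
        assert curve["survival"].tolist() == pytest.approx([1.0, 2 / 3, 1 / 3])
        assert curve["time"].tolist() == [0.0, 1.0, 2.0]  # no step at censored t=3

    def test_all_censored_survival_stays_one(self):
        curve = km_curve([5, 8, 2], [0, 0, 0])
        assert curve["survival"].tolist() == [1.0]

    def test_single_event_drops_by_one_over_n(self):
        curve = km_curve([1, 2, 3, 4], [0, 1, 0, 0])
        assert curve["survival"].iloc[-1] == pytest.approx(1 - 1 / 3)

    def test_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10.0, 60)
        curve = km_curve(times, np.ones(60, dtype=int))
        for _, row in curve.iloc[1:].iterrows():
            ecdf = (times <= row["time"]).mean()
            assert row["survival"] == pytest.approx(1 - ecdf, abs=1e-12)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(10.0, 80)
        events = rng.binomial(1, 0.6, 80)
        curve = km_curve(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for _, row in curve.iterrows():
            assert row["survival"] == pytest.approx(
                float(kmf.survival_function_at_times(row["time"]).iloc[0]), abs=1e-9
            )


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        res = logrank(t, e, t, e)
        assert res.chi2 == pytest.approx(0.0)
        assert res.hr == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # O/E and hypergeometric variance summed over event times 1..4
        res = logrank([1, 2], [1, 1], [3, 4], [1, 1])
        assert res.chi2 == pytest.approx(2.8824, abs=1e-3)
        assert res.hr == pytest.approx(3.8, abs=1e-3)

    def test_no_events_convention(self):
        res = logrank([1, 2], [0, 0], [3, 4], [0, 0])
        assert res.p == 1.0 and np.isnan(res.hr)

    def test_group_exchange_inverts_hr_keeps_chi2(self):
        rng = np.random.default_rng(12)
        ta, tb = rng.exponential(1, 40), rng.exponential(2, 40)
        ea, eb = np.ones(40, int), np.ones(40, int)
        fwd = logrank(ta, ea, tb, eb)
        rev = logrank(tb, eb, ta, ea)
        assert fwd.chi2 == pytest.approx(rev.chi2, rel=1e-9)
        assert fwd.hr == pytest.approx(1 / rev.hr, rel=1e-9)

    def test_chi2_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(3)
        ta = rng.integers(1, 15, 50).astype(float)  # heavy ties
        tb = rng.integers(1, 15, 50).astype(float)
        ea = rng.binomial(1, 0.7, 50)
        eb = rng.binomial(1, 0.7, 50)
        ours = logrank(ta, ea, tb, eb)
        ref = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert ours.chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
        assert ours.p == pytest.approx(ref.p_value, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([], [], [1.0], [1])


class TestCohortAnalysis:
    def test_high_hazard_detected(self):
        cohort = simulate.generate_survival(
            simulate.SurvivalSimConfig(n_patients=400, true_hr=3.0, seed=14)
        )
        res = analyze_cohort(cohort)
        assert res.p < 0.001
        assert res.hr > 1.5  # direction: high expression is the risk group

    def test_cleaning_feeds_analysis(self):
        cohort = simulate.generate_survival(
            simulate.SurvivalSimConfig(
                n_patients=200, frac_zero_expression=0.1, frac_short_followup=0.05,
                seed=15,
            )
        )
        res = analyze_cohort(cohort)
        assert res.dropped["zero_expression"] == 20
        assert res.n_high + res.n_low == res.dropped["retained"]


class TestSubgroups:
    def test_filter_matching_nobody_refused(self, null_cohort):
        null_cohort["er"] = 0
        with pytest.raises(ValueError, match="analyzable"):
            subgroup_analysis(null_cohort, {"er": 1})

    def test_unknown_covariate_refused(self, null_cohort):
        with pytest.raises(ValueError, match="covariate"):
            subgroup_analysis(null_cohort, {"brca": 1})

    def test_filter_matching_everyone_equals_unstratified(self, null_cohort):
        null_cohort["er"] = 1
        full = analyze_cohort(null_cohort)
        sub = subgroup_analysis(null_cohort, {"er": 1})
        assert sub.chi2 == pytest.approx(full.chi2)
        assert (sub.n_high, sub.n_low) == (full.n_high, full.n_low)

    def test_planted_subgroup_effect_detected_only_in_subgroup(self):
        cfg = simulate.SurvivalSimConfig(
            n_patients=800,
            true_hr=1.0,
            subgroup_hr=(("er", 3.0),),
            baseline_hazard=1 / 300.0,
            censor_rate=0.1,
            seed=16,
        )
        cohort = simulate.generate_survival(cfg)
        er_pos = subgroup_analysis(cohort, {"er": 1})
        er_neg = subgroup_analysis(cohort, {"er": 0})
        assert er_pos.p < 0.01 and er_pos.hr > 1.8
        assert 1 / 1.5 < er_neg.hr < 1.5  # complement stays near the null
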