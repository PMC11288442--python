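"""Threshold classification, TAS and cohort summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from equiasym import (
    Thresholds, classify_horse, compute_tas, compute_tas_lunge,
    concordance_summary, flag_double_threshold, population_summary,
    quartile_summary, summarize_trial, assess_horses,
)
from conftest import make_summary

finite_mm = st.floats(min_value=-40, max_value=40, allow_nan=False)
sd_mm = st.floats(min_value=0, max_value=40, allow_nan=False)


class TestSummarize:
    def test_single_stride_summary_has_zero_sd(self):
        df = pd.DataFrame(
            {"duration_s": [0.7], "hd_min_mm": [4.0], "hd_max_mm": [-2.0],
             "pd_min_mm": [1.0], "pd_max_mm": [0.5], "flagged": [False]}
        )
        s = summarize_trial(df, "H1", "straight_hard")
        assert s.mean_hd_min == 4.0 and s.sd_hd_min == 0.0
        assert s.n_strides == 1

    def test_plus_minus_five_gives_sample_sd(self):
        df = pd.DataFrame(
            {"duration_s": [0.7, 0.7], "hd_min_mm": [5.0, -5.0],
             "hd_max_mm": [0.0, 0.0], "pd_min_mm": [0.0, 0.0],
             "pd_max_mm": [0.0, 0.0]}
        )
        s = summarize_trial(df)
        assert s.mean_hd_min == 0.0
        assert s.sd_hd_min == pytest.approx(7.0710678, abs=1e-6)

    def test_random_table_matches_numpy_oracle(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "duration_s": rng.uniform(0.6, 0.8, 50),
                "hd_min_mm": rng.normal(3, 2, 50),
                "hd_max_mm": rng.normal(-1, 1, 50),
                "pd_min_mm": rng.normal(0, 1, 50),
                "pd_max_mm": rng.normal(2, 3, 50),
            }
        )
        s = summarize_trial(df)
        assert s.mean_pd_max == pytest.approx(df["pd_max_mm"].mean())
        assert s.sd_hd_min == pytest.approx(df["hd_min_mm"].std(ddof=1))

    def test_flagged_strides_are_excluded(self):
        df = pd.DataFrame(
            {"duration_s": [0.7] * 3, "hd_min_mm": [1.0, 1.0, 99.0],
             "hd_max_mm": [0.0] * 3, "pd_min_mm": [0.0] * 3,
             "pd_max_mm": [0.0] * 3, "flagged": [False, False, True]}
        )
        assert summarize_trial(df).mean_hd_min == 1.0

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            summarize_trial(pd.DataFrame(columns=["hd_min_mm"]))


class TestClassification:
    def test_above_threshold_with_low_sd_is_asymmetric(self):
        s = make_summary(mean_hd_min=7.0, sd_hd_min=3.0)
        c = classify_horse(s)
        assert c.status == "asymmetric" and c.triggered == ["hd_min"]

    def test_high_sd_classifies_symmetric_with_flag(self):
        s = make_summary(mean_pd_min=4.0, sd_pd_min=5.0)
        c = classify_horse(s)
        assert c.status == "symmetric"
        assert c.high_variability and c.high_variability_params == ["pd_min"]

    @pytest.mark.parametrize(
        "param,mean,sd,expected",
        [
            ("hd_min", 6.0, 1.0, "symmetric"),   # strictly greater than 6 required
            ("hd_min", 6.01, 1.0, "asymmetric"),
            ("pd_max", 3.0, 0.1, "symmetric"),
            ("pd_max", -3.01, 0.1, "asymmetric"),  # absolute value, either side
            ("pd_min", 4.0, 4.0, "symmetric"),   # SD must be strictly below |mean|
        ],
    )
    def test_strict_threshold_boundaries(self, param, mean, sd, expected):
        s = make_summary(**{f"mean_{param}": mean, f"sd_{param}": sd})
        assert classify_horse(s).status == expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(mean=finite_mm, sd=sd_mm, bump=st.floats(min_value=0, max_value=20))
    def test_monotone_in_mean_and_sd(self, mean, sd, bump):
        base = classify_horse(make_summary(mean_pd_min=mean, sd_pd_min=sd)).status
        larger_mean = classify_horse(
            make_summary(mean_pd_min=math.copysign(abs(mean) + bump, mean or 1.0),
                         sd_pd_min=sd)
        ).status
        larger_sd = classify_horse(
            make_summary(mean_pd_min=mean, sd_pd_min=sd + bump)
        ).status
        if base == "asymmetric":
            assert larger_mean == "asymmetric" or abs(mean) + bump <= sd
        if base == "symmetric" and abs(mean) <= 3.0:
            assert larger_sd == "symmetric"

    @pytest.mark.parametrize(
        "param,mean,sd,expected",
        [
            ("hd_min", 12.5, 4.0, True),
            ("hd_min", 12.0, 1.0, False),  # strictly greater than double
            ("pd_max", 6.1, 2.0, True),
            ("hd_max", -13.0, 2.0, True),
        ],
    )
    def test_double_threshold_boundaries(self, param, mean, sd, expected):
        s = make_summary(**{f"mean_{param}": mean, f"sd_{param}": sd})
        assert flag_double_threshold(s) is expected

    def test_double_threshold_inherits_sd_condition(self):
        s = make_summary(mean_hd_min=13.0, sd_hd_min=14.0)
        assert flag_double_threshold(s) is False
        assert flag_double_threshold(s, require_sd_condition=False) is True

    def test_invalid_thresholds_raise(self):
        with pytest.raises(ValueError):
            Thresholds(head_mm=0.0)


class TestTAS:
    def test_zero_means_give_zero(self):
        assert compute_tas(make_summary()) == 0.0

    def test_halved_head_terms_arithmetic(self):
        s = make_summary(mean_hd_min=-12.0, mean_hd_max=6.0,
                         mean_pd_min=4.0, mean_pd_max=2.0)
        assert compute_tas(s) == pytest.approx(15.0)

    def test_all_parameters_at_threshold_give_twelve(self):
        # 6/2 + 6/2 + 3 + 3: equal 3 mm contributions per parameter
        s = make_summary(mean_hd_min=6.0, mean_hd_max=-6.0,
                         mean_pd_min=3.0, mean_pd_max=-3.0)
        assert compute_tas(s) == pytest.approx(12.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=finite_mm, b=finite_mm, c=finite_mm, d=finite_mm)
    def test_sign_invariance_and_zero_iff_all_zero(self, a, b, c, d):
        s = make_summary(mean_hd_min=a, mean_hd_max=b, mean_pd_min=c, mean_pd_max=d)
        f = make_summary(mean_hd_min=-a, mean_hd_max=-b, mean_pd_min=-c, mean_pd_max=-d)
        assert compute_tas(s) == compute_tas(f)
        assert (compute_tas(s) == 0.0) == (a == b == c == d == 0.0)

    def test_lunge_signed_cancellation(self):
        left = make_summary(condition="lunge_left", mean_hd_min=5.0)
        right = make_summary(condition="lunge_right", mean_hd_min=-5.0)
        assert compute_tas_lunge(left, right) == 0.0

    def test_lunge_sum_then_formula(self):
        left = make_summary(condition="lunge_left")
        right = make_summary(condition="lunge_right", mean_hd_min=-12.0,
                             mean_hd_max=6.0, mean_pd_min=4.0, mean_pd_max=2.0)
        assert compute_tas_lunge(left, right) == pytest.approx(15.0)

    def test_missing_direction_propagates_nan(self):
        assert math.isnan(compute_tas_lunge(make_summary(), None))

    def test_random_summaries_match_bruteforce(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            vals_l = rng.normal(0, 8, 4)
            vals_r = rng.normal(0, 8, 4)
            left = make_summary(mean_hd_min=vals_l[0], mean_hd_max=vals_l[1],
                                mean_pd_min=vals_l[2], mean_pd_max=vals_l[3])
            right = make_summary(mean_hd_min=vals_r[0], mean_hd_max=vals_r[1],
                                 mean_pd_min=vals_r[2], mean_pd_max=vals_r[3])
            sums = vals_l + vals_r
            expected = abs(sums[0]) / 2 + abs(sums[1]) / 2 + abs(sums[2]) + abs(sums[3])
            assert compute_tas_lunge(left, right) == pytest.approx(expected)


def make_assessments(hard_flags, soft_flags=None, disciplines=None):
    n = len(hard_flags)
    soft_flags = soft_flags if soft_flags is not None else hard_flags
    df = pd.DataFrame(
        {
            "horse_id": [f"H{i}" for i in range(n)],
            "class_hard": ["asymmetric" if f else "symmetric" for f in hard_flags],
            "class_soft": ["asymmetric" if f else "symmetric" for f in soft_flags],
            "double_hard": [bool(f) for f in hard_flags],
            "double_soft": [bool(f) for f in soft_flags],
            "high_var_hard": False,
            "high_var_soft": False,
        }
    )
    if disciplines is not None:
        df["discipline"] = disciplines
    return df


class TestCohortSummaries:
    def test_prevalence_of_79_in_114(self):
        flags = [True] * 79 + [False] * 35
        s = population_summary(make_assessments(flags), "hard")
        assert s["n"] == 114 and s["n_asymmetric"] == 79
        assert s["prevalence_pct"] == round(100 * 79 / 114, 1)

    def test_zero_asymmetric_gives_zero_percent(self):
        s = population_summary(make_assessments([False] * 20), "hard")
        assert s["prevalence_pct"] == 0.0

    def test_counts_match_direct_counting_oracle(self):
        rng = np.random.default_rng(77)
        flags = rng.random(200) < 0.6
        disc = rng.choice(["dressage", "show_jumping", "eventing"], 200)
        s = population_summary(make_assessments(flags, disciplines=list(disc)), "hard")
        assert s["n_asymmetric"] == int(flags.sum())
        for d in set(disc):
            sel = disc == d
            assert s["by_discipline"][d]["n_asymmetric"] == int(flags[sel].sum())

    def test_concordance_partitions_cohort(self):
        rng = np.random.default_rng(13)
        hard = rng.random(150) < 0.6
        soft = rng.random(150) < 0.6
        c = concordance_summary(make_assessments(hard, soft))
        assert c["n_both_asymmetric"] == int((hard & soft).sum())
        assert c["n_both_symmetric"] == int((~hard & ~soft).sum())
        assert (c["n_both_asymmetric"] + c["n_both_symmetric"]
                + c["n_discordant"]) == 150

    def test_identical_surfaces_have_no_discordance(self):
        flags = [True, False] * 10
        assert concordance_summary(make_assessments(flags, flags))["n_discordant"] == 0

    def test_missing_trials_shrink_denominators(self, small_population):
        assess = assess_horses(small_population.trials,
                               horses=small_population.horses)
        s = population_summary(assess, "hard")
        assert s["n"] < len(assess)  # some horses lack the hard-surface trial
        c = concordance_summary(assess)
        assert c["n"] <= s["n"]


class TestQuartiles:
    def test_four_equal_values(self):
        q = quartile_summary([5.0, 5.0, 5.0, 5.0])
        assert q["mean_top"] == 5.0 and q["n_top"] == 1

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(6, 30, 39)
        q = quartile_summary(x)
        srt = np.sort(x)
        expected_top = srt[srt > np.percentile(x, 75)]
        assert q["n_top"] == expected_top.size
        assert q["mean_top"] == pytest.approx(expected_top.mean())
        assert q["range_top"] == (pytest.approx(expected_top.min()),
                                  pytest.approx(expected_top.max()))

    def test_ceil_convention(self):
        x = np.arange(1.0, 40.0)  # 39 values
        q = quartile_summary(x, convention="ceil_n4")
        assert q["n_top"] == 10

    def test_too_few_values_skip_quartiles(self):
        q = quartile_summary([1.0, 2.0, 3.0])
        assert "n_top" not in q and q["n"] == 3

    def test_unknown_convention_raises(self):
        with pytest.raises(ValueError):
            quartile_summary([1, 2, 3, 4], convention="bogus")
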