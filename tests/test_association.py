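"""Questionnaire handling and the sidedness mixed-effects models."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from equiasym import (
    PopulationConfig, assess_horses, binarize, build_association_table,
    fit_association, generate_population, pairwise_contrasts, reduce_questions,
)
from equiasym.association import ResponseCodeError


def questionnaire_frame(n=100, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "qa": rng.choice(["no", "left", "right", "na"], n, p=[0.6, 0.2, 0.15, 0.05]),
            "qb": rng.choice(["no", "left", "right", "na"], n, p=[0.3, 0.3, 0.3, 0.1]),
            "qc": rng.choice(["no", "left", "right", "na"], n, p=[0.49, 0.25, 0.26, 0.0]),
        }
    )


class TestQuestionReduction:
    def test_majority_no_question_is_excluded(self):
        df = questionnaire_frame(200, seed=1)  # qa is ~60% "no"
        selected, log = reduce_questions(df, [["qa"], ["qc"]])
        assert "qa" not in selected and "qc" in selected
        assert not log.loc[log["selected"] == "qa", "kept"].item()

    def test_fewest_na_wins_within_group(self):
        df = pd.DataFrame(
            {"q_first": ["na"] * 5 + ["left"] * 15,
             "q_second": ["na"] * 2 + ["right"] * 18}
        )
        selected, _ = reduce_questions(df, [["q_first", "q_second"]])
        assert selected == ["q_second"]

    def test_na_tie_breaks_to_declared_order_and_is_logged(self):
        df = pd.DataFrame(
            {"q_x": ["left"] * 10, "q_y": ["right"] * 10}
        )
        selected, log = reduce_questions(df, [["q_x", "q_y"]])
        assert selected == ["q_x"]
        assert log["tie_broken_by_order"].item()

    def test_singleton_group_with_49_percent_no_is_kept(self):
        df = questionnaire_frame(300, seed=4)
        selected, _ = reduce_questions(df, [["qc"]])
        assert selected == ["qc"]


class TestBinarize:
    def test_directional_answers(self):
        s = pd.Series(["left", "right", "no", "na"])
        out = binarize(s, "q4_drift")
        assert list(out[:3]) == ["yes", "yes", "no"]
        assert out.isna().iloc[3]

    def test_graded_sidedness_merges_severe(self):
        s = pd.Series(["no", "mild", "moderate", "severe", "na"])
        out = binarize(s, "q1_sidedness")
        assert list(out[:4]) == ["no", "mild", "moderate", "moderate"]
        assert out.isna().iloc[4]
        assert list(out.cat.categories) == ["no", "mild", "moderate"]

    def test_unknown_code_raises(self):
        with pytest.raises(ResponseCodeError):
            binarize(pd.Series(["sometimes"]), "q3_rein")


def association_table(seed=0, effect=0.0, n_horses=71, n_riders=51):
    pop = generate_population(
        PopulationConfig(n_horses=n_horses, n_riders=n_riders,
                         sidedness_association_effect=effect, seed=seed)
    )
    assess = assess_horses(pop.trials, horses=pop.horses)
    table = build_association_table(assess, pop.trials, pop.questionnaire)
    return table.rename(columns={"stride_duration_lunge": "stride_duration"}), pop


class TestFitAssociation:
    def test_one_horse_per_rider_equals_ols(self):
        table, _ = association_table(seed=3, n_horses=40, n_riders=40)
        r = fit_association(table, "q1_sidedness", "tas_lunge",
                            skew_threshold=np.inf)
        assert r.ols_fallback
        df = table[["q1_sidedness", "tas_lunge", "rider_id", "stride_duration"]].dropna()
        fac = df["q1_sidedness"]
        levels = [l for l in fac.cat.categories if (fac == l).any()]
        X = np.column_stack(
            [np.ones(len(df))]
            + [(fac == l).to_numpy(float) for l in levels[1:]]
            + [df["stride_duration"].to_numpy()]
        )
        ols = sm.OLS(df["tas_lunge"].to_numpy(), X).fit()
        assert np.allclose(r.coef_table["estimate"].to_numpy(), ols.params, atol=1e-10)

    def test_flipping_all_parameter_signs_changes_nothing(self):
        table, pop = association_table(seed=9)
        flipped_trials = pop.trials.copy()
        for p in ("hd_min", "hd_max", "pd_min", "pd_max"):
            flipped_trials[f"mean_{p}"] *= -1.0
        assess = assess_horses(flipped_trials, horses=pop.horses)
        flipped = build_association_table(
            assess, flipped_trials, pop.questionnaire
        ).rename(columns={"stride_duration_lunge": "stride_duration"})
        a = fit_association(table, "q1_sidedness", "tas_lunge")
        b = fit_association(flipped, "q1_sidedness", "tas_lunge")
        assert a.anova_pvalues["factor"] == pytest.approx(
            b.anova_pvalues["factor"], abs=1e-8
        )
        assert a.emmeans == pytest.approx(b.emmeans, abs=1e-8)

    def test_constant_response_is_degenerate(self):
        table, _ = association_table(seed=5)
        table = table.assign(tas_lunge=3.0)
        r = fit_association(table, "q1_sidedness", "tas_lunge")
        assert r.degenerate
        assert not (r.anova_pvalues["factor"] < 0.05)

    def test_boxcox_triggers_on_skewed_response(self):
        table, _ = association_table(seed=6)
        rng = np.random.default_rng(1)
        table = table.assign(tas_lunge=rng.lognormal(0.0, 1.4, len(table)) ** 2)
        r = fit_association(table, "q1_sidedness", "tas_lunge")
        assert r.transformation == "box-cox"
        assert r.boxcox_lambda is not None and -2.0 <= r.boxcox_lambda <= 2.0

    def test_three_groups_give_three_contrasts(self):
        table, _ = association_table(seed=10, n_horses=150, n_riders=60)
        r = fit_association(table, "q1_sidedness", "tas_lunge")
        assert len(r.levels) == 3
        assert len(r.contrasts) == 3
        # contrast estimates agree with marginal-mean differences
        for row in r.contrasts.itertuples():
            assert row.estimate == pytest.approx(
                r.emmeans[row.group_1] - r.emmeans[row.group_2], abs=1e-9
            )

    def test_identical_groups_have_small_contrast(self):
        # binary factor assigned independently of the response
        rng = np.random.default_rng(15)
        n = 400
        df = pd.DataFrame(
            {
                "g": pd.Categorical(rng.choice(["no", "yes"], n)),
                "y": rng.gamma(4.0, 2.0, n),
                "rider_id": rng.integers(0, 100, n),
                "stride_duration": rng.normal(0.7, 0.03, n),
            }
        )
        r = fit_association(df, "g", "y", skew_threshold=np.inf)
        row = r.contrasts.iloc[0]
        assert abs(row["estimate"]) < 3.0 * row["se"]

    def test_large_injected_shift_is_detected(self):
        table, _ = association_table(seed=20, effect=8.0)
        r = fit_association(table, "q1_sidedness", "tas_lunge")
        assert r.anova_pvalues["factor"] < 0.05

    def test_tukey_adjustment_is_conservative(self):
        table, _ = association_table(seed=30, n_horses=150, n_riders=60)
        tukey = fit_association(table, "q1_sidedness", "tas_lunge", adjust="tukey")
        raw = pairwise_contrasts(tukey, adjust="none")
        merged = tukey.contrasts.merge(raw, on=["group_1", "group_2"])
        assert (merged["p_value_x"] >= merged["p_value_y"] - 1e-12).all()


class TestAgainstLme4:
    def test_fixed_effects_match_lme4(self, tmp_path):
        """Independent cross-check of the mixed fit against R's lme4."""
        table, _ = association_table(seed=40, n_horses=150, n_riders=60)
        r = fit_association(table, "q1_sidedness", "tas_lunge",
                            skew_threshold=np.inf)
        assert not r.ols_fallback
        df = table[["q1_sidedness", "tas_lunge", "rider_id",
                    "stride_duration"]].dropna()
        csv = tmp_path / "assoc.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$q1_sidedness <- factor(d$q1_sidedness, levels=c("no","mild","moderate"))
            m <- lmer(tas_lunge ~ q1_sidedness + stride_duration + (1|rider_id),
                      data=d, REML=TRUE)
            cat(fixef(m), sep="\\n")
            """
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert proc.returncode == 0, proc.stderr
        lme4_fe = np.array([float(x) for x in proc.stdout.split()])
        ours = r.coef_table["estimate"].to_numpy()
        assert np.allclose(ours, lme4_fe, rtol=1e-3, atol=1e-3), (ours, lme4_fe)
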