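"""Rider-sidedness association models.

Questionnaire answers about perceived horse sidedness are reduced (one
representative question per overlap group, questions with a majority of
"no" answers dropped), binarized ("left"/"right" become "yes"; the graded
sidedness question keeps ordered levels no < mild < moderate, with the rare
"severe" answers merged into "moderate"), and tested against the absolute
movement-asymmetry magnitudes with linear mixed models:

    |asymmetry| ~ sidedness + mean stride duration + (1 | rider)

Stride duration proxies speed; the rider is a random intercept because one
rider may answer for several horses.  Model residuals that are clearly
skewed trigger a Box-Cox re-fit.  Reported per model: a type-III-style
joint F test per fixed term, estimated marginal means per sidedness group,
and all pairwise group contrasts (Tukey-adjusted by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import studentized_range
import statsmodels.api as sm

#: Response variables mapped to each questionnaire question: the graded
#: sidedness question is tested against the total asymmetry scores, the
#: weak-hind-limb question against the pelvic parameters, the rein question
#: against the head parameters, and the drift / rider-side questions
#: against all four parameters (straight-line absolute values).
QUESTION_RESPONSES = {
    "q1_sidedness": ["tas_straight", "tas_lunge"],
    "q2_weak_hind": ["abs_pd_min", "abs_pd_max"],
    "q3_rein": ["abs_hd_min", "abs_hd_max"],
    "q4_drift": ["abs_hd_min", "abs_hd_max", "abs_pd_min", "abs_pd_max"],
    "q5_rider_side": ["abs_hd_min", "abs_hd_max", "abs_pd_min", "abs_pd_max"],
}

_DIRECTIONAL = {"no", "left", "right", "na"}
_GRADED = {"no", "mild", "moderate", "severe", "na"}


class ResponseCodeError(ValueError):
    """Unknown questionnaire answer code."""


def reduce_questions(
    responses: pd.DataFrame,
    groups: list[list[str]],
    no_fraction_cutoff: float = 0.5,
) -> tuple[list[str], pd.DataFrame]:
    """Select one representative question per declared overlap group.

    Within each group the question with the fewest "na" answers wins (ties
    break to the first in declared order, logged).  Selected questions in
    which more than ``no_fraction_cutoff`` of responders answered "no"
    (no sidedness perceived) are then excluded.

    Returns the selected column names and a log table of the decisions.
    """
    if not groups:
        raise ValueError("need at least one question group")
    selected, log = [], []
    for group in groups:
        na_counts = {q: int((responses[q] == "na").sum()) for q in group}
        winner = min(group, key=lambda q: (na_counts[q], group.index(q)))
        tie = sum(1 for q in group if na_counts[q] == na_counts[winner]) > 1
        n = len(responses)
        no_frac = float((responses[winner] == "no").sum()) / n if n else 0.0
        keep = no_frac <= no_fraction_cutoff
        if keep:
            selected.append(winner)
        log.append(
            {
                "group": "+".join(group),
                "selected": winner,
                "na_count": na_counts[winner],
                "tie_broken_by_order": tie,
                "no_fraction": round(no_frac, 3),
                "kept": keep,
            }
        )
    return selected, pd.DataFrame(log)


def binarize(values: pd.Series, question: str = "") -> pd.Series:
    """Convert questionnaire answers to analysis levels.

    Directional questions: "left"/"right" -> "yes", "no" -> "no",
    "na" -> missing.  The graded sidedness question (name containing
    "sidedness") keeps its grades with "severe" merged into "moderate",
    giving ordered levels no < mild < moderate.
    """
    graded = "sidedness" in question
    valid = _GRADED if graded else _DIRECTIONAL
    bad = set(values.dropna().unique()) - valid
    if bad:
        raise ResponseCodeError(f"unknown answer code(s) {sorted(bad)} for {question or 'question'}")
    if graded:
        out = values.replace({"severe": "moderate", "na": None})
        cats = ["no", "mild", "moderate"]
    else:
        out = values.replace({"left": "yes", "right": "yes", "na": None})
        cats = ["no", "yes"]
    return pd.Series(
        pd.Categorical(out, categories=cats, ordered=graded),
        index=values.index, name=values.name,
    )


@dataclass
class AssociationResult:
    """Fitted sidedness-association model for one question/response pair."""

    question: str
    response: str
    transformation: str = "none"  # "none" or "box-cox"
    boxcox_lambda: float | None = None
    coef_table: pd.DataFrame | None = None
    anova_pvalues: dict = field(default_factory=dict)  # factor + stride duration
    contrasts: pd.DataFrame | None = None
    emmeans: dict = field(default_factory=dict)
    n_obs: int = 0
    n_riders: int = 0
    degenerate: bool = False
    ols_fallback: bool = False
    converged: bool = True
    # internals for contrast computation
    levels: list = field(default_factory=list)
    _beta: np.ndarray | None = None
    _cov: np.ndarray | None = None
    _df_resid: int = 0


def _boxcox_grid(y: np.ndarray, grid=None) -> tuple[np.ndarray, float]:
    """Box-Cox transform with lambda chosen by ML over a fixed grid."""
    if grid is None:
        grid = np.linspace(-2.0, 2.0, 81)
    llf = [stats.boxcox_llf(lam, y) for lam in grid]
    lam = float(grid[int(np.argmax(llf))])
    return stats.boxcox(y, lmbda=lam), lam


def fit_association(
    data: pd.DataFrame,
    question: str,
    response: str,
    rider_col: str = "rider_id",
    duration_col: str = "stride_duration",
    skew_threshold: float = 1.0,
    boxcox_offset: float = 0.01,
    adjust: str = "tukey",
) -> AssociationResult:
    """Fit |asymmetry| ~ sidedness + stride duration + (1 | rider).

    ``data`` holds one row per horse with the binarized/graded factor in
    column ``question``, the absolute response in column ``response``, the
    rider identifier and the stride-duration covariate.  Rows with missing
    values are dropped listwise.

    If the absolute skewness of the residuals exceeds ``skew_threshold``
    the response is Box-Cox transformed (after adding ``boxcox_offset`` mm,
    since absolute asymmetries can be zero) and the model re-fitted.

    When every rider has a single horse, or the random-intercept fit fails
    or is singular, the model falls back to ordinary least squares and the
    result is flagged.
    """
    cols = [question, response, rider_col, duration_col]
    df = data[cols].dropna()
    result = AssociationResult(question=question, response=response)
    result.n_obs = len(df)
    result.n_riders = df[rider_col].nunique()

    fac = df[question]
    levels = (
        [l for l in fac.cat.categories if (fac == l).any()]
        if isinstance(fac.dtype, pd.CategoricalDtype)
        else sorted(fac.unique())
    )
    result.levels = levels
    y = df[response].to_numpy(dtype=float)
    if len(levels) < 2 or result.n_riders < 2 or np.ptp(y) == 0.0:
        result.degenerate = True
        result.anova_pvalues = {"factor": np.nan, "duration": np.nan}
        return result

    dur = df[duration_col].to_numpy(dtype=float)
    dummies = np.column_stack([(fac == l).to_numpy(float) for l in levels[1:]])
    X = np.column_stack([np.ones(len(df)), dummies, dur])
    names = ["intercept"] + [f"{question}[{l}]" for l in levels[1:]] + [duration_col]
    groups = df[rider_col].to_numpy()

    def _fit(yv):
        one_per_group = pd.Series(groups).value_counts().max() == 1
        if not one_per_group:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = sm.MixedLM(yv, X, groups=groups)
                    # Powell is the most robust optimizer here when the
                    # rider variance sits near the boundary
                    r = m.fit(reml=True, method="powell", maxiter=200)
                k = X.shape[1]
                cov = np.asarray(r.cov_params())[:k, :k]
                if (r.converged and np.all(np.isfinite(r.fe_params))
                        and np.all(np.isfinite(cov))
                        and np.all(np.diag(cov) > 0)):
                    return np.asarray(r.fe_params), cov, False
            except (np.linalg.LinAlgError, ValueError):
                pass
        r = sm.OLS(yv, X).fit()
        return np.asarray(r.params), np.asarray(r.cov_params()), True

    beta, cov, used_ols = _fit(y)
    resid = y - X @ beta
    if abs(stats.skew(resid)) > skew_threshold and np.all(y + boxcox_offset > 0):
        yt, lam = _boxcox_grid(y + boxcox_offset)
        result.transformation = "box-cox"
        result.boxcox_lambda = lam
        beta, cov, used_ols = _fit(yt)
        y = yt
    result.ols_fallback = used_ols

    n, p = X.shape
    df_resid = n - p
    result._beta, result._cov, result._df_resid = beta, cov, df_resid
    result.coef_table = pd.DataFrame(
        {"term": names, "estimate": beta, "se": np.sqrt(np.diag(cov))}
    )

    def wald_f(idx):
        idx = np.asarray(idx)
        b = beta[idx]
        V = cov[np.ix_(idx, idx)]
        q = len(idx)
        try:
            F = float(b @ np.linalg.solve(V, b)) / q
        except np.linalg.LinAlgError:
            return np.nan
        return float(stats.f.sf(F, q, df_resid))

    k_fac = len(levels) - 1
    result.anova_pvalues = {
        "factor": wald_f(range(1, 1 + k_fac)),
        "duration": wald_f([1 + k_fac]),
    }

    mean_dur = float(np.mean(dur))
    emm = {levels[0]: beta[0] + beta[1 + k_fac] * mean_dur}
    for i, l in enumerate(levels[1:]):
        emm[l] = emm[levels[0]] + beta[1 + i]
    result.emmeans = emm
    result.contrasts = pairwise_contrasts(result, adjust=adjust)
    return result


def pairwise_contrasts(result: AssociationResult, adjust: str = "tukey") -> pd.DataFrame:
    """All pairwise comparisons of the factor-level marginal means.

    Estimates, standard errors and t tests on the residual degrees of
    freedom; ``adjust`` is ``"tukey"`` (studentized-range adjustment,
    default) or ``"none"``.  A single-level model yields an empty table.
    """
    levels = result.levels
    if result._beta is None or len(levels) < 2:
        return pd.DataFrame(
            columns=["group_1", "group_2", "estimate", "se", "t", "p_value"]
        )
    beta, cov, dfr = result._beta, result._cov, result._df_resid
    k = len(levels)

    def coef_vec(level):
        v = np.zeros(beta.size)
        i = levels.index(level)
        if i > 0:
            v[i] = 1.0
        return v

    rows = []
    for a, b in combinations(levels, 2):
        c = coef_vec(a) - coef_vec(b)
        est = float(c @ beta)
        se = float(np.sqrt(max(c @ cov @ c, 0.0)))
        t = est / se if se > 0 else np.nan
        if adjust == "tukey" and k > 2:
            p = float(studentized_range.sf(abs(t) * np.sqrt(2.0), k, dfr))
        else:
            p = float(2.0 * stats.t.sf(abs(t), dfr))
        rows.append(
            {"group_1": a, "group_2": b, "estimate": est, "se": se, "t": t,
             "p_value": min(1.0, p)}
        )
    return pd.DataFrame(rows)


def build_association_table(
    assessments: pd.DataFrame,
    trials: pd.DataFrame,
    questionnaire: pd.DataFrame,
) -> pd.DataFrame:
    """One row per horse with responses, covariates and factor levels.

    Absolute straight-line (hard surface) parameter means become
    ``abs_hd_min`` .. ``abs_pd_max``; TAS columns and the per-model stride
    duration covariates come from the assessment table; questionnaire
    answers are binarized (graded for the sidedness question).
    """
    hard = trials.loc[trials["condition"] == "straight_hard",
                      ["horse_id", "mean_hd_min", "mean_hd_max",
                       "mean_pd_min", "mean_pd_max"]].copy()
    for p in ("hd_min", "hd_max", "pd_min", "pd_max"):
        hard[f"abs_{p}"] = hard[f"mean_{p}"].abs()
    hard = hard[["horse_id"] + [f"abs_{p}" for p in
                                ("hd_min", "hd_max", "pd_min", "pd_max")]]
    out = assessments.merge(hard, on="horse_id", how="left")
    q = questionnaire.copy()
    for col in q.columns:
        if col.startswith("q"):
            q[col] = binarize(q[col], col)
    out = out.merge(q, on="horse_id", how="inner",
                    suffixes=("", "_questionnaire"))
    return out


def run_association_suite(
    table: pd.DataFrame,
    questions: list[str] | None = None,
    adjust: str = "tukey",
) -> list[AssociationResult]:
    """Fit every question/response model on the per-horse table.

    Lunge responses use the mean lunge stride duration as covariate,
    straight-line responses the hard-surface trial's.
    """
    results = []
    for question in questions or list(QUESTION_RESPONSES):
        for response in QUESTION_RESPONSES[question]:
            dur_col = ("stride_duration_lunge" if "lunge" in response
                       else "stride_duration_straight")
            sub = table.rename(columns={dur_col: "stride_duration"})
            results.append(
                fit_association(sub, question, response, adjust=adjust)
            )
    return results


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabular report: one row per fitted model, Table-5 style."""
    return pd.DataFrame(
        [
            {
                "question": r.question,
                "response": r.response,
                "p_value": r.anova_pvalues.get("factor"),
                "stride_duration_p_value": r.anova_pvalues.get("duration"),
                "transformation": r.transformation,
                "boxcox_lambda": r.boxcox_lambda,
                "n_obs": r.n_obs,
                "n_riders": r.n_riders,
                "degenerate": r.degenerate,
                "ols_fallback": r.ols_fallback,
            }
            for r in results
        ]
    )
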