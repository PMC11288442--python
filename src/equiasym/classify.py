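"""Threshold-based asymmetry classification and cohort summaries.

A horse is classified *asymmetric* on a surface when at least one of the
four trial-mean asymmetry parameters exceeds its clinical threshold in
absolute value (strictly >6 mm for the head parameters HDmin/HDmax,
strictly >3 mm for the pelvic parameters PDmin/PDmax) *and* the
stride-level SD of that parameter is below the absolute mean.  Horses with
an above-threshold mean but SD >= |mean| show high inter-stride
variability and classify symmetric (flagged).  A double-threshold flag
marks means beyond twice the thresholds (>12 mm head, >6 mm pelvis),
the magnitude range reported for clinically lame horses.

The Total Asymmetry Score combines the four absolute trial means with the
head terms half-weighted, so the head thresholds (6 mm, double the pelvic
3 mm) contribute equally at threshold:

    TAS = |HDmin|/2 + |HDmax|/2 + |PDmin| + |PDmax|

For lunge trials a combined score sums each parameter (signed) across the
left and right circle first and applies the formula to the sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PARAMS = ("hd_min", "hd_max", "pd_min", "pd_max")
STRIDE_COLS = {p: f"{p}_mm" for p in PARAMS}


@dataclass
class Thresholds:
    """Clinical asymmetry thresholds (mm) and the double-threshold factor."""

    head_mm: float = 6.0
    pelvis_mm: float = 3.0
    double_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.head_mm <= 0 or self.pelvis_mm <= 0 or self.double_factor <= 0:
            raise ValueError("thresholds must be positive")

    def for_param(self, param: str) -> float:
        return self.head_mm if param.startswith("hd") else self.pelvis_mm


@dataclass
class TrialSummary:
    """Per-trial asymmetry parameter means/SDs (mm) and stride statistics."""

    horse_id: str
    condition: str  # straight_hard | straight_soft | lunge_left | lunge_right
    n_strides: int
    mean_hd_min: float
    mean_hd_max: float
    mean_pd_min: float
    mean_pd_max: float
    sd_hd_min: float
    sd_hd_max: float
    sd_pd_min: float
    sd_pd_max: float
    mean_stride_duration: float

    def mean(self, param: str) -> float:
        return getattr(self, f"mean_{param}")

    def sd(self, param: str) -> float:
        return getattr(self, f"sd_{param}")

    @classmethod
    def from_row(cls, row) -> "TrialSummary":
        return cls(
            horse_id=row["horse_id"],
            condition=row["condition"],
            n_strides=int(row["n_strides"]),
            **{f"mean_{p}": float(row[f"mean_{p}"]) for p in PARAMS},
            **{f"sd_{p}": float(row[f"sd_{p}"]) for p in PARAMS},
            mean_stride_duration=float(row["mean_stride_duration"]),
        )


@dataclass
class Classification:
    """Outcome of the threshold rule for one trial."""

    status: str  # "asymmetric" | "symmetric"
    triggered: list = field(default_factory=list)  # params exceeding with SD < |mean|
    high_variability: bool = False  # above threshold but SD >= |mean|
    high_variability_params: list = field(default_factory=list)


def summarize_trial(strides: pd.DataFrame, horse_id: str = "",
                    condition: str = "") -> TrialSummary:
    """Arithmetic mean and sample SD per parameter over a stride table.

    Flagged strides (extrema-count violations) are excluded from the
    statistics.  A single-stride trial has SDs of zero.
    """
    if "flagged" in strides.columns:
        strides = strides.loc[~strides["flagged"].astype(bool)]
    if strides.empty:
        raise ValueError("cannot summarize an empty stride table")
    n = len(strides)
    kw = {}
    for p, col in STRIDE_COLS.items():
        x = strides[col].to_numpy(dtype=float)
        kw[f"mean_{p}"] = float(np.mean(x))
        kw[f"sd_{p}"] = float(np.std(x, ddof=1)) if n > 1 else 0.0
    return TrialSummary(
        horse_id=horse_id,
        condition=condition,
        n_strides=n,
        mean_stride_duration=float(strides["duration_s"].mean()),
        **kw,
    )


def classify_horse(summary: TrialSummary,
                   thresholds: Thresholds | None = None) -> Classification:
    """Apply the threshold + dispersion rule to one trial summary.

    Asymmetric iff any parameter has |mean| strictly above its threshold
    with SD strictly below |mean|; otherwise symmetric.  Parameters above
    threshold that fail the SD condition set the high-variability flag.
    """
    th = thresholds or Thresholds()
    triggered, high_var = [], []
    for p in PARAMS:
        m, sd = abs(summary.mean(p)), summary.sd(p)
        if m > th.for_param(p):
            if sd < m:
                triggered.append(p)
            else:
                high_var.append(p)
    return Classification(
        status="asymmetric" if triggered else "symmetric",
        triggered=triggered,
        high_variability=bool(high_var) and not triggered,
        high_variability_params=high_var,
    )


def flag_double_threshold(summary: TrialSummary,
                          thresholds: Thresholds | None = None,
                          require_sd_condition: bool = True) -> bool:
    """True iff any parameter's |mean| strictly exceeds twice its threshold.

    By default the dispersion condition (SD < |mean|) is inherited from the
    parent classification rule, since the double-threshold proportion is
    reported among horses classified as asymmetric.
    """
    th = thresholds or Thresholds()
    for p in PARAMS:
        m, sd = abs(summary.mean(p)), summary.sd(p)
        if m > th.double_factor * th.for_param(p):
            if not require_sd_condition or sd < m:
                return True
    return False


def compute_tas(summary: TrialSummary) -> float:
    """Total Asymmetry Score of one trial (mm), head terms half-weighted."""
    return (
        abs(summary.mean_hd_min) / 2.0
        + abs(summary.mean_hd_max) / 2.0
        + abs(summary.mean_pd_min)
        + abs(summary.mean_pd_max)
    )


def compute_tas_lunge(left: TrialSummary | None,
                      right: TrialSummary | None) -> float:
    """Combined lunge TAS: signed per-parameter sums over both directions,
    then the TAS formula on the sums.  Missing direction propagates NaN."""
    if left is None or right is None:
        return math.nan
    s = {p: left.mean(p) + right.mean(p) for p in PARAMS}
    return (
        abs(s["hd_min"]) / 2.0 + abs(s["hd_max"]) / 2.0
        + abs(s["pd_min"]) + abs(s["pd_max"])
    )


def assess_horses(trials: pd.DataFrame,
                  thresholds: Thresholds | None = None,
                  horses: pd.DataFrame | None = None) -> pd.DataFrame:
    """Build the per-horse assessment table from trial summaries.

    One row per horse: classification per straight-line surface, double
    threshold and high-variability flags, TAS on the hard-surface trial and
    the combined lunge TAS.  Missing trials propagate as missing
    classifications (the denominators of downstream summaries shrink).
    """
    th = thresholds or Thresholds()
    rows = []
    for horse_id, grp in trials.groupby("horse_id", sort=True):
        by_cond = {
            row["condition"]: TrialSummary.from_row(row)
            for _, row in grp.iterrows()
        }
        rec: dict = {"horse_id": horse_id}
        for cond, tag in (("straight_hard", "hard"), ("straight_soft", "soft")):
            s = by_cond.get(cond)
            if s is None:
                rec[f"class_{tag}"] = "missing"
                rec[f"double_{tag}"] = np.nan
                rec[f"double_any_sd_{tag}"] = np.nan
                rec[f"high_var_{tag}"] = np.nan
            else:
                c = classify_horse(s, th)
                rec[f"class_{tag}"] = c.status
                rec[f"double_{tag}"] = flag_double_threshold(s, th)
                rec[f"double_any_sd_{tag}"] = flag_double_threshold(
                    s, th, require_sd_condition=False
                )
                rec[f"high_var_{tag}"] = c.high_variability
        hard = by_cond.get("straight_hard")
        rec["tas_straight"] = compute_tas(hard) if hard else math.nan
        rec["tas_lunge"] = compute_tas_lunge(
            by_cond.get("lunge_left"), by_cond.get("lunge_right")
        )
        lunges = [by_cond.get("lunge_left"), by_cond.get("lunge_right")]
        durs = [s.mean_stride_duration for s in lunges if s is not None]
        rec["stride_duration_lunge"] = float(np.mean(durs)) if durs else math.nan
        rec["stride_duration_straight"] = (
            hard.mean_stride_duration if hard else math.nan
        )
        rows.append(rec)
    out = pd.DataFrame(rows)
    if horses is not None:
        out = out.merge(
            horses[[c for c in ("horse_id", "discipline", "rider_id")
                    if c in horses.columns]],
            on="horse_id", how="left",
        )
    return out


def _pct(k: int, n: int) -> float:
    return round(100.0 * k / n, 1) if n else 0.0


def population_summary(assessments: pd.DataFrame, surface: str = "hard") -> dict:
    """Prevalence, double-threshold and high-variability summary per surface.

    Percentages are reported to one decimal and recompute exactly from the
    integer counts.  Horses without the surface's trial are excluded from
    the denominator.
    """
    cls = assessments[f"class_{surface}"]
    have = assessments.loc[cls.isin(["asymmetric", "symmetric"])]
    n = len(have)
    asym = have[f"class_{surface}"] == "asymmetric"
    n_asym = int(asym.sum())
    n_double = int(have.loc[asym, f"double_{surface}"].astype(bool).sum())
    n_high_var = int(
        have.loc[~asym, f"high_var_{surface}"].astype(bool).sum()
    )
    result = {
        "surface": surface,
        "n": n,
        "n_asymmetric": n_asym,
        "prevalence_pct": _pct(n_asym, n),
        "n_double_threshold": n_double,
        "double_threshold_pct": _pct(n_double, n),
        "n_high_variability": n_high_var,
        "by_discipline": {},
    }
    if "discipline" in have.columns:
        for disc, grp in have.groupby("discipline"):
            k = int((grp[f"class_{surface}"] == "asymmetric").sum())
            result["by_discipline"][disc] = {
                "n": len(grp),
                "n_asymmetric": k,
                "prevalence_pct": _pct(k, len(grp)),
            }
    return result


def concordance_summary(assessments: pd.DataFrame) -> dict:
    """Hard/soft surface agreement of the classification.

    Partitions horses with both straight-line trials into three exhaustive,
    disjoint categories: asymmetric on both, symmetric on both, discordant.
    """
    both = assessments.loc[
        assessments["class_hard"].isin(["asymmetric", "symmetric"])
        & assessments["class_soft"].isin(["asymmetric", "symmetric"])
    ]
    n = len(both)
    aa = int(((both["class_hard"] == "asymmetric")
              & (both["class_soft"] == "asymmetric")).sum())
    ss = int(((both["class_hard"] == "symmetric")
              & (both["class_soft"] == "symmetric")).sum())
    disc = n - aa - ss
    return {
        "n": n,
        "n_both_asymmetric": aa,
        "both_asymmetric_pct": _pct(aa, n),
        "n_both_symmetric": ss,
        "both_symmetric_pct": _pct(ss, n),
        "n_discordant": disc,
        "discordant_pct": _pct(disc, n),
    }


def quartile_summary(values, convention: str = "strict_above") -> dict:
    """Descriptives plus the upper quartile of threshold-exceeding values.

    ``values`` are absolute trial means of one parameter over the horses
    that exceeded its threshold (with the SD condition).  The "top
    quartile" is the set of values above the 75th percentile; with
    ``convention="strict_above"`` (default) those strictly greater than the
    linearly interpolated percentile, with ``"ceil_n4"`` the ceil(n/4)
    largest values.

    With fewer than 4 values only the overall n/mean/SD are returned.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    out = {
        "n": n,
        "mean": float(np.mean(x)) if n else math.nan,
        "sd": float(np.std(x, ddof=1)) if n > 1 else 0.0 if n else math.nan,
    }
    if n < 4:
        return out
    q75 = float(np.percentile(x, 75))
    if convention == "strict_above":
        top = x[x > q75]
        if top.size == 0:  # ties at the percentile (e.g. all values equal)
            top = x[-math.ceil(n / 4):]
    elif convention == "ceil_n4":
        top = x[-math.ceil(n / 4):]
    else:
        raise ValueError(f"unknown quartile convention {convention!r}")
    out.update(
        {
            "q75": q75,
            "n_top": int(top.size),
            "mean_top": float(np.mean(top)) if top.size else math.nan,
            "range_top": (float(top.min()), float(top.max())) if top.size else None,
        }
    )
    return out


def parameter_table(trials: pd.DataFrame,
                    condition: str,
                    thresholds: Thresholds | None = None,
                    convention: str = "strict_above") -> pd.DataFrame:
    """Per-parameter summary of threshold-exceeding horses on one condition.

    For each parameter: number of horses whose |mean| exceeds the threshold
    with SD < |mean|, mean and SD of those |mean| values, and the upper
    quartile descriptives.  A final row summarizes TAS over the horses
    classified asymmetric on that condition.
    """
    th = thresholds or Thresholds()
    sub = trials.loc[trials["condition"] == condition]
    rows = []
    for p in PARAMS:
        m = sub[f"mean_{p}"].abs()
        sd = sub[f"sd_{p}"]
        exceed = m[(m > th.for_param(p)) & (sd < m)]
        q = quartile_summary(exceed.to_numpy(), convention=convention)
        rows.append({"variable": f"|{p}|", **_flatten_quartiles(q)})
    tas_vals = []
    for _, row in sub.iterrows():
        s = TrialSummary.from_row(row)
        if classify_horse(s, th).status == "asymmetric":
            tas_vals.append(compute_tas(s))
    q = quartile_summary(np.asarray(tas_vals), convention=convention)
    rows.append({"variable": "tas", **_flatten_quartiles(q)})
    return pd.DataFrame(rows)


def _flatten_quartiles(q: dict) -> dict:
    flat = {k: v for k, v in q.items() if k != "range_top"}
    rng = q.get("range_top")
    flat["top_min"] = rng[0] if rng else math.nan
    flat["top_max"] = rng[1] if rng else math.nan
    return flat
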