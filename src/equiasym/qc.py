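"""Trial quality control: outlier strides, manual exclusions, inclusion rules.

Stride-level outlier removal mirrors the standard processing of IMU gait
trials: each stride's head parameters are compared with the trial average
using the Mahalanobis distance and strides at three or more standard
deviations are removed; the statistics are recomputed and the procedure is
repeated until no further outliers are found.  Trials that end up with too
few strides are excluded: lunge trials need at least 25 strides and
straight-line trials at least 20, except that straight-line trials with
16-19 strides are accepted when every asymmetry parameter's SD is below the
absolute parameter mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PARAM_COLS = ("hd_min_mm", "hd_max_mm", "pd_min_mm", "pd_max_mm")
HEAD_COLS = ("hd_min_mm", "hd_max_mm")


class QCInputError(ValueError):
    """Invalid input to a QC operation."""


@dataclass
class QCReport:
    """Log of what quality control did to one trial."""

    trial_id: str = ""
    n_strides_in: int = 0
    n_strides_removed_auto: int = 0
    n_strides_removed_manual: int = 0
    iterations: int = 0
    method: str = ""  # "mahalanobis" or "univariate-3sd" fallback
    included: bool = True
    exclusion_reason: str = ""


def _mahalanobis_sq(x: np.ndarray) -> np.ndarray | None:
    """Squared Mahalanobis distance of each row to the sample mean.

    Returns ``None`` when the sample covariance is singular or the sample
    is too small for a stable estimate, signalling the univariate fallback.
    """
    n, p = x.shape
    if n <= p:
        return None
    mu = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if np.linalg.cond(cov) > 1e10:
        return None
    diff = x - mu
    sol = np.linalg.solve(cov, diff.T)
    return np.einsum("ij,ji->i", diff, sol)


def _univariate_outliers(x: np.ndarray) -> np.ndarray:
    """Boolean mask of rows with any parameter >= 3 SD from its mean."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    mask = np.zeros(x.shape[0], dtype=bool)
    ok = sd > 0
    if np.any(ok):
        dev = np.abs(x[:, ok] - mu[ok]) / sd[ok]
        mask = np.any(dev >= 3.0, axis=1)
    return mask


def remove_outliers_iterative(
    strides: pd.DataFrame,
    parameters: str = "head",
    threshold: float = 3.0,
    trial_id: str = "",
) -> tuple[pd.DataFrame, QCReport]:
    """Iteratively remove outlier strides by Mahalanobis distance.

    Parameters
    ----------
    strides : pandas.DataFrame
        Stride table with the four ``*_mm`` parameter columns.
    parameters : {"head", "all"}
        Which parameters enter the distance: the head pair (default, the
        standard processing) or all four.
    threshold : float
        Removal at distance >= ``threshold`` standard deviations
        (inclusive, "three or more").

    Returns the cleaned table and a :class:`QCReport`.  When the covariance
    is singular the per-parameter univariate 3-SD rule is used instead and
    recorded in the report.  The operation is idempotent on its own output.
    """
    if parameters not in ("head", "all"):
        raise QCInputError(f"parameters must be 'head' or 'all', got {parameters!r}")
    cols = list(HEAD_COLS if parameters == "head" else PARAM_COLS)
    if len(strides) < 2:
        raise QCInputError("need at least 2 strides for outlier removal")

    report = QCReport(trial_id=trial_id, n_strides_in=len(strides))
    current = strides.reset_index(drop=True)
    method = "mahalanobis"
    while True:
        report.iterations += 1
        x = current[cols].to_numpy(dtype=float)
        if np.allclose(x.std(axis=0), 0.0):
            break  # constant values: nothing can be an outlier
        d2 = _mahalanobis_sq(x)
        if d2 is None:
            method = "univariate-3sd"
            out = _univariate_outliers(x)
        else:
            out = d2 >= threshold**2
        if not np.any(out) or np.all(out):
            if np.all(out):
                # refusing to delete the whole trial; flag instead
                report.included = False
                report.exclusion_reason = "outlier removal flagged every stride"
            break
        report.n_strides_removed_auto += int(np.sum(out))
        current = current.loc[~out].reset_index(drop=True)
        if len(current) < 2:
            report.included = False
            report.exclusion_reason = "fewer than 2 strides left after outlier removal"
            break
    report.method = method
    if len(current) == 0:
        report.included = False
        report.exclusion_reason = report.exclusion_reason or "all strides removed"
    return current, report


def exclude_stride_ranges(
    strides: pd.DataFrame,
    ranges: list[tuple[int, int]],
    trial_id: str = "",
) -> tuple[pd.DataFrame, QCReport]:
    """Drop manually specified stride ranges (inclusive index pairs).

    Ranges refer to ``stride_index`` values; they must lie within the trial
    and must not overlap.  Used for sequences with disturbed head movement
    (head tossing, biting at the handler) identified on video.
    """
    report = QCReport(trial_id=trial_id, n_strides_in=len(strides))
    if not ranges:
        return strides, report
    idx = strides["stride_index"].to_numpy()
    lo, hi = idx.min(), idx.max()
    covered: set[int] = set()
    for start, end in ranges:
        if start > end or start < lo or end > hi:
            raise QCInputError(f"stride range ({start}, {end}) outside trial [{lo}, {hi}]")
        span = set(range(start, end + 1))
        if covered & span:
            raise QCInputError(f"stride range ({start}, {end}) overlaps another range")
        covered |= span
    keep = ~strides["stride_index"].isin(covered)
    report.n_strides_removed_manual = int((~keep).sum())
    out = strides.loc[keep].reset_index(drop=True)
    if out.empty:
        report.included = False
        report.exclusion_reason = "manual exclusion removed every stride"
    return out, report


def apply_inclusion_rules(summary) -> tuple[bool, str]:
    """Decide whether a trial enters the analysis.

    Lunge trials require >= 25 strides.  Straight-line trials require
    >= 20 strides, or 16-19 strides with SD < |mean| for all four
    asymmetry parameters.

    Parameters
    ----------
    summary : TrialSummary
        Needs ``condition``, ``n_strides`` and the per-parameter
        mean/SD attributes.
    """
    cond = getattr(summary, "condition", None)
    if not cond:
        raise QCInputError("trial summary is missing its condition label")
    n = summary.n_strides
    if cond.startswith("lunge"):
        if n >= 25:
            return True, ""
        return False, f"lunge trial with {n} < 25 strides"
    if cond.startswith("straight"):
        if n >= 20:
            return True, ""
        if 16 <= n < 20:
            pairs = [
                (summary.mean_hd_min, summary.sd_hd_min),
                (summary.mean_hd_max, summary.sd_hd_max),
                (summary.mean_pd_min, summary.sd_pd_min),
                (summary.mean_pd_max, summary.sd_pd_max),
            ]
            if all(sd < abs(m) for m, sd in pairs):
                return True, ""
            return False, (
                f"straight-line trial with {n} strides and SD >= |mean| "
                "for at least one parameter"
            )
        return False, f"straight-line trial with {n} < 16 strides"
    raise QCInputError(f"unknown condition label {cond!r}")
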