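"""Descriptive and inferential behavioral statistics.

The placebo (hypoalgesic) effect is the mean test-phase control rating minus
the mean test-phase placebo rating: positive values mean pain relief under
physically identical stimulation.  Individual treatment variability is the
subject's n-1 SD over the conditioning-phase placebo ratings; the sub-sample
cut-offs select subjects in whom the precision manipulation took hold (HTP
kept below a variance ceiling, LTP above a variance floor — both derived from
an independent behavioral sample in the original design).

Correlations use Pearson's product-moment r; the precision regression is an
OLS of the observed placebo effect on sigma_prior and sigma_like (Bayesian
model fits) with an intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import InputError, InsufficientDataError, MissingCellError, ParameterError

# variance cut-offs (VAS^2) from the independent calibration sample:
# HTP subjects are kept when their conditioning-placebo rating variance is
# strictly below the LTP-average ceiling; LTP subjects when strictly above the
# HTP-average floor.  (SD equivalents: 19.60 and 13.96.)
HTP_VARIANCE_CEILING = 384.08
LTP_VARIANCE_FLOOR = 194.90

_CELLS = [
    ("conditioning", "placebo"),
    ("conditioning", "control"),
    ("test", "placebo"),
    ("test", "control"),
]


@dataclass(frozen=True)
class SubjectSummary:
    subject_id: object
    group: str
    placebo_effect_observed: float
    mean_cond_placebo: float
    mean_cond_control: float
    mean_test_placebo: float
    mean_test_control: float
    sd_cond_placebo: float  # n-1 convention throughout
    sd_cond_control: float
    sd_test_placebo: float
    sd_test_control: float


@dataclass(frozen=True)
class RegressionResult:
    """OLS of observed placebo effect on (sigma_prior, sigma_like)."""

    params: dict[str, float]  # unstandardized coefficients incl. intercept
    bse: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    standardized: dict[str, float]  # beta weights on z-scored variables
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_subject(trials: pd.DataFrame, subject_id) -> SubjectSummary:
    sub = trials[trials["subject_id"] == subject_id]
    means, sds = {}, {}
    for phase, condition in _CELLS:
        vals = sub.loc[
            (sub["phase"] == phase) & (sub["condition"] == condition), "vas"
        ].to_numpy(dtype=float)
        if vals.size == 0:
            raise MissingCellError(subject_id, phase, condition)
        means[(phase, condition)] = float(np.mean(vals))
        sds[(phase, condition)] = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    group = str(sub["group"].iloc[0]) if "group" in sub.columns else ""
    return SubjectSummary(
        subject_id=subject_id,
        group=group,
        placebo_effect_observed=means[("test", "control")] - means[("test", "placebo")],
        mean_cond_placebo=means[("conditioning", "placebo")],
        mean_cond_control=means[("conditioning", "control")],
        mean_test_placebo=means[("test", "placebo")],
        mean_test_control=means[("test", "control")],
        sd_cond_placebo=sds[("conditioning", "placebo")],
        sd_cond_control=sds[("conditioning", "control")],
        sd_test_placebo=sds[("test", "placebo")],
        sd_test_control=sds[("test", "control")],
    )


def summarize_cohort(trials: pd.DataFrame, models: pd.DataFrame | None = None) -> pd.DataFrame:
    """One summary row per subject; adds the Bayesian model's predicted effect if given."""
    rows = [asdict(summarize_subject(trials, s)) for s in pd.unique(trials["subject_id"])]
    out = pd.DataFrame(rows)
    if models is not None:
        pred = models.loc[models["model"] == "bayes", ["subject_id", "predicted_placebo_effect"]]
        out = out.merge(
            pred.rename(columns={"predicted_placebo_effect": "placebo_effect_predicted"}),
            on="subject_id",
            how="left",
        )
    return out


def apply_subsample_cutoffs(
    summaries: pd.DataFrame,
    htp_variance_ceiling: float = HTP_VARIANCE_CEILING,
    ltp_variance_floor: float = LTP_VARIANCE_FLOOR,
) -> pd.DataFrame:
    """Flag subjects in whom the precision manipulation was induced.

    Returns a copy with an ``in_subsample`` column; no rating-derived value is
    altered.  Inequalities are strict on the conditioning-placebo rating
    variance (n-1).
    """
    known = {"HTP", "LTP"}
    bad = set(summaries["group"].unique()) - known
    if bad:
        raise InputError(f"unknown group labels {sorted(bad)}; expected {sorted(known)}")
    out = summaries.copy()
    variance = out["sd_cond_placebo"].to_numpy(dtype=float) ** 2
    is_htp = (out["group"] == "HTP").to_numpy()
    out["in_subsample"] = np.where(
        is_htp, variance < htp_variance_ceiling, variance > ltp_variance_floor
    )
    return out


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment r with its two-sided t-based p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-d and of equal length")
    if x.size < 3:
        raise InsufficientDataError(f"need at least 3 pairs, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ParameterError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def regress_placebo_on_sigmas(
    summaries: pd.DataFrame, models: pd.DataFrame
) -> RegressionResult:
    """OLS: observed placebo effect ~ intercept + sigma_prior + sigma_like.

    Uses the Bayesian model's fitted sigmas.  Reports both unstandardized
    coefficients (the prediction-equation scale) and standardized betas.
    """
    bayes = models.loc[models["model"] == "bayes", ["subject_id", "sigma_prior", "sigma_like"]]
    data = summaries[["subject_id", "placebo_effect_observed"]].merge(bayes, on="subject_id")
    if len(data) < 4:
        raise InsufficientDataError(f"need at least 4 subjects, got {len(data)}")
    y = data["placebo_effect_observed"].to_numpy(dtype=float)
    X = data[["sigma_prior", "sigma_like"]].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ParameterError("collinear predictors: design matrix is rank deficient")
    fit = sm.OLS(y, design).fit()

    names = ["intercept", "sigma_prior", "sigma_like"]
    sy = float(np.std(y, ddof=1))
    standardized = {"intercept": 0.0}
    for i, name in enumerate(names[1:], start=1):
        sx = float(np.std(X[:, i - 1], ddof=1))
        standardized[name] = float(fit.params[i]) * sx / sy
    return RegressionResult(
        params=dict(zip(names, map(float, fit.params))),
        bse=dict(zip(names, map(float, fit.bse))),
        tvalues=dict(zip(names, map(float, fit.tvalues))),
        pvalues=dict(zip(names, map(float, fit.pvalues))),
        standardized=standardized,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        n=len(data),
    )
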