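"""Per-subject model comparison via the conjugate Gaussian marginal likelihood.

Each candidate model predicts the subject's test-phase placebo percept as a
Gaussian N(mu_M, sigma_M^2) (its integrated posterior).  Treating that
prediction as a prior over the uncertain rating mean mu_obs, and the observed
test-placebo ratings X = {x_1..x_n} as i.i.d. N(mu_obs, sigma_obs^2), the
model evidence integrates mu_obs out in closed form:

    p(X | mu_M, sigma_obs^2, sigma_M^2)
        = integral [prod_i N(x_i | mu_obs, sigma_obs^2)] N(mu_obs | mu_M, sigma_M^2) d mu_obs

Equivalently X is marginally Gaussian with mean mu_M * 1 and covariance
sigma_obs^2 I + sigma_M^2 11', giving the numerically stable log form used
here:

    log p = -n/2 log(2 pi sigma_obs^2) - 1/2 log(1 + n sigma_M^2 / sigma_obs^2)
            - SS / (2 sigma_obs^2) - n (xbar - mu_M)^2 / (2 (sigma_obs^2 + n sigma_M^2))

with xbar the sample mean and SS the centred sum of squares.  The Bayes
factor BF10 = evidence(bayes) / evidence(null) is formed in log space; the
posterior model probability under equal model priors is BF10 / (BF10 + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import InsufficientDataError, ParameterError
from .gaussian_fit import DEFAULT_SIGMA_FLOOR, GaussianParams

_LOG_BF_DISPLAY_CAP = 700.0  # keeps exp() finite for reporting; comparisons stay in logs

SigmaObsConvention = Literal["n_minus_1", "n"]


@dataclass(frozen=True)
class EvidenceResult:
    subject_id: object
    log_evidence_bayes: float
    log_evidence_null: float
    bf_10: float
    bf_01: float
    p_bayes: float
    p_null: float
    sigma_obs: float
    n_obs: int
    sigma_obs_floored: bool = False

    @property
    def log_bf_10(self) -> float:
        return self.log_evidence_bayes - self.log_evidence_null


@dataclass(frozen=True)
class PERResult:
    """Positive evidence ratio: counts of subjects decisively favoring each model."""

    n_favoring_bayes: int
    n_favoring_null: int
    per: float  # NaN when undefined (no subject favors the null model)
    threshold: float

    @property
    def defined(self) -> bool:
        return self.n_favoring_null > 0


def log_marginal_likelihood(
    data: Sequence[float],
    model_mu: float,
    model_sigma: float,
    sigma_obs: float,
) -> float:
    """Natural log of the conjugate marginal likelihood of ``data``."""
    x = np.asarray(data, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise InsufficientDataError("need at least one observation")
    if not np.all(np.isfinite(x)):
        raise ParameterError("observations must be finite")
    if model_sigma <= 0 or sigma_obs <= 0:
        raise ParameterError(
            f"scales must be positive (model_sigma={model_sigma}, sigma_obs={sigma_obs})"
        )
    n = x.size
    xbar = float(np.mean(x))
    ss = float(np.sum((x - xbar) ** 2))
    so2 = sigma_obs * sigma_obs
    sm2 = model_sigma * model_sigma
    return (
        -0.5 * n * math.log(2.0 * math.pi * so2)
        - 0.5 * math.log1p(n * sm2 / so2)
        - ss / (2.0 * so2)
        - n * (xbar - model_mu) ** 2 / (2.0 * (so2 + n * sm2))
    )


def compare_models(
    test_placebo_ratings: Sequence[float],
    bayes_posterior: GaussianParams,
    null_posterior: GaussianParams,
    *,
    subject_id=None,
    sigma_obs_convention: SigmaObsConvention = "n_minus_1",
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
) -> EvidenceResult:
    """Evidence comparison of the two models on one subject's test-placebo ratings.

    sigma_obs is estimated from the ratings themselves (shared by both models,
    so the comparison isolates the prior) with the n-1 convention by default;
    degenerate rating series fall back to ``sigma_floor`` and are flagged.
    """
    x = np.asarray(test_placebo_ratings, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"need at least 2 ratings, got {x.size}")
    ddof = 1 if sigma_obs_convention == "n_minus_1" else 0
    if sigma_obs_convention not in ("n_minus_1", "n"):
        raise ParameterError(f"unknown sigma_obs convention {sigma_obs_convention!r}")
    sigma_obs = float(np.std(x, ddof=ddof))
    floored = sigma_obs < sigma_floor
    if floored:
        sigma_obs = sigma_floor

    le_bayes = log_marginal_likelihood(x, bayes_posterior.mu, bayes_posterior.sigma, sigma_obs)
    le_null = log_marginal_likelihood(x, null_posterior.mu, null_posterior.sigma, sigma_obs)
    log_bf = le_bayes - le_null
    p_bayes = float(expit(log_bf))  # BF10/(BF10+1), stable in log space
    capped = min(max(log_bf, -_LOG_BF_DISPLAY_CAP), _LOG_BF_DISPLAY_CAP)
    return EvidenceResult(
        subject_id=subject_id,
        log_evidence_bayes=le_bayes,
        log_evidence_null=le_null,
        bf_10=math.exp(capped),
        bf_01=math.exp(-capped),
        p_bayes=p_bayes,
        p_null=1.0 - p_bayes,
        sigma_obs=sigma_obs,
        n_obs=int(x.size),
        sigma_obs_floored=floored,
    )


def evidence_table(results: Sequence[EvidenceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": r.subject_id,
            "log_evidence_bayes": r.log_evidence_bayes,
            "log_evidence_null": r.log_evidence_null,
            "bf_10": r.bf_10,
            "bf_01": r.bf_01,
            "p_bayes": r.p_bayes,
            "p_null": r.p_null,
            "sigma_obs": r.sigma_obs,
            "n_obs": r.n_obs,
            "sigma_obs_floored": r.sigma_obs_floored,
        }
        for r in results
    )


def per_from_counts(n_favoring_bayes: int, n_favoring_null: int, threshold: float = 3.0) -> PERResult:
    """Positive evidence ratio from decisive-subject counts.

    With no subject decisively favoring the null model the ratio is undefined
    and reported as NaN with the counts preserved, never as infinity.
    """
    if n_favoring_bayes < 0 or n_favoring_null < 0:
        raise ParameterError("counts must be non-negative")
    per = n_favoring_bayes / n_favoring_null if n_favoring_null > 0 else math.nan
    return PERResult(
        n_favoring_bayes=int(n_favoring_bayes),
        n_favoring_null=int(n_favoring_null),
        per=per,
        threshold=threshold,
    )


def positive_evidence_ratio(evidence: pd.DataFrame, threshold: float = 3.0) -> PERResult:
    """Count subjects with BF10 > threshold vs BF01 > threshold (strict).

    Comparison is done on log evidences so astronomically large Bayes factors
    cannot overflow the count.
    """
    if threshold <= 1:
        raise ParameterError(f"threshold must exceed 1, got {threshold}")
    log_bf = (
        evidence["log_evidence_bayes"].to_numpy(dtype=float)
        - evidence["log_evidence_null"].to_numpy(dtype=float)
    )
    log_t = math.log(threshold)
    return per_from_counts(int(np.sum(log_bf > log_t)), int(np.sum(-log_bf > log_t)), threshold)
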