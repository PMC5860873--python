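"""Maximum-likelihood Gaussian fits to a subject's trial ratings.

Each subject's rating distribution in one phase x condition cell is summarised
by a Gaussian N(mu, sigma^2).  The fit maximises the Gaussian log-likelihood
with a derivative-free simplex search initialised at the closed-form ML
estimates (sample mean; SD with the n denominator, matching the likelihood
being maximised).  A configurable ``sigma_floor`` guards against degenerate
all-identical rating series; floored fits are flagged.

Descriptive statistics elsewhere in the package use the n-1 convention; the
two conventions are never mixed within one statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import InsufficientDataError, MissingCellError, ParameterError

DEFAULT_SIGMA_FLOOR = 0.5  # VAS units

ModelName = Literal["bayes", "null"]

# phase x condition cell that supplies the prior under each model; the
# likelihood always comes from the untreated test-control ratings
_PRIOR_CELL = {"bayes": ("conditioning", "placebo"), "null": ("conditioning", "control")}
_LIKELIHOOD_CELL = ("test", "control")


@dataclass(frozen=True)
class GaussianParams:
    """Mean and standard deviation of a fitted rating distribution (VAS units)."""

    mu: float
    sigma: float
    degenerate: bool = False

    def __post_init__(self):
        if not (math.isfinite(self.mu) and math.isfinite(self.sigma)):
            raise ParameterError(f"non-finite Gaussian parameters ({self.mu}, {self.sigma})")
        if self.sigma <= 0:
            raise ParameterError(f"sigma must be positive, got {self.sigma}")

    @property
    def precision(self) -> float:
        return 1.0 / (self.sigma * self.sigma)


def _negative_log_likelihood(params: np.ndarray, x: np.ndarray) -> float:
    mu, log_sigma = params
    sigma2 = math.exp(2.0 * log_sigma)
    n = x.size
    return 0.5 * n * (math.log(2.0 * math.pi) + 2.0 * log_sigma) + float(
        np.sum((x - mu) ** 2)
    ) / (2.0 * sigma2)


def fit_gaussian(
    ratings: Sequence[float] | Iterable[float],
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
) -> GaussianParams:
    """ML Gaussian fit to a series of VAS ratings.

    Runs a Nelder-Mead search on (mu, log sigma) initialised at the
    closed-form estimates; for a Gaussian likelihood the two agree to
    numerical precision whenever the unconstrained optimum respects
    ``sigma_floor``.  A zero-spread series returns ``sigma_floor`` with the
    ``degenerate`` flag set.
    """
    x = np.asarray(list(ratings) if not isinstance(ratings, np.ndarray) else ratings, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InsufficientDataError(f"need at least 2 ratings, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ParameterError("ratings must be finite")
    if sigma_floor <= 0:
        raise ParameterError(f"sigma_floor must be positive, got {sigma_floor}")

    mu0 = float(np.mean(x))
    sigma0 = float(np.std(x, ddof=0))  # n-denominator ML estimate
    if sigma0 <= sigma_floor:
        # the constrained optimum sits on the floor; mu is unaffected
        return GaussianParams(mu=mu0, sigma=sigma_floor, degenerate=True)

    x0 = np.array([mu0, math.log(sigma0)])
    res = optimize.minimize(
        _negative_log_likelihood,
        x0=x0,
        args=(x,),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 10_000},
    )
    # keep the better point: accept the simplex result only if it improves on
    # the analytic start beyond floating-point noise (ties go to the start)
    f0 = _negative_log_likelihood(x0, x)
    best = res.x if res.fun < f0 - 1e-9 * max(1.0, abs(f0)) else x0
    mu, sigma = float(best[0]), float(math.exp(best[1]))
    if sigma < sigma_floor:
        return GaussianParams(mu=mu, sigma=sigma_floor, degenerate=True)
    return GaussianParams(mu=mu, sigma=sigma)


def _cell_ratings(trials: pd.DataFrame, subject_id, phase: str, condition: str) -> np.ndarray:
    mask = (
        (trials["subject_id"] == subject_id)
        & (trials["phase"] == phase)
        & (trials["condition"] == condition)
    )
    vals = trials.loc[mask, "vas"].to_numpy(dtype=float)
    if vals.size == 0:
        raise MissingCellError(subject_id, phase, condition)
    return vals


def fit_subject(
    trials: pd.DataFrame,
    subject_id,
    model: ModelName,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
) -> tuple[GaussianParams, GaussianParams]:
    """Fit (prior, likelihood) for one subject under one model.

    The Bayesian-integration model takes its prior from the conditioning
    placebo (treated) ratings; the Null model takes it from the conditioning
    control ratings, encoding no influence of the treatment experience.  Both
    share the likelihood fitted on test-phase control ratings.
    """
    if model not in _PRIOR_CELL:
        raise ParameterError(f"unknown model {model!r}; expected 'bayes' or 'null'")
    phase, condition = _PRIOR_CELL[model]
    prior = fit_gaussian(_cell_ratings(trials, subject_id, phase, condition), sigma_floor)
    likelihood = fit_gaussian(_cell_ratings(trials, subject_id, *_LIKELIHOOD_CELL), sigma_floor)
    return prior, likelihood


def fit_all_subjects(
    trials: pd.DataFrame, sigma_floor: float = DEFAULT_SIGMA_FLOOR
) -> pd.DataFrame:
    """Fit both models for every subject.

    Returns a tidy table with one row per subject x model: ``subject_id``,
    ``model``, ``mu_prior``, ``sigma_prior``, ``mu_like``, ``sigma_like`` and
    a ``degenerate_flags`` string ('' / 'prior' / 'like' / 'prior,like').
    """
    rows = []
    for subject_id in pd.unique(trials["subject_id"]):
        for model in ("bayes", "null"):
            prior, like = fit_subject(trials, subject_id, model, sigma_floor)
            flags = ",".join(
                name for name, p in (("prior", prior), ("like", like)) if p.degenerate
            )
            rows.append(
                {
                    "subject_id": subject_id,
                    "model": model,
                    "mu_prior": prior.mu,
                    "sigma_prior": prior.sigma,
                    "mu_like": like.mu,
                    "sigma_like": like.sigma,
                    "degenerate_flags": flags,
                }
            )
    return pd.DataFrame(rows)


def params_from_row(row, which: str) -> GaussianParams:
    """Rebuild :class:`GaussianParams` from a ``fit_all_subjects`` row."""
    flags = str(row["degenerate_flags"]) if not pd.isna(row["degenerate_flags"]) else ""
    key = "prior" if which == "prior" else "like"
    return GaussianParams(
        mu=float(row[f"mu_{key}"]),
        sigma=float(row[f"sigma_{key}"]),
        degenerate=key in flags.split(","),
    )
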