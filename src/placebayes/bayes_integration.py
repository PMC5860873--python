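"""Precision-weighted integration of prior and likelihood.

With Gaussian prior N(mu_p, sigma_p^2) and likelihood N(mu_l, sigma_l^2), the
posterior percept is the normalised product of the two densities:

    w_prior = (1/sigma_p^2) / (1/sigma_p^2 + 1/sigma_l^2)
    mu_post = w_prior * mu_p + w_like * mu_l
    1/sigma_post^2 = 1/sigma_p^2 + 1/sigma_l^2

The attraction weight w_prior is the relative precision of the treatment
expectation: the closer to 1, the more the predicted treated percept is pulled
toward the expectation and away from the incoming nociceptive evidence.

Weights are evaluated in variance space, w_prior = sigma_l^2 / (sigma_p^2 +
sigma_l^2), which is algebraically identical but cannot overflow when a
floored (near-degenerate) sigma makes a raw precision huge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import pandas as pd

from .errors import ParameterError
from .gaussian_fit import GaussianParams


@dataclass(frozen=True)
class SubjectModel:
    """One subject's fitted prior/likelihood and predicted posterior under one model."""

    subject_id: object
    model: Literal["bayes", "null"]
    prior: GaussianParams
    likelihood: GaussianParams
    posterior: GaussianParams
    w_prior: float
    w_like: float
    predicted_placebo_effect: float  # likelihood mu - posterior mu, VAS units


def attraction_weight(prior: GaussianParams, likelihood: GaussianParams) -> tuple[float, float]:
    """Relative precision (w_prior, w_like) of prior vs likelihood; sums to 1."""
    sp2 = prior.sigma * prior.sigma
    sl2 = likelihood.sigma * likelihood.sigma
    w_prior = sl2 / (sp2 + sl2)
    return w_prior, 1.0 - w_prior


def integrate(prior: GaussianParams, likelihood: GaussianParams) -> GaussianParams:
    """Posterior Gaussian: precision-weighted mean, summed precisions."""
    w_prior, w_like = attraction_weight(prior, likelihood)
    mu_post = w_prior * prior.mu + w_like * likelihood.mu
    # sigma_p * sigma_l / sqrt(sigma_p^2 + sigma_l^2), overflow-safe
    sigma_post = prior.sigma * likelihood.sigma / math.hypot(prior.sigma, likelihood.sigma)
    return GaussianParams(mu=mu_post, sigma=sigma_post)


def build_subject_model(
    subject_id, model: str, prior: GaussianParams, likelihood: GaussianParams
) -> SubjectModel:
    if model not in ("bayes", "null"):
        raise ParameterError(f"unknown model {model!r}")
    posterior = integrate(prior, likelihood)
    w_prior, w_like = attraction_weight(prior, likelihood)
    return SubjectModel(
        subject_id=subject_id,
        model=model,
        prior=prior,
        likelihood=likelihood,
        posterior=posterior,
        w_prior=w_prior,
        w_like=w_like,
        predicted_placebo_effect=likelihood.mu - posterior.mu,
    )


def build_subject_models(
    subject_id,
    bayes_prior: GaussianParams,
    null_prior: GaussianParams,
    likelihood: GaussianParams,
) -> tuple[SubjectModel, SubjectModel]:
    """Both candidate models for one subject; they share the likelihood."""
    return (
        build_subject_model(subject_id, "bayes", bayes_prior, likelihood),
        build_subject_model(subject_id, "null", null_prior, likelihood),
    )


def models_table(models: list[SubjectModel]) -> pd.DataFrame:
    """Tidy table of subject models, one row per subject x model."""
    return pd.DataFrame(
        {
            "subject_id": m.subject_id,
            "model": m.model,
            "mu_prior": m.prior.mu,
            "sigma_prior": m.prior.sigma,
            "mu_like": m.likelihood.mu,
            "sigma_like": m.likelihood.sigma,
            "mu_post": m.posterior.mu,
            "sigma_post": m.posterior.sigma,
            "w_prior": m.w_prior,
            "w_like": m.w_like,
            "predicted_placebo_effect": m.predicted_placebo_effect,
        }
        for m in models
    )
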