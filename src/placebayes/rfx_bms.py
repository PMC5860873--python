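"""Random-effects Bayesian model selection over per-subject log evidences.

The group is modelled as drawing each subject's model from a multinomial with
frequencies r ~ Dirichlet(alpha).  A variational Bayes scheme alternates

    u_nk  proportional to  exp(log_evidence_nk + psi(alpha_k) - psi(sum alpha))
    alpha_k = prior_alpha_k + sum_n u_nk / sum_j u_nj

until the concentration parameters stabilise.  Expected model probabilities
are alpha / sum(alpha); the exceedance probability of model k is the posterior
probability that r_k is the largest component.  For two models that is an
exact Beta tail probability; for three or more it is estimated by seeded
Monte-Carlo sampling of the Dirichlet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import digamma, softmax

from .errors import InputError, ParameterError

DEFAULT_PRIOR_ALPHA = 1.0
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 10_000
DEFAULT_MC_DRAWS = 1_000_000


@dataclass(frozen=True)
class RFXResult:
    alpha: np.ndarray
    expected_prob: np.ndarray
    exceedance_prob: np.ndarray
    n_subjects: int
    converged: bool
    iterations: int
    seed: int | None = None  # used only when exceedance needed sampling

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha.tolist(),
            "expected_prob": self.expected_prob.tolist(),
            "exceedance_prob": self.exceedance_prob.tolist(),
            "n_subjects": self.n_subjects,
            "converged": self.converged,
            "iterations": self.iterations,
            "seed": self.seed,
        }


def exceedance_probabilities(
    alpha, n_draws: int = DEFAULT_MC_DRAWS, seed: int | None = None
) -> np.ndarray:
    """P(model k has the largest frequency) under Dirichlet(alpha).

    Exact via the Beta distribution for two models; seeded Monte Carlo
    otherwise.
    """
    a = np.asarray(alpha, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ParameterError("alpha must be a vector of length >= 2")
    if np.any(a <= 0) or not np.all(np.isfinite(a)):
        raise ParameterError("alpha entries must be positive and finite")
    if a.size == 2:
        # r0 ~ Beta(a0, a1); model 0 exceeds iff r0 > 1/2
        phi0 = stats.beta.sf(0.5, a[0], a[1])
        return np.array([phi0, 1.0 - phi0])
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(a, size=n_draws)
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=a.size) / n_draws


def rfx_model_selection(
    log_evidence_matrix,
    prior_alpha: float = DEFAULT_PRIOR_ALPHA,
    *,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | None = None,
    mc_draws: int = DEFAULT_MC_DRAWS,
) -> RFXResult:
    """Variational RFX model selection on a subjects x models log-evidence matrix."""
    lme = np.asarray(log_evidence_matrix, dtype=float)
    if lme.ndim != 2 or lme.shape[0] < 1 or lme.shape[1] < 2:
        raise ParameterError("need a (subjects >= 1) x (models >= 2) matrix")
    if not np.all(np.isfinite(lme)):
        raise InputError("log evidences must be finite")
    if prior_alpha <= 0:
        raise ParameterError(f"prior_alpha must be positive, got {prior_alpha}")

    n, k = lme.shape
    alpha0 = np.full(k, float(prior_alpha))
    alpha = alpha0.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        log_u = lme + digamma(alpha) - digamma(alpha.sum())
        responsibilities = softmax(log_u, axis=1)
        alpha_new = alpha0 + responsibilities.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new

    return RFXResult(
        alpha=alpha,
        expected_prob=alpha / alpha.sum(),
        exceedance_prob=exceedance_probabilities(alpha, n_draws=mc_draws, seed=seed),
        n_subjects=n,
        converged=converged,
        iterations=iterations,
        seed=seed if k > 2 else None,
    )
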