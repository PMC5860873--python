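"""Seeded synthetic cohorts with the conditioning/test placebo experiment's structure.

The emulated design: two groups of subjects receive a sham analgesic
treatment.  During conditioning, treated (placebo) heat stimuli are calibrated
to a mild VAS 30 while untreated control stimuli sit at VAS 70.  The
high-treatment-precision (HTP) group always receives the identical VAS-30
temperature; the low-treatment-precision (LTP) group receives temperatures
jittered around it (SD 0.55 degC, |offset| <= 0.8 degC), inflating their
rating variability.  In the test phase both conditions deliver the identical
VAS-50 temperature, and each subject's treated ratings are drawn from their
generating model's integrated posterior — Bayesian (conditioning-placebo
prior) or Null (conditioning-control prior).

Every subject carries a private logistic psychometric function mapping
temperature to expected VAS; midpoint and slope are sampled from configured
ranges.  Ratings are expected VAS plus Gaussian noise, bounded to [0, 100].
The default "resample" bounding draws from a truncated normal whose location
and scale are solved so the realized mean and SD equal the design values,
keeping the stated anchors (VAS 30/50/70) and noise levels exact despite the
bounded scale; "clip" is a simple clamp and slightly biases means near the
bounds.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import erfcx, expit, logit

from .bayes_integration import integrate
from .errors import ParameterError
from .gaussian_fit import GaussianParams

GROUPS = ("HTP", "LTP")
PHASES = ("conditioning", "test")
CONDITIONS = ("placebo", "control")

TRIAL_COLUMNS = ["subject_id", "group", "phase", "condition", "trial", "temperature_c", "vas"]


@dataclass(frozen=True)
class CohortConfig:
    """Design parameters of a simulated two-group conditioning/test cohort.

    Defaults reproduce the study conditions: 31 subjects per group, 12 trials
    per condition per phase, VAS anchors 30 (conditioning placebo), 70
    (conditioning control) and 50 (test), and LTP temperature jitter with
    SD 0.55 degC bounded at +/- 0.8 degC.  Per-subject psychometric slopes and
    rating-noise SDs are uniform over the configured ranges.
    """

    seed: int
    n_htp: int = 31
    n_ltp: int = 31
    trials_per_condition: int = 12
    vas_cond_placebo_mean: float = 30.0
    vas_cond_control_mean: float = 70.0
    vas_test_mean: float = 50.0
    ltp_temp_sd: float = 0.55
    ltp_temp_max_offset: float = 0.8
    rating_noise_sd_range: tuple[float, float] = (9.0, 18.0)
    psychometric_slope_range: tuple[float, float] = (30.0, 45.0)  # VAS per degC at midpoint
    psychometric_midpoint_range: tuple[float, float] = (44.0, 46.0)  # degC for VAS 50
    fraction_bayes_subjects: float = 1.0
    truncation_policy: Literal["clip", "resample"] = "resample"

    def __post_init__(self):
        if self.n_htp < 1 or self.n_ltp < 1:
            raise ParameterError("group sizes must be >= 1")
        if self.trials_per_condition < 1:
            raise ParameterError("trials_per_condition must be >= 1")
        for name in ("vas_cond_placebo_mean", "vas_cond_control_mean", "vas_test_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ParameterError(f"{name} must lie in [0, 100], got {v}")
        if self.ltp_temp_sd < 0 or self.ltp_temp_max_offset <= 0:
            raise ParameterError("temperature jitter parameters must be positive")
        for name in (
            "rating_noise_sd_range",
            "psychometric_slope_range",
            "psychometric_midpoint_range",
        ):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ParameterError(f"{name} must satisfy 0 < low <= high")
        if not 0.0 <= self.fraction_bayes_subjects <= 1.0:
            raise ParameterError("fraction_bayes_subjects must lie in [0, 1]")
        if self.truncation_policy not in ("clip", "resample"):
            raise ParameterError(f"unknown truncation_policy {self.truncation_policy!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def heterogeneous_cohort_config(seed: int, **overrides) -> CohortConfig:
    """Preset with 90% Bayesian-integrating subjects, mimicking cohort heterogeneity."""
    overrides.setdefault("fraction_bayes_subjects", 0.9)
    return CohortConfig(seed=seed, **overrides)


class Psychometric:
    """Logistic temperature -> expected-VAS mapping.

    Parametrised by the VAS-50 midpoint temperature (degC) and the slope at
    the midpoint (VAS per degC); logistic chosen for closed-form inversion.
    """

    def __init__(self, midpoint: float, slope: float):
        if slope <= 0:
            raise ParameterError(f"slope must be positive, got {slope}")
        self.midpoint = float(midpoint)
        self.slope = float(slope)
        self._rate = 4.0 * slope / 100.0  # logistic rate per degC

    def __call__(self, temperature_c):
        return 100.0 * expit(self._rate * (np.asarray(temperature_c, dtype=float) - self.midpoint))

    def invert(self, vas: float) -> float:
        if not 0.0 < vas < 100.0:
            raise ParameterError(f"can only invert VAS in (0, 100), got {vas}")
        return self.midpoint + float(logit(vas / 100.0)) / self._rate


def make_psychometric(midpoint: float, slope: float) -> Psychometric:
    return Psychometric(midpoint, slope)


def ltp_offset_schedule(
    n_trials: int,
    target_sd: float,
    max_offset: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Deterministic balanced temperature-offset schedule for the LTP group.

    Offsets come in +/- pairs (sample mean exactly 0) at equally spaced
    magnitude levels; a single shape parameter (the smallest level) is solved
    so the sample SD (n-1 denominator) equals ``target_sd`` without any
    |offset| exceeding ``max_offset``.  Pass the cohort RNG to shuffle the
    administration order.
    """
    if n_trials < 2 or n_trials % 2 != 0:
        raise ParameterError(f"n_trials must be even and >= 2, got {n_trials}")
    if target_sd < 0 or max_offset <= 0:
        raise ParameterError("target_sd must be >= 0 and max_offset > 0")
    if target_sd > max_offset:
        raise ParameterError(
            f"infeasible schedule: target_sd {target_sd} exceeds max_offset {max_offset}"
        )
    if target_sd == 0:
        return np.zeros(n_trials)

    m = n_trials // 2

    def levels(lam: float) -> np.ndarray:
        if m == 1:
            return np.array([1.0])
        return lam + (1.0 - lam) * np.arange(m) / (m - 1)

    def sd_at_unit_scale(lam: float) -> float:
        l = levels(lam)
        return math.sqrt(2.0 * float(np.sum(l * l)) / (n_trials - 1))

    if max_offset * sd_at_unit_scale(0.0) >= target_sd:
        lam, scale = 0.0, target_sd / sd_at_unit_scale(0.0)
    else:
        # raise the smallest levels until the SD is reachable at max_offset
        lam = optimize.brentq(
            lambda l: max_offset * sd_at_unit_scale(l) - target_sd, 0.0, 1.0, xtol=1e-15
        )
        scale = max_offset
    half = scale * levels(lam)
    schedule = np.concatenate([half, -half])
    if rng is not None:
        rng.shuffle(schedule)
    return schedule


_SQRT2 = math.sqrt(2.0)
_C_MILLS = math.sqrt(2.0 / math.pi)


def _truncnorm_moments(loc: float, scale: float, lo: float, hi: float) -> tuple[float, float]:
    """Mean and SD of N(loc, scale^2) truncated to [lo, hi].

    Closed form; one-sided far-tail cases go through erfcx so the normalising
    mass never underflows.
    """
    a = (lo - loc) / scale
    b = (hi - loc) / scale
    flip = False
    if b < 0:  # reflect so the hard tail is on the right
        a, b = -b, -a
        flip = True
    if a > 4.0:  # both bounds deep in the upper tail: Mills-ratio form
        e_delta = math.exp(-0.5 * (b - a) * (b + a)) if math.isfinite(b) else 0.0
        denom = erfcx(a / _SQRT2) - erfcx(b / _SQRT2) * e_delta
        d = _C_MILLS * (1.0 - e_delta) / denom  # (phi(a)-phi(b)) / Z
        t = _C_MILLS * (a - b * e_delta) / denom  # (a phi(a)-b phi(b)) / Z
    else:
        z = stats.norm._cdf(b) - stats.norm._cdf(a)
        pa, pb = stats.norm._pdf(a), stats.norm._pdf(b)
        d = (pa - pb) / z
        t = (a * pa - b * pb) / z
    var = scale * scale * (1.0 + t - d * d)
    mean = loc - scale * d if flip else loc + scale * d
    return mean, math.sqrt(max(var, 0.0))


def _bounded_normal_params(mu: float, sd: float, lo: float = 0.0, hi: float = 100.0):
    """(loc, scale) of a [lo, hi]-truncated normal with mean mu and SD sd."""
    a0, b0 = (lo - mu) / sd, (hi - mu) / sd
    if stats.norm._cdf(a0) + stats.norm._sf(b0) < 1e-7:
        return mu, sd  # truncation mass negligible (moment shift < 1e-5 VAS)

    def residual(p):
        loc, log_scale = p
        s = math.exp(log_scale)
        m, v = _truncnorm_moments(loc, s, lo, hi)
        return [m - mu, v - sd]

    sol = optimize.root(residual, [mu, math.log(sd)], method="hybr", tol=1e-12)
    if sol.success and max(abs(r) for r in residual(sol.x)) < 1e-8:
        return float(sol.x[0]), float(math.exp(sol.x[1]))

    # Near the bounds a truncated normal cannot reach SD/mean ratios much
    # above 1, so an exact joint match can be infeasible; match the mean
    # (the anchored quantity) and accept a mildly shrunken spread.
    loc = optimize.brentq(
        lambda l: _truncnorm_moments(l, sd, lo, hi)[0] - mu,
        mu - 12.0 * sd,
        mu + 12.0 * sd,
        xtol=1e-12,
    )
    return float(loc), sd


def _draw_ratings(
    rng: np.random.Generator, mu: float, sd: float, size: int, policy: str
) -> tuple[np.ndarray, float, float]:
    """Bounded rating draws; returns (samples, achieved_mean, achieved_sd).

    Under "resample" the achieved moments are the truncated normal's, equal to
    (mu, sd) whenever the joint match is feasible; under "clip" the nominal
    moments are reported (clipping biases them slightly near the bounds).
    """
    if policy == "clip":
        return np.clip(rng.normal(mu, sd, size), 0.0, 100.0), mu, sd
    loc, scale = _bounded_normal_params(mu, sd)
    a, b = (0.0 - loc) / scale, (100.0 - loc) / scale
    samples = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)
    achieved_mean, achieved_sd = _truncnorm_moments(loc, scale, 0.0, 100.0)
    return samples, achieved_mean, achieved_sd


def _center_offsets(psy: Psychometric, t30: float, offsets: np.ndarray, target: float) -> float:
    """Shift (degC) making the mean expected VAS over the jittered trials equal target."""

    def mean_vas(delta: float) -> float:
        return float(np.mean(psy(t30 + delta + offsets))) - target

    return optimize.brentq(mean_vas, -3.0, 3.0, xtol=1e-12)


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort.

    Returns ``(trials, ground_truth)``: a long trial table (one row per
    stimulus/rating event) and a per-subject table of generating parameters,
    including the prior/likelihood/posterior Gaussians the test-placebo
    ratings were drawn from.  Identical configs (same seed) give bit-identical
    tables.
    """
    rng = np.random.default_rng(config.seed)
    n_trials = config.trials_per_condition
    trial_rows: list[dict] = []
    truth_rows: list[dict] = []

    for group, n_subjects in (("HTP", config.n_htp), ("LTP", config.n_ltp)):
        n_bayes = int(round(config.fraction_bayes_subjects * n_subjects))
        generating = np.array(["bayes"] * n_bayes + ["null"] * (n_subjects - n_bayes))
        rng.shuffle(generating)
        for i in range(n_subjects):
            subject_id = f"{group}{i + 1:03d}"
            midpoint = rng.uniform(*config.psychometric_midpoint_range)
            slope = rng.uniform(*config.psychometric_slope_range)
            noise_sd = rng.uniform(*config.rating_noise_sd_range)
            psy = Psychometric(midpoint, slope)
            t30 = psy.invert(config.vas_cond_placebo_mean)
            t70 = psy.invert(config.vas_cond_control_mean)
            t50 = psy.invert(config.vas_test_mean)

            # conditioning placebo temperatures: constant for HTP, jittered for
            # LTP with the mean *rating* (not temperature) pinned to the anchor
            if group == "HTP":
                cond_placebo_temps = np.full(n_trials, t30)
            else:
                offsets = ltp_offset_schedule(
                    n_trials, config.ltp_temp_sd, config.ltp_temp_max_offset, rng=rng
                )
                delta = _center_offsets(psy, t30, offsets, config.vas_cond_placebo_mean)
                cond_placebo_temps = t30 + delta + offsets

            cond_placebo_levels = np.asarray(psy(cond_placebo_temps), dtype=float)

            def emit(phase, condition, temps, vas):
                for j in range(n_trials):
                    trial_rows.append(
                        {
                            "subject_id": subject_id,
                            "group": group,
                            "phase": phase,
                            "condition": condition,
                            "trial": j + 1,
                            "temperature_c": float(temps[j]),
                            "vas": float(vas[j]),
                        }
                    )

            # conditioning placebo: draw per stimulus level, tracking the
            # achieved per-trial noise SD (bounding can shrink it for extreme
            # level/noise combinations); the ground-truth prior records the
            # moments of the distribution the ratings actually come from
            if np.ptp(cond_placebo_levels) == 0:
                vas, _, trial_sd = _draw_ratings(
                    rng, float(cond_placebo_levels[0]), noise_sd, n_trials,
                    config.truncation_policy,
                )
                trial_vars = np.full(n_trials, trial_sd**2)
            else:
                vas = np.empty(n_trials)
                trial_vars = np.empty(n_trials)
                for j, level in enumerate(cond_placebo_levels):
                    draws, _, trial_sd = _draw_ratings(
                        rng, float(level), noise_sd, 1, config.truncation_policy
                    )
                    vas[j] = draws[0]
                    trial_vars[j] = trial_sd**2
            emit("conditioning", "placebo", cond_placebo_temps, vas)

            prior_mu = float(np.mean(cond_placebo_levels))
            prior_sd = math.sqrt(float(np.var(cond_placebo_levels)) + float(np.mean(trial_vars)))
            true_prior = GaussianParams(prior_mu, prior_sd)
            true_like = GaussianParams(config.vas_test_mean, noise_sd)
            null_prior = GaussianParams(config.vas_cond_control_mean, noise_sd)
            gen_model = generating[i]
            gen_prior = true_prior if gen_model == "bayes" else null_prior
            true_posterior = integrate(gen_prior, true_like)

            for phase, condition, temps, mu, sd in (
                ("conditioning", "control", np.full(n_trials, t70),
                 config.vas_cond_control_mean, noise_sd),
                ("test", "control", np.full(n_trials, t50), config.vas_test_mean, noise_sd),
                ("test", "placebo", np.full(n_trials, t50),
                 true_posterior.mu, true_posterior.sigma),
            ):
                vas, _, _ = _draw_ratings(rng, mu, sd, n_trials, config.truncation_policy)
                emit(phase, condition, temps, vas)

            truth_rows.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "t50_c": midpoint,
                    "slope_vas_per_c": slope,
                    "rating_noise_sd": noise_sd,
                    "prior_mu": true_prior.mu,
                    "prior_sigma": true_prior.sigma,
                    "gen_prior_mu": gen_prior.mu,
                    "gen_prior_sigma": gen_prior.sigma,
                    "like_mu": true_like.mu,
                    "like_sigma": true_like.sigma,
                    "posterior_mu": true_posterior.mu,
                    "posterior_sigma": true_posterior.sigma,
                    "generating_model": gen_model,
                }
            )

    return pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS), pd.DataFrame(truth_rows)
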