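# Methods

## Model

Each subject contributes four cells of 12 visual-analogue-scale (VAS, 0–100)
pain ratings: conditioning × {placebo, control} and test × {placebo, control}.
Three Gaussian summaries are fitted by maximum likelihood:

- **prior** — conditioning-phase placebo (treated) ratings; the treatment
  expectation (integration model), or conditioning-phase control ratings
  (null model, encoding no treatment-experience influence);
- **likelihood** — test-phase control ratings; the incoming nociceptive
  evidence under the identical test stimulus.

The predicted treated percept is the normalised product of prior and
likelihood densities: precision-weighted mean, summed precisions. The
attraction weight w_prior = σ²_like/(σ²_prior + σ²_like) is computed in
variance space, which is algebraically identical to the precision form but
cannot overflow when a floored σ makes a raw precision huge.

### Model evidence

The test-phase placebo ratings X are modelled as i.i.d. N(μ, σ²_obs) with the
rating mean μ uncertain and distributed as the model's integrated posterior
N(μ_M, σ²_M). Marginalising μ gives X ~ N(μ_M·1, σ²_obs·I + σ²_M·11ᵀ), whose
log density we evaluate in the centred, log1p form

    log p = −n/2·log(2π σ²_obs) − 1/2·log(1 + n σ²_M/σ²_obs)
            − SS/(2σ²_obs) − n(x̄ − μ_M)²/(2(σ²_obs + n σ²_M))

(x̄ the sample mean, SS the centred sum of squares). This is algebraically
identical to the expanded conjugate-integral expression but stable for very
small or very large σ_M; the test suite checks it against adaptive quadrature
and a multivariate-normal density to relative 1e-6.

Choices the conjugate form leaves open, with our defaults (both switchable):

- **σ_obs** is the n−1 sample SD of the subject's test-placebo ratings,
  shared by both models so that the comparison isolates the prior;
- **(μ_M, σ_M)** is each model's *posterior* (not its prior) — the model's
  actual prediction of the treated test percept.

Bayes factors are formed in log space; posterior model probabilities use
equal model priors, p(Bayes|X) = BF₁₀/(BF₁₀+1) = logistic(log BF₁₀).
Displayed Bayes factors are capped at exp(±700) to stay finite; counts and
comparisons always use log evidence. The positive evidence ratio counts
subjects with BF₁₀ strictly above 3 against subjects with BF₀₁ strictly
above 3; with zero subjects in the denominator it is reported as undefined
with the counts preserved, never as infinity.

### Random-effects model selection

Group-level inference uses the variational Dirichlet scheme standard for
random-effects Bayesian model selection: responsibilities
u_nk ∝ exp(log-evidence_nk + ψ(α_k) − ψ(Σα)) and concentration updates
α = α₀ + Σ_n u_n, iterated until the maximum absolute α change falls below
1e-8 (cap 10,000 iterations; the result carries a `converged` flag). The
prior is uniform (α₀ = 1 per model). Expected model probabilities are
α/Σα. Exceedance probabilities — the posterior probability that a model is
the most frequent — are exact for two models via the Beta tail
P(Beta(α₁, α₂) > 1/2), avoiding sampling noise in the headline quantity; for
three or more models a seeded Dirichlet Monte-Carlo sampler (10⁶ draws by
default) is used, and the sampler doubles as the test oracle for the
two-model closed form.

## Gaussian fitting

`fit_gaussian` maximises the Gaussian log-likelihood with a Nelder–Mead
simplex on (μ, log σ) initialised at the closed-form ML estimates (sample
mean; SD with the n denominator, the estimate the likelihood itself
maximises). The simplex result is accepted only if it improves on the
analytic start beyond floating-point noise, so fitted values agree with the
closed form to much better than 1e-6 whenever the optimum respects the
σ floor. The floor (default 0.5 VAS) guards all-identical rating series —
possible for constant-temperature subjects — and floored fits carry a
`degenerate` flag through every downstream table.

Two SD conventions coexist deliberately: fitting uses n (matching the
likelihood), descriptive behavioral statistics use n−1 (standard reporting).
They are never mixed within one statistic.

## Synthetic cohorts

The generator emulates the two-group conditioning/test design so the full
pipeline, including parameter recovery, runs without any external data.
Defaults are the study conditions: 31 subjects per group, 12 trials per
condition per phase, VAS anchors 30 (conditioning placebo), 70 (conditioning
control), 50 (test).

- **Psychometric function.** Temperature → expected VAS is logistic with
  per-subject midpoint (uniform 44–46 °C) and midpoint slope (uniform 30–45
  VAS/°C). Logistic is chosen for closed-form inversion; the slope range
  makes the VAS-30→70 temperature span 0.94–1.41 °C, bracketing the ~1.1 °C
  group-mean calibration span of the emulated design.
- **Precision manipulation.** HTP subjects receive their VAS-30 temperature
  on every conditioning-placebo trial. LTP subjects receive a deterministic
  balanced offset schedule: ± paired magnitude levels, equally spaced, with
  the smallest level raised (one shape parameter, solved by bisection) until
  the sample SD (n−1) equals 0.55 °C under the 0.8 °C cap; administration
  order is shuffled by the cohort RNG. A deterministic schedule is used
  because the design specifies an exact SD and range for 12 trials, which a
  small i.i.d. sample would miss. The schedule is centred so that the *mean
  expected rating* (not the mean temperature) equals the VAS-30 anchor,
  compensating for the logistic's curvature.
- **Rating noise.** Per-subject noise SD is uniform on 9–18 VAS, putting the
  HTP group-mean conditioning-placebo rating SD near 13.5 and the implied
  LTP mean (temperature jitter mapped through the psychometric slope, plus
  noise) near 22 — matching the variability levels the design aims for.
- **Bounded scale.** Ratings live in [0, 100]. The default "resample" policy
  draws from a truncated normal whose location and scale are solved (hybrid
  Newton on closed-form truncated-normal moments) so the realized mean and
  SD equal the design values; where the joint match is infeasible (a
  truncated normal cannot exceed an SD/mean ratio of ~1 near a bound) the
  mean alone is matched and the spread shrinks slightly. The ground-truth
  table records the *achieved* moments, so parameter-recovery comparisons
  are exact. A "clip" policy (simple clamping) is available; it slightly
  biases moments near the bounds and ground truth then records nominal
  values.
- **Generating models.** Each subject's test-placebo ratings are drawn from
  the integrated posterior of their generating model — Bayesian
  (conditioning-placebo prior) by default, or null for a configurable
  fraction of subjects (a 0.9 preset mimics cohort heterogeneity). The
  stored ground-truth posterior is exactly `integrate(prior, likelihood)`
  under the generating prior, to 1e-12.

Identical seeds give bit-identical tables. What passing tests on these
cohorts do *not* show: real rating distributions are not exactly Gaussian or
symmetric, real subjects drift, habituate and anchor their ratings, noise
need not be identical across phases, and the mapping from temperature jitter
to rating variability depends on psychometric slopes that vary more than the
configured ranges. The synthetic analogs of the behavioral statistics
(correlations, regression coefficients) therefore check signs, orderings and
qualitative magnitudes, not the empirical values from any real cohort.

## Behavioral statistics

The observed placebo effect is mean(test control) − mean(test placebo).
Sub-sample selection flags subjects in whom the manipulation took hold:
HTP kept when the conditioning-placebo rating variance (n−1) is strictly
below 384.08 VAS² (SD 19.60), LTP kept when strictly above 194.90 VAS²
(SD 13.96); the operation only flags rows and alters no data. Correlations
are Pearson product-moment with two-sided t-based p values; the precision
regression is OLS of the observed effect on σ_prior and σ_like with an
intercept, reporting both unstandardized coefficients (the
prediction-equation scale) and standardized betas, since "β" notation is
ambiguous between the two. No multiple-testing correction is applied. The
condition × group mixed-effects tests are deliberately out of scope; the
pipeline exports a tidy long-format table so any standard tool can fit them.

## Pipeline

`run_pipeline` executes simulate (or load) → fit → integrate → evidence →
RFX → stats, writes every intermediate table, and records a manifest
(config, seeds, package version, SHA-256 of every output); identical
config + seed reproduce identical hashes, and the manifest alone suffices to
re-derive every file. The covariate export (w_prior, μ_prior, log σ_prior —
natural log — and P(Bayes)) is tab-separated with optional mean-centering.

## Problem sizes

The bundled checks use the design-scale cohort (62 subjects × 48 trials) for
the model-selection and behavioral analogs, 200-subject groups for
law-of-large-numbers checks on the generator, and 200 trials/condition for
parameter recovery (recovery bias bound: 0.5 VAS). Oracle-equivalence suites
use 100–1000 random instances per closed form at relative tolerance 1e-6 and
10⁶ Monte-Carlo draws for the exceedance cross-check.

## Known limitations

- The marginal-likelihood comparison conditions on point estimates of each
  model's posterior; uncertainty in the fitted σ's is not propagated.
- σ_obs is estimated from the same 12 ratings the evidence is evaluated on;
  with so few trials the Bayes factors are themselves noisy, which the
  random-effects layer (not the per-subject factors) is meant to absorb.
- Exceedance probabilities for K > 2 models are Monte-Carlo estimates;
  protected exceedance probabilities and the Bayesian omnibus risk are not
  implemented.
- The generator's Gaussian-with-bounds rating model is a deliberate
  idealisation (see above).
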