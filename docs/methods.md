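# Methods

## Model

For grouped binary data with covariate patterns `x_i`, successes `y_i`
and trials `m_i`, all models here have the form
`Pr(success | x_i) = mu_i = g^{-1}(eta_i; shape)`, `eta_i = x_i' beta`,
and the Bernoulli-form grouped log-likelihood

```
l(beta, shape) = sum_i [ y_i log mu_i + (m_i - y_i) log(1 - mu_i) ].
```

No binomial coefficient is included. This normalization matters only
for absolute comparisons: AIC and BIC are computed from this `l`, and
BIC's sample size is the total number of individuals (`sum m_i`), not
the number of patterns. These two conventions are the ones under which
the package's information criteria reproduce the published comparison
tables for the embedded datasets.

The Weibull link `mu = 1 - exp(-eta^gamma)` requires `eta > 0`; the
intercept absorbs the Weibull location/threshold, which avoids a
separate unidentifiable location parameter. Its skewness is a function
of `gamma` alone — moment skewness
`(G3 - 3 G2 G1 + 2 G1^3)/(G2 - G1^2)^{3/2}` with `Gj = Gamma(1 + j/gamma)`,
range `(-1.1395, inf)`; Arnold–Groeneveld (mode) skewness
`2 exp((1-gamma)/gamma) - 1`, range `(2/e - 1, inf)` — and its
large-`gamma` rescaled limit is the complementary log–log link. The
reflected link `mu = exp(-eta^gamma)` is stored as a *decreasing* link;
no sign flip of `eta` is applied, so its loglog-type limit is likewise
decreasing.

### Link catalog

All competing links follow their standard definitions (logit; probit;
cloglog; loglog `exp(-e^eta)`, decreasing; Aranda–Ordaz power-logit;
Stukel two-tail `h`-transform; Prentice Beta-cdf-of-logistic;
skew-probit). Two deliberate choices:

* **Skew-probit** uses the direct skew-normal parameterization
  (location 0, scale 1, slant `delta/sqrt(1-delta^2)`, `delta` in
  (−1, 1)). The mean-zero/unit-variance *centered* convention differs
  only by an affine map of `eta`, which the regression coefficients
  absorb; the shape parameter's interpretation shifts accordingly.
* **AEP** is the two-piece exponential-power cdf with mass 1/2 per
  side: for `eta <= 0`,
  `F(eta) = Q(1/theta1, (-2 eta Gamma(1+1/theta1))^theta1) / 2`
  (`Q` the regularized upper incomplete gamma), symmetrically above
  zero. In this normalization the density is simply
  `exp(-(2|eta|Gamma(1+1/theta))^theta)` on each side, continuous with
  `f(0) = 1`; `theta1 = theta2 = 1` is the Laplace cdf. Quantiles come
  from the inverse incomplete-gamma, so the forward link is closed-form.

Probabilities are clipped to `[1e-300, 1 - 1e-16]` before logs; for the
Weibull pair, cloglog and loglog the `log(1-mu)` (resp. `log mu`) terms
use their exact complements (`-eta^gamma`, `-e^eta`) instead of clipped
differences, which keeps the likelihood honest deep in the tails where
`1 - mu` underflows.

## Maximum likelihood

* Points with any `eta_i <= 0` under the Weibull pair receive the
  exterior penalty `-1e10 - 1e6 * sum max(0, -eta_i)` instead of an
  error, so Nelder–Mead recovers from boundary excursions.
* Initialization (Weibull pair): slopes from a probit fit (statsmodels
  GLM), intercept shifted so `min_i eta_i = 0.001`, shape seed 3.60235
  (the shape at which the Weibull cdf best mimics a standard normal).
  The reflected link runs the probit step on failures, via the identity
  `rweibull-fit(y) = weibull-fit(m - y)`. If the probit fit fails
  (separation), slopes start at zero with intercept 0.001.
* Optimization: shape parameters are transformed to an unconstrained
  scale (log for positive, atanh for interval-bounded); Nelder–Mead is
  restarted until the loglik gain drops below 1e-8 (three shape starts
  `{3.60235, 1, 0.25}` for the Weibull pair — the likelihood in `gamma`
  can be multimodal-flat, and the snail stage-1 optimum sits near
  `gamma = 0.17`); smooth families get a BFGS pre-pass. Weibull-pair
  solutions are then polished by damped Newton–Raphson on the analytic
  score/Hessian (derived by the chain rule through `t_i = eta_i^gamma`
  and validated against central finite differences at 1e-5 relative
  tolerance).
* Convergence is declared on the log-likelihood, not on the parameters:
  on both embedded datasets the likelihood is nearly flat in large
  `gamma` (the cloglog limit), so the fitted `gamma` itself is
  ill-determined while the fit, fitted probabilities and selection
  statistics are stable. Reported shape estimates in that regime should
  be read as "effectively the limiting link".
* Standard errors are square roots of the diagonal of the inverse
  negative observed information (analytic Hessian for the Weibull pair,
  central differences otherwise, with finite-difference steps kept
  inside the shape space). A singular information yields absent (NaN)
  standard errors with a warning, never zeros.

## Bayesian estimation

Single-site random-walk Metropolis within Gibbs on each coefficient and
each transformed shape parameter (log-scale proposals for `gamma`, with
the Jacobian in the target). Proposal scales adapt every 100 burn-in
iterations toward a 20–50% acceptance band and freeze afterwards, so
the post-burn-in chain targets the exact posterior. Chains are
bit-reproducible given the seed; ergodic means are retained for
convergence monitoring, and a block that rejects every proposal after
adaptation raises a diagnostic error.

* Hierarchical prior: `gamma ~ Gamma(mean m_g, variance v_g)`
  (internally shape `m_g^2/v_g`, rate `m_g/v_g`),
  `beta ~ N(m_b, v_b I)`. Empirical Bayes estimates `(m_g, m_b)` by
  Monte-Carlo EM: the E-step is an MCMC run at the current hyper-means;
  the Gaussian M-step is the posterior draw mean (closed form); the
  gamma-mean M-step maximizes the Monte-Carlo Q-function by a 1-D
  bounded search, since the fixed-variance gamma family has no
  closed-form mean update. Iteration stops at relative change 1e-3 or
  50 iterations; the result inherits Monte-Carlo noise of order the
  E-step's standard error, so hyper-means should be quoted to about two
  significant figures.
* Non-informative prior: `p(beta, gamma) ∝ 1/gamma^c` on `gamma > 1`,
  `c > 1` (default `c = 2`). Restricting `gamma > 1` caps the link
  skewness at 2. Posterior propriety holds whenever the signed design
  rows overlap; `separation_check` decides this exactly by linear
  programming (feasibility of `X*'a = 0, a >= 1` over the observed
  success/failure cells) and returns the feasible `a` as a certificate.
* DIC is `2 E[deviance] - deviance(E[parameters])`; if the
  posterior-mean parameters are inadmissible (Weibull `eta <= 0`), the
  plug-in term falls back to the posterior median with a warning. The
  marginal likelihood `Pr(D|M)` uses the harmonic-mean estimator via
  log-sum-exp, with a warning when one draw contributes more than 99%
  of the harmonic sum (the estimator's infinite-variance failure mode).
  Because of that instability the package reports the log marginal
  likelihood for Bayes-factor differences only and does not attach an
  absolute interpretation to its scale.
* For ridge-shaped near-flat posteriors (large-`gamma` Weibull fits),
  initialize the chain at the MLE: the single-site sampler mixes along,
  but does not traverse, the curved flat ridge in `(beta, gamma)`.

## Multinomial continuation partition

Ordered categories `1..K` are fitted as K−1 nested binomial stages:
stage k models category k against categories k..K, with successes
`s_k` and trials `sum_{l>=k} s_l` per pattern (patterns with no
remaining subjects drop out of that stage). The multinomial likelihood
factorizes exactly into the product of the stage likelihoods, so stages
are fitted independently, possibly with different links or covariates.
Back-transformation `p_1 = theta_1`,
`p_k = theta_k prod_{l<k}(1-theta_l)`,
`p_K = prod_{l<K}(1-theta_l)` yields a probability vector that sums to
one by construction. The category order defines the partition; it is
part of the model specification and never rearranged.

## Selection statistics

KS and MAE compare *group-level* frequencies: per-pattern observed
proportion versus fitted probability (binomial), or per
pattern-by-category relative frequency (multinomial). The Brier score
and the log-likelihood are *individual-level*, computed in grouped
form. This split is deliberate and is the only convention consistent
with both embedded analyses; mixing levels changes KS/MAE by an order
of magnitude.

## Analytic properties

* The moment-skewness infimum is found by bounded 1-D minimization over
  `log gamma` in `[log 0.5, log 1e8]`, with the gamma functions
  evaluated in arbitrary precision (mpmath, 40 digits): in float64 the
  central-moment differences cancel catastrophically beyond
  `gamma ~ 1e4`. The skewness decreases monotonically to the Gumbel
  limit `-12 sqrt(6) zeta(3) / pi^3 = -1.13955`, so the infimum is
  attained at the search boundary.
* Approximation distances are sup-norms on a 100,001-point uniform grid
  over the region where both curves lie in `[1e-6, 1 - 1e-6]` (the
  quoted figures depend mildly on this range, hence it is fixed here).
  Probit/logit use the published affine constants
  `(0.90114, 0.27787, 3.60235)` and `(0.89864, 0.16957, 3.50215)`.
  For cloglog/loglog only the shape values (21.03, 114.45) are
  documented; the affine `eta`-map is optimized here, which gives gaps
  at least as small as the quoted 0.0082/0.0031 — those two figures are
  therefore reproduced as upper bounds, not point targets.
* `cloglog_limit_gap` evaluates the Proposition-style rescaled form
  `1 - exp(-(1 + eta/gamma)^gamma)` on `eta in [-5, 5]`; the gap to
  cloglog decreases monotonically to zero and both sides coincide
  exactly at `eta = 0`.

## Synthetic data

`simulate(SyntheticSpec(...))` draws grouped binomial data with
`p = g^{-1}(X beta; shape)` per pattern, or a K-category dataset via the
continuation cascade (stage-by-stage binomial thinning), fully
determined by the seed. Defaults (20-pattern dose grid, 100 trials per
pattern) emulate a designed bioassay: balanced patterns, exact link
form, no overdispersion, no covariate measurement error, no missing
cells. Passing recovery tests on these data therefore demonstrates
correctness of the estimators under the model, not robustness to the
misspecifications real assay data may carry. Recovery tests use
`beta = (0.2, 0.75)`, `gamma = 2`, 250 trials x 20 patterns (n = 5,000),
chosen so the fitted probabilities sweep most of (0, 1) — a
well-conditioned design where 3-standard-error recovery is a meaningful
check.

## Problem sizes and tolerances

The test suite and the acceptance script run the full embedded datasets
(818 and 4,800 individuals — the studies are small by design) and
moderate MCMC lengths (4,000–20,000 retained draws), sizes at which the
deterministic results are exact to optimizer tolerance (1e-8 on the
log-likelihood) and the stochastic checks have comfortable margins
(DIC band of ±7.5 around the reference value across five seeds).

## Known limitations

* The fitted `gamma` (and its standard error) is unstable whenever the
  data prefer the limiting cloglog regime; compare models on the
  log-likelihood and fitted probabilities, not on `gamma`.
* The harmonic-mean marginal likelihood is variance-unstable by nature;
  it is included for completeness and flagged when unreliable.
* Shape-parameter gradients for the Prentice, skew-probit and AEP links
  are finite-difference, not analytic.
* The continuation partition is order-dependent; it does not implement
  baseline-category multinomial logit or proportional-odds structure.
* `empirical_bayes_hyperparams` inherits MCMC noise; it reports
  hyper-means, not a full hyperposterior.
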