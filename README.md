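# skewlink

Skewed Weibull-link regression for binomial and multinomial categorical
responses.

## The problem

In binary regression the link function decides how fast the success
probability approaches 0 versus 1 along the covariate axis. The classical
logit and probit links are symmetric; when the two tails behave
differently — common in dose–response bioassays and toxicology — a skewed
link fits better. `skewlink` implements the **Weibull link**

```
mu = g^{-1}(eta) = 1 - exp(-eta^gamma),     eta = x'beta > 0,  gamma > 0,
```

whose skewness is carried entirely by the shape parameter `gamma`: the
moment skewness sweeps `(-1.1395, +inf)` (2 at `gamma = 1`, zero near
`gamma = 3.6`, the Gumbel limit `-1.1395` as `gamma -> inf`), and the
complementary log–log link is the limiting case
`lim_{gamma->inf} 1 - exp(-(1 + eta/gamma)^gamma) = 1 - exp(-e^eta)`.
The reflected variant `mu = exp(-eta^gamma)` covers left skew. Affine
recalibrations of the Weibull cdf approximate the probit link to sup-norm
0.0078 and the logit link to 0.0148, so the family effectively nests the
standard symmetric links too.

The package provides, for grouped binomial data (one row per covariate
pattern with success/trial counts):

* **Maximum likelihood** under the Weibull link (analytic score and
  Hessian, probit-based initialization, Nelder–Mead with Newton polish)
  and under a catalog of competitors: logit, probit, cloglog, loglog,
  Aranda–Ordaz, Stukel, Prentice, skew-probit, and the asymmetric
  exponential power (AEP) link.
* **Bayesian estimation** by Metropolis-within-Gibbs, with a
  hierarchical gamma/normal prior whose hyper-means can be estimated by
  Monte-Carlo EM (empirical Bayes), or a non-informative
  `p(beta, gamma) ∝ 1/gamma^c` prior whose posterior propriety is
  certified by an exact linear-programming overlap (separation) check.
* A **continuation partition** for K-category multinomial responses:
  `p_1 = theta_1`, `p_k = theta_k * prod_{l<k}(1 - theta_l)` factorizes
  the multinomial likelihood into K−1 independent binomial fits, each
  under any link, back-transformed to a category-probability surface.
* **Model-selection statistics**: AIC, BIC, DIC, the group-frequency KS
  and MAE, the individual-level Brier score, and the harmonic-mean
  marginal-likelihood estimator.

Two classic datasets ship as embedded fixtures: a poison-potency
bioassay (17 dose/poison patterns, 818 insects) and a snail
gamma-irradiation study with a four-level DNA-damage response
(5 doses, 4,800 snails).

## Worked example

```python
>>> import skewlink as sk
>>> poison = sk.load_poison()          # 17 patterns, 818 insects
>>> res = sk.BinomialLinkModel(poison, link="weibull").fit()
>>> round(res.llf, 2)
-370.33
>>> st = res.selection_stats()
>>> round(st.aic, 2), round(st.ks, 4), round(st.mae, 4)
(750.66, 0.1451, 0.0551)
```

The Weibull fit edges out the symmetric links (logit `-373.41`, probit
`-372.57`) and lands within rounding of the cloglog fit (`-370.33`) with
a very large fitted `gamma` — the likelihood is nearly flat in `gamma`
there, which is exactly the cloglog-limit behaviour the model predicts.

The multinomial analysis, with the reflected Weibull per stage:

```python
>>> snail, _ = sk.load_snail()
>>> mfit = sk.ContinuationModel(snail, link="rweibull").fit()
>>> round(mfit.llf, 2)
-5654.19
>>> mfit.category_probabilities([[1.0, 0.0, 0.0]]).round(3)  # dose 0
array([[0.595, 0.12 , 0.065, 0.22 ]])
```

i.e. at dose 0 an estimated 59.5% of snails show no DNA damage and 22.0%
high damage; the fitted surface tracks the observed within-dose
frequencies to a maximum cell gap (KS) of 0.030.

A Bayesian fit of the same binary model:

```python
>>> import numpy as np
>>> prior = sk.PriorSpec.hierarchical(9.1089, 100.0,
...     np.array([0.1588, 0.8879, 0.1261, -0.1717]), 25.0)
>>> post = sk.mcmc_sample(poison, "weibull", prior,
...                       n_draws=6000, burn_in=3000, seed=1)
>>> round(sk.dic(post, poison, "weibull"), 1)
752.4
```

There is also a CLI (`skewlink fit`, `fit-multinomial`, `bayes`,
`compare`, `simulate`, `properties`, `fixtures export`); run
`skewlink --help`.

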