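"""skewlink: skewed Weibull-link regression for categorical responses.

Binary and multinomial regression with a catalog of parametric link
functions centered on the Weibull link mu = 1 - exp(-eta**gamma), whose
shape parameter carries the skewness and whose large-gamma limit is the
complementary log-log link.  Provides maximum-likelihood and Bayesian
(Metropolis-within-Gibbs, hierarchical / empirical-Bayes priors)
estimation, a continuation partition reducing K-category multinomial
regression to K-1 binomial fits, and the usual model-selection
statistics (AIC, BIC, DIC, KS, MAE, Brier, harmonic-mean marginal
likelihood).
"""

from .links import (
    LinkSpec,
    LinkError,
    EtaDomainError,
    ShapeConstraintError,
    get_link,
    available_links,
)
from .data import (
    GroupedBinomialData,
    GroupedMultinomialData,
    SyntheticSpec,
    load_poison,
    load_snail,
    read_binomial_csv,
    read_multinomial_csv,
    simulate,
)
from .model import (
    BinomialLinkModel,
    BinomialLinkResults,
    fit_mle,
    initial_guess,
    log_likelihood,
    score_and_hessian,
    standard_errors,
)
from .multinomial import (
    ContinuationModel,
    ContinuationResults,
    category_probabilities,
    fit_multinomial,
    partition_multinomial,
)
from .bayes import (
    PriorSpec,
    PosteriorSample,
    dic,
    empirical_bayes_hyperparams,
    log_marginal_likelihood,
    log_posterior,
    mcmc_sample,
    separation_check,
)
from .selection import SelectionStats, aic_bic, brier_score, compare, ks_mae
from . import properties

__version__ = "0.1.0"


def _fit_bayes(self, prior, **kwargs):
    """Sample the posterior of this model; see :func:`skewlink.mcmc_sample`."""
    return mcmc_sample(self.data, self.link, prior, **kwargs)


BinomialLinkModel.fit_bayes = _fit_bayes
del _fit_bayes
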