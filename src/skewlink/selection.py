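"""Comparison statistics for fitted categorical regressions.

Conventions (the only ones consistent with the worked analyses):

* ``aic``/``bic`` are computed from the Bernoulli-form log-likelihood,
  with BIC's sample size the total number of INDIVIDUALS (818 insects,
  4,800 snails), not the number of covariate patterns;
* KS and MAE compare GROUP-level frequencies — one observed proportion
  against one fitted probability per covariate pattern (binomial), or
  one relative frequency per pattern-by-category cell (multinomial);
* the Brier score averages squared errors over INDIVIDUAL outcomes,
  computed in grouped form.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["SelectionStats", "aic_bic", "ks_mae", "brier_score",
           "stats_for_binomial_fit", "stats_for_multinomial_fit", "compare"]


@dataclass
class SelectionStats:
    loglik: float
    aic: float
    bic: float
    ks: float
    mae: float
    brier: float
    n_params: int
    n_individuals: int
    dic: float = None
    log_pr_d_m: float = None

    def to_dict(self):
        return {k: v for k, v in asdict(self).items() if v is not None}


def aic_bic(loglik: float, n_params: int, n_individuals: int):
    """AIC = -2 l + 2 k and BIC = -2 l + k log(N), N = total individuals."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + n_params * np.log(n_individuals)
    return aic, bic


def ks_mae(observed_freqs, fitted_freqs):
    """Max and mean absolute gap between observed and fitted frequencies.

    The inputs are group-level cells: per-pattern proportions for a
    binomial fit, per pattern-by-category relative frequencies for a
    multinomial fit.  Both statistics are invariant to cell order and
    satisfy KS >= MAE.
    """
    obs = np.ravel(np.asarray(observed_freqs, dtype=float))
    fit = np.ravel(np.asarray(fitted_freqs, dtype=float))
    if obs.shape != fit.shape:
        raise ValueError("observed and fitted frequency vectors differ in length")
    gap = np.abs(obs - fit)
    return float(gap.max()), float(gap.mean())


def brier_score(counts, fitted_probs, trials=None) -> float:
    """Mean squared error of predicted probabilities at the individual level.

    Binomial (1-d inputs): (1/N) sum_i [ y_i (1-p_i)^2 + (m_i-y_i) p_i^2 ].
    Multinomial (2-d inputs): (1/N) sum over individuals and categories of
    (indicator - p_k)^2, evaluated in grouped form.
    """
    counts = np.asarray(counts, dtype=float)
    P = np.asarray(fitted_probs, dtype=float)
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("fitted probabilities must lie in [0, 1]")
    if counts.ndim == 1:
        if trials is None:
            raise ValueError("binomial form requires trials")
        m = np.asarray(trials, dtype=float)
        N = m.sum()
        return float(np.sum(counts * (1.0 - P) ** 2 + (m - counts) * P ** 2) / N)
    m = counts.sum(axis=1)
    N = m.sum()
    # each subject in category k contributes (1-p_k)^2 + sum_{j != k} p_j^2
    per_cell = counts * (1.0 - P) ** 2 + (m[:, None] - counts) * P ** 2
    return float(per_cell.sum() / N)


def stats_for_binomial_fit(fit, dic=None, log_pr_d_m=None) -> SelectionStats:
    """Assemble the comparison table row for a fitted binomial model."""
    data = fit.model.data
    p_hat = fit.predict()
    ks, mae = ks_mae(data.proportions, p_hat)
    aic, bic = aic_bic(fit.llf, fit.n_params, data.n_individuals)
    return SelectionStats(
        loglik=fit.llf, aic=aic, bic=bic, ks=ks, mae=mae,
        brier=brier_score(data.successes, p_hat, data.trials),
        n_params=fit.n_params, n_individuals=data.n_individuals,
        dic=dic, log_pr_d_m=log_pr_d_m,
    )


def stats_for_multinomial_fit(fit) -> SelectionStats:
    """Comparison row for a continuation-partition multinomial fit."""
    data = fit.data
    P = fit.fitted_category_probabilities()
    ks, mae = ks_mae(data.relative_frequencies, P)
    aic, bic = aic_bic(fit.llf, fit.n_params, data.n_individuals)
    return SelectionStats(
        loglik=fit.llf, aic=aic, bic=bic, ks=ks, mae=mae,
        brier=brier_score(data.counts, P),
        n_params=fit.n_params, n_individuals=data.n_individuals,
    )


def compare(named_stats) -> "pandas.DataFrame":
    """Build a comparison table from {model name: SelectionStats}."""
    import pandas as pd

    rows = {name: s.to_dict() for name, s in named_stats.items()}
    df = pd.DataFrame(rows).T
    return df.sort_values("aic")
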