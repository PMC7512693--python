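"""Continuation partition of a K-category multinomial regression.

A K-category response with ordered categories factorizes through the
reparameterization

    p_1 = theta_1,   p_k = theta_k * prod_{l<k} (1 - theta_l),
    p_K = prod_{l<K} (1 - theta_l),

under which the multinomial likelihood is the product of K-1 independent
binomial likelihoods: stage k models membership in category k among
subjects not in categories 1..k-1.  Each stage may use any registered
link; the fitted stage probabilities back-transform to a category
probability surface that sums to one by construction.

The category order is part of the model: the partition depends on it
and no reordering is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import GroupedBinomialData, GroupedMultinomialData
from .links import get_link
from .model import BinomialLinkModel, BinomialLinkResults

__all__ = [
    "partition_multinomial",
    "fit_multinomial",
    "category_probabilities",
    "ContinuationModel",
    "ContinuationResults",
]


def partition_multinomial(data: GroupedMultinomialData):
    """Split K-category counts into K-1 nested binomial sub-datasets.

    Stage k has successes = category-k count and trials = count of
    categories k..K at each pattern; patterns with zero stage-k trials
    are dropped from that stage (they carry no information about
    theta_k).
    """
    subs = []
    for k in range(data.K - 1):
        trials = data.counts[:, k:].sum(axis=1)
        keep = trials > 0
        if not np.any(keep):
            warnings.warn(f"stage {k + 1}: no subjects remain; stage skipped")
            subs.append(None)
            continue
        subs.append(
            GroupedBinomialData(
                data.X[keep], data.counts[keep, k], trials[keep], names=list(data.names)
            )
        )
    return subs


def category_probabilities(theta) -> np.ndarray:
    """Back-transform stage probabilities to category probabilities.

    ``theta`` has K-1 columns; the result has K columns that sum to one
    exactly: p_k = theta_k * prod_{l<k}(1 - theta_l), with the final
    category taking the remaining mass.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    surv = np.cumprod(1.0 - theta, axis=1)
    p = np.empty((theta.shape[0], theta.shape[1] + 1))
    p[:, 0] = theta[:, 0]
    p[:, 1:-1] = theta[:, 1:] * surv[:, :-1]
    p[:, -1] = surv[:, -1]
    return p


@dataclass
class ContinuationResults:
    """K-1 fitted stage models plus the back-transformed surface."""

    model: "ContinuationModel"
    stage_fits: list  # BinomialLinkResults per stage
    converged: bool = True

    def __post_init__(self):
        self.converged = all(f.converged for f in self.stage_fits)

    @property
    def data(self) -> GroupedMultinomialData:
        return self.model.data

    @property
    def llf(self) -> float:
        """Combined log-likelihood: the sum of stage log-likelihoods."""
        return float(sum(f.llf for f in self.stage_fits))

    @property
    def n_params(self) -> int:
        return int(sum(f.n_params for f in self.stage_fits))

    def stage_probabilities(self, X=None) -> np.ndarray:
        """theta_k(x) per stage at the given (or training) design rows."""
        X = self.data.X if X is None else np.atleast_2d(np.asarray(X, dtype=float))
        cols = []
        for k, f in enumerate(self.stage_fits):
            link = f.model.link
            eta = X @ f.beta
            if not link.supports_negative_eta and np.any(eta <= 0):
                bad = np.flatnonzero(eta <= 0)
                raise ValueError(
                    f"stage {k + 1} ({link.name}): eta <= 0 at design row(s) {bad.tolist()}"
                )
            cols.append(np.atleast_1d(link.inverse(eta, f.shape)))
        return np.column_stack(cols)

    def category_probabilities(self, X=None) -> np.ndarray:
        """Category probability surface (rows sum to one exactly)."""
        return category_probabilities(self.stage_probabilities(X))

    def fitted_category_probabilities(self) -> np.ndarray:
        return self.category_probabilities()

    def selection_stats(self):
        from .selection import stats_for_multinomial_fit

        return stats_for_multinomial_fit(self)

    def summary(self) -> str:
        lines = [
            f"Continuation-partition multinomial fit ({self.data.K} categories, "
            f"link per stage below)",
            f"combined log-likelihood: {self.llf:.4f}   params: {self.n_params}"
            f"   converged: {self.converged}",
        ]
        for k, f in enumerate(self.stage_fits):
            lines.append(f"\n--- stage {k + 1} ---\n{f.summary()}")
        return "\n".join(lines)


class ContinuationModel:
    """Multinomial regression as K-1 sequential binomial models.

    Parameters
    ----------
    data : GroupedMultinomialData
    link : link name or LinkSpec, or a list of K-1 of them (per stage).
    """

    def __init__(self, data: GroupedMultinomialData, link="weibull"):
        self.data = data
        K = data.K
        if isinstance(link, (list, tuple)):
            if len(link) != K - 1:
                raise ValueError(f"need {K - 1} per-stage links, got {len(link)}")
            self.links = [get_link(l) for l in link]
        else:
            self.links = [get_link(link)] * (K - 1)
        self.partition = partition_multinomial(data)

    def fit(self, stage_options=None, **options) -> ContinuationResults:
        """Fit each stage independently by ML.

        ``options`` are forwarded to every stage fit;  ``stage_options``
        (list of dicts) overrides per stage.
        """
        fits = []
        for k, (sub, link) in enumerate(zip(self.partition, self.links)):
            if sub is None:
                raise ValueError(f"stage {k + 1} has no data; cannot fit")
            opts = dict(options)
            if stage_options is not None:
                opts.update(stage_options[k] or {})
            fits.append(BinomialLinkModel(sub, link=link).fit(**opts))
        res = ContinuationResults(model=self, stage_fits=fits)
        if not res.converged:
            warnings.warn("one or more stage fits did not converge")
        return res


def fit_multinomial(data: GroupedMultinomialData, link="weibull", **options):
    """Functional entry point mirroring ``ContinuationModel(...).fit()``."""
    return ContinuationModel(data, link=link).fit(**options)
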