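"""Grouped categorical data containers, study fixtures, and simulation.

Two embedded datasets drive the worked analyses:

* a poison-potency bioassay — 17 dose/poison covariate patterns, 818
  insects, binary dead/alive response; covariates are log-dose plus
  indicators for Rotenone and Deguelin (the poison mixture is the
  reference level);
* a snail irradiation study — 4,800 snails randomized to five gamma-ray
  doses, with a four-level DNA-damage response recorded as three nested
  binary indicator tables (Z1, Z2, Z3).

The synthetic generator draws grouped binomial or multinomial data under
any registered link, a coefficient vector and shape parameters, for
parameter-recovery testing of the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .links import get_link

__all__ = [
    "GroupedBinomialData",
    "GroupedMultinomialData",
    "load_poison",
    "load_snail",
    "read_binomial_csv",
    "read_multinomial_csv",
    "SyntheticSpec",
    "simulate",
]


@dataclass
class GroupedBinomialData:
    """Binomial observations grouped by covariate pattern.

    Parameters
    ----------
    X : (n_patterns, p) design matrix; first column must be all ones.
    successes : non-negative integer counts per pattern.
    trials : positive integer totals per pattern, successes <= trials.
    names : column names for the design matrix.
    """

    X: np.ndarray
    successes: np.ndarray
    trials: np.ndarray
    names: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be two-dimensional")
        self.successes = np.asarray(self.successes, dtype=float)
        self.trials = np.asarray(self.trials, dtype=float)
        if self.X.shape[0] != self.successes.shape[0] or self.X.shape[0] != self.trials.shape[0]:
            raise ValueError("X, successes and trials must have matching lengths")
        if np.any(self.successes < 0) or np.any(self.trials <= 0):
            raise ValueError("counts must satisfy successes >= 0 and trials > 0")
        if np.any(self.successes > self.trials):
            raise ValueError("successes must not exceed trials")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be an intercept of ones")
        if not self.names:
            self.names = ["const"] + [f"x{j}" for j in range(1, self.X.shape[1])]

    @property
    def n_patterns(self) -> int:
        return self.X.shape[0]

    @property
    def n_individuals(self) -> int:
        return int(round(self.trials.sum()))

    @property
    def proportions(self) -> np.ndarray:
        """Observed success proportions per covariate pattern."""
        return self.successes / self.trials

    def check_full_rank(self):
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    def expand(self) -> "GroupedBinomialData":
        """Individual-level expansion: one Bernoulli row per subject."""
        rows, y = [], []
        for xi, si, mi in zip(self.X, self.successes, self.trials):
            mi, si = int(round(mi)), int(round(si))
            rows.extend([xi] * mi)
            y.extend([1] * si + [0] * (mi - si))
        return GroupedBinomialData(
            np.asarray(rows), np.asarray(y, dtype=float),
            np.ones(len(y)), names=list(self.names),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X[:, 1:], columns=self.names[1:])
        df["successes"] = self.successes.astype(int)
        df["trials"] = self.trials.astype(int)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, covariates=None) -> "GroupedBinomialData":
        if covariates is None:
            covariates = [c for c in df.columns if c not in ("successes", "trials")]
        X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in covariates])
        return cls(X, df["successes"].to_numpy(float), df["trials"].to_numpy(float),
                   names=["const"] + list(covariates))


@dataclass
class GroupedMultinomialData:
    """K-category multinomial counts grouped by covariate pattern.

    ``counts[i, k]`` is the number of subjects in pattern i falling in
    ordered category k (the order is part of the model: it defines the
    continuation partition and is never rearranged).
    """

    X: np.ndarray
    counts: np.ndarray
    names: list = field(default_factory=list)
    categories: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] < 2:
            raise ValueError("counts must be (n_patterns, K) with K >= 2")
        if self.X.shape[0] != self.counts.shape[0]:
            raise ValueError("X and counts must have matching lengths")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be an intercept of ones")
        if not self.names:
            self.names = ["const"] + [f"x{j}" for j in range(1, self.X.shape[1])]
        if not self.categories:
            self.categories = list(range(1, self.K + 1))

    @property
    def K(self) -> int:
        return self.counts.shape[1]

    @property
    def n_patterns(self) -> int:
        return self.X.shape[0]

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_individuals(self) -> int:
        return int(round(self.counts.sum()))

    @property
    def relative_frequencies(self) -> np.ndarray:
        """Within-pattern category relative frequencies (n_patterns, K)."""
        return self.counts / self.totals[:, None]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X[:, 1:], columns=self.names[1:])
        for k in range(self.K):
            df[f"count_{k + 1}"] = self.counts[:, k].astype(int)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, covariates=None) -> "GroupedMultinomialData":
        count_cols = sorted(
            (c for c in df.columns if c.startswith("count_")),
            key=lambda c: int(c.split("_")[1]),
        )
        if covariates is None:
            covariates = [c for c in df.columns if c not in count_cols]
        X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in covariates])
        counts = df[count_cols].to_numpy(float)
        return cls(X, counts, names=["const"] + list(covariates))


# ---------------------------------------------------------------------
# Embedded study fixtures
# ---------------------------------------------------------------------

# poison bioassay: (log dose, dead, n) per poison
_POISON_ROWS = [
    # Rotenone (indicator x2 = 1)
    (1.01, 44, 50, 1, 0),
    (0.89, 42, 49, 1, 0),
    (0.71, 24, 46, 1, 0),
    (0.58, 16, 48, 1, 0),
    (0.41, 6, 50, 1, 0),
    # Deguelin (indicator x3 = 1)
    (1.70, 48, 48, 0, 1),
    (1.61, 47, 50, 0, 1),
    (1.48, 47, 49, 0, 1),
    (1.31, 34, 48, 0, 1),
    (1.00, 18, 48, 0, 1),
    (0.71, 16, 49, 0, 1),
    # Mixture (reference: x2 = x3 = 0)
    (1.40, 48, 50, 0, 0),
    (1.31, 43, 46, 0, 0),
    (1.18, 38, 48, 0, 0),
    (1.00, 27, 46, 0, 0),
    (0.71, 22, 46, 0, 0),
    (0.40, 7, 47, 0, 0),
]

# snail irradiation study: dose -> (Z1 zeros, Z1 ones, Z2 zeros, Z2 ones,
# Z3 zeros, Z3 ones); Zk is the indicator of damage class k among snails
# not in classes 1..k-1
_SNAIL_Z = {
    0.0: (446, 654, 321, 125, 249, 72),
    2.5: (458, 442, 280, 178, 175, 105),
    5.0: (703, 197, 450, 253, 277, 173),
    10.0: (841, 159, 545, 296, 281, 264),
    20.0: (842, 58, 793, 49, 660, 133),
}


def load_poison() -> GroupedBinomialData:
    """Poison-potency bioassay: 17 patterns, 818 insects, 527 dead.

    Covariates: intercept, log-dose (as printed), Rotenone indicator,
    Deguelin indicator; the two-poison mixture is the reference level.
    """
    d = np.asarray(_POISON_ROWS, dtype=float)
    X = np.column_stack([np.ones(len(d)), d[:, 0], d[:, 3], d[:, 4]])
    return GroupedBinomialData(
        X, d[:, 1], d[:, 2], names=["const", "logdose", "rotenone", "deguelin"]
    )


def load_snail():
    """Snail DNA-damage study.

    Returns
    -------
    data : GroupedMultinomialData
        Four-category damage counts at doses 0, 2.5, 5, 10, 20 Gy,
        reconstructed from the nested indicator tables (category k count
        = Zk ones; category K count = Z3 zeros).
    z_tables : list of GroupedBinomialData
        The three indicator sub-datasets exactly as recorded, with
        covariates (1, dose, dose^2).
    """
    doses = np.array(sorted(_SNAIL_Z))
    Z = np.asarray([_SNAIL_Z[d] for d in doses], dtype=float)
    counts = np.column_stack([Z[:, 1], Z[:, 3], Z[:, 5], Z[:, 4]])
    # Z3 zeros are the class-4 snails; sanity: nesting identities
    assert np.all(Z[:, 2] + Z[:, 3] == Z[:, 0])
    assert np.all(Z[:, 4] + Z[:, 5] == Z[:, 2])
    X = np.column_stack([np.ones(len(doses)), doses, doses ** 2])
    names = ["const", "dose", "dose2"]
    data = GroupedMultinomialData(X, counts, names=names,
                                  categories=["none", "low", "intermediate", "high"])
    z_tables = [
        GroupedBinomialData(X, Z[:, 2 * k + 1], Z[:, 2 * k] + Z[:, 2 * k + 1], names=names)
        for k in range(3)
    ]
    return data, z_tables


def read_binomial_csv(path, covariates=None) -> GroupedBinomialData:
    """Read grouped binomial data from CSV (covariates..., successes, trials)."""
    return GroupedBinomialData.from_frame(pd.read_csv(path), covariates)


def read_multinomial_csv(path, covariates=None) -> GroupedMultinomialData:
    """Read grouped multinomial data from CSV (covariates..., count_1..count_K)."""
    return GroupedMultinomialData.from_frame(pd.read_csv(path), covariates)


# ---------------------------------------------------------------------
# Synthetic data
# ---------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Recipe for a reproducible grouped synthetic dataset.

    For ``K == 2`` a grouped binomial dataset is drawn with success
    probability ``inverse_link(X @ beta)`` at each pattern.  For
    ``K > 2`` the continuation cascade is simulated: Z1 thins category 1
    from all subjects, Z2 thins category 2 from the remainder, and so
    on, each stage using the same link with per-stage coefficients.
    """

    link: str = "weibull"
    beta: tuple = (1.0, 0.5)
    shape: tuple = ()
    X: np.ndarray = None
    trials: int = 100
    K: int = 2
    seed: int = 0

    def design(self) -> np.ndarray:
        if self.X is not None:
            return np.asarray(self.X, dtype=float)
        # default: intercept + one covariate on a grid
        grid = np.linspace(0.1, 2.0, 20)
        return np.column_stack([np.ones(grid.size), grid])


def _stage_params(spec):
    beta = np.asarray(spec.beta, dtype=float)
    if spec.K == 2:
        return [(beta, tuple(spec.shape))]
    if beta.ndim == 1:
        return [(beta, tuple(spec.shape))] * (spec.K - 1)
    shapes = spec.shape if spec.shape and np.ndim(spec.shape[0]) else [spec.shape] * (spec.K - 1)
    return [(beta[k], tuple(np.atleast_1d(shapes[k]))) for k in range(spec.K - 1)]


def simulate(spec: SyntheticSpec):
    """Draw a grouped dataset under ``spec`` (deterministic given seed).

    Raises
    ------
    EtaDomainError
        If any design row yields an inadmissible linear predictor for
        the chosen link (checked before any sampling).
    """
    link = get_link(spec.link)
    X = spec.design()
    rng = np.random.default_rng(spec.seed)
    stages = _stage_params(spec)
    probs = [link.inverse(X @ b, s) for b, s in stages]  # validates eta domains

    if spec.K == 2:
        m = np.full(X.shape[0], spec.trials)
        y = rng.binomial(m.astype(int), probs[0])
        return GroupedBinomialData(X, y, m)

    remaining = np.full(X.shape[0], spec.trials, dtype=int)
    counts = np.zeros((X.shape[0], spec.K), dtype=float)
    for k in range(spec.K - 1):
        taken = rng.binomial(remaining, probs[k])
        counts[:, k] = taken
        remaining = remaining - taken
    counts[:, -1] = remaining
    return GroupedMultinomialData(X, counts)
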