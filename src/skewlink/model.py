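"""Maximum-likelihood estimation for grouped binary regression under any
registered link, with the Weibull-specific analytic score/Hessian and
Newton polish.

The likelihood is the Bernoulli-form grouped log-likelihood

    l(beta, shape) = sum_i [ y_i log mu_i + (m_i - y_i) log(1 - mu_i) ],
    mu_i = g^{-1}(x_i' beta; shape),

without binomial coefficients.  This normalization is what the AIC/BIC
accounting in the worked analyses uses (BIC's sample size is the total
number of individuals, not the number of covariate patterns).

For the Weibull link the predictor must stay positive; during
optimization points with eta <= 0 receive a smooth exterior penalty so
that Nelder-Mead can recover from boundary excursions (the intercept
plays the role of the threshold parameter of the Weibull cdf).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .data import GroupedBinomialData
from .links import EtaDomainError, get_link

__all__ = [
    "log_likelihood",
    "score_and_hessian",
    "initial_guess",
    "fit_mle",
    "standard_errors",
    "BinomialLinkModel",
    "BinomialLinkResults",
]

#: shape seed for the Weibull pair: the value at which the Weibull cdf is
#: closest to a standard normal, so the initial fit mimics a probit fit
GAMMA_INIT = 3.60235

_PENALTY = 1e10
_PENALTY_SLOPE = 1e6
_CLIP_LO = 1e-300
_CLIP_HI = 1.0 - 1e-16


def _loglik_terms(link, eta, shape):
    """(log mu, log(1-mu)) with numerically exact complements where known."""
    name = link.name
    if name in ("weibull", "rweibull"):
        (g,) = shape
        t = eta ** g
        log_cdf = np.log(np.clip(-np.expm1(-t), _CLIP_LO, None))
        return (log_cdf, -t) if name == "weibull" else (-t, log_cdf)
    if name == "cloglog":
        return np.log(np.clip(-np.expm1(-np.exp(eta)), _CLIP_LO, None)), -np.exp(eta)
    if name == "loglog":
        return -np.exp(eta), np.log(np.clip(-np.expm1(-np.exp(eta)), _CLIP_LO, None))
    mu = np.clip(link._inverse(eta, shape), _CLIP_LO, _CLIP_HI)
    return np.log(mu), np.log1p(-mu)


def log_likelihood(data: GroupedBinomialData, link, beta, shape=()) -> float:
    """Grouped Bernoulli-form log-likelihood (no binomial coefficients).

    For the Weibull pair, parameter points with any pattern's eta <= 0
    return a large negative exterior penalty rather than raising, so the
    function can be handed directly to a derivative-free optimizer.
    """
    link = get_link(link)
    shape = link.validate_shape(shape)
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != data.X.shape[1]:
        raise ValueError(
            f"beta has length {beta.shape[0]} but design has {data.X.shape[1]} columns"
        )
    eta = data.X @ beta
    if not link.supports_negative_eta and np.any(eta <= 0):
        return -_PENALTY - _PENALTY_SLOPE * float(np.sum(np.maximum(0.0, -eta)))
    with np.errstate(over="ignore", invalid="ignore"):
        log_mu, log_1m = _loglik_terms(link, eta, shape)
        y, m = data.successes, data.trials
        # guard 0 * (-inf): cells with zero count contribute exactly zero
        succ = np.where(y > 0, y * log_mu, 0.0)
        fail = np.where(m - y > 0, (m - y) * log_1m, 0.0)
        return float(np.sum(succ + fail))


def score_and_hessian(data: GroupedBinomialData, beta, gamma):
    """Analytic gradient and Hessian of the Weibull-link log-likelihood.

    Parameters are ordered (beta_0..beta_r, gamma).  Writing
    t_i = eta_i**gamma, the chain rule through t gives

        dl/dtheta   = sum_i A_i dt_i/dtheta,
        d2l/dth dph = sum_i B_i dt_i/dth dt_i/dph + A_i d2t_i/dth dph,

    with A = y e^{-t}/(1-e^{-t}) - (m - y) and B = -y e^{-t}/(1-e^{-t})^2.

    Raises
    ------
    EtaDomainError
        At boundary points (some eta <= 0); callers should use the
        penalized ``log_likelihood`` there instead.
    """
    beta = np.asarray(beta, dtype=float)
    gamma = float(gamma)
    eta = data.X @ beta
    if np.any(eta <= 0):
        raise EtaDomainError(
            "score/Hessian only defined for eta > 0 everywhere; "
            "use the penalized log-likelihood near the boundary"
        )
    y, m, X = data.successes, data.trials, data.X
    t = eta ** gamma
    log_eta = np.log(eta)
    em = np.exp(-t)
    ratio = em / (-np.expm1(-t))          # e^{-t} / (1 - e^{-t})
    A = y * ratio - (m - y)
    B = -y * em / np.expm1(-t) ** 2

    # first and second derivatives of t w.r.t. (beta, gamma)
    dt_db = (gamma * eta ** (gamma - 1.0))[:, None] * X          # (n, p)
    dt_dg = t * log_eta                                          # (n,)
    p = X.shape[1]
    grad = np.empty(p + 1)
    grad[:p] = A @ dt_db
    grad[p] = A @ dt_dg

    H = np.empty((p + 1, p + 1))
    # beta-beta block
    w_bb = B * (gamma * eta ** (gamma - 1.0)) ** 2 + A * gamma * (gamma - 1.0) * eta ** (gamma - 2.0)
    H[:p, :p] = (X * w_bb[:, None]).T @ X
    # beta-gamma block: d2t/dbeta dgamma = eta^{gamma-1} (1 + gamma log eta) x
    w_bg = B * (gamma * eta ** (gamma - 1.0)) * dt_dg + A * eta ** (gamma - 1.0) * (1.0 + gamma * log_eta)
    H[:p, p] = w_bg @ X
    H[p, :p] = H[:p, p]
    # gamma-gamma: d2t/dgamma2 = t (log eta)^2
    H[p, p] = np.sum(B * dt_dg ** 2 + A * t * log_eta ** 2)
    return grad, H


def initial_guess(data: GroupedBinomialData, flip: bool = False):
    """Starting point for the Weibull-link fit.

    A probit fit supplies the slopes; the intercept is shifted so that
    the smallest initial predictor equals +0.001 (strictly inside the
    Weibull domain); the shape seed is ``GAMMA_INIT`` = 3.60235, at which
    the Weibull link approximates the probit link.  ``flip=True`` runs
    the probit fit on failures instead of successes, the appropriate
    start for the reflected (decreasing) Weibull link.

    Falls back to zero slopes with intercept 0.001 when the probit fit
    fails (e.g. complete separation).
    """
    import statsmodels.api as sm

    y = data.trials - data.successes if flip else data.successes
    endog = np.column_stack([y, data.trials - y])
    try:
        if y.sum() == 0 or (data.trials - y).sum() == 0:
            raise ValueError("degenerate response: all successes or all failures")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            probit = sm.GLM(
                endog, data.X, family=sm.families.Binomial(sm.families.links.Probit())
            ).fit()
        params = np.asarray(probit.params)
        if not np.all(np.isfinite(params)):
            raise ValueError("non-finite probit parameters")
        eta = data.X @ params
        beta0 = params[0] - eta.min() + 0.001
        beta = np.concatenate([[beta0], params[1:]])
        fallback = False
    except Exception:
        beta = np.zeros(data.X.shape[1])
        beta[0] = 0.001
        fallback = True
    return beta, GAMMA_INIT, fallback


# ---------------------------------------------------------------------
# shape-parameter transforms (optimize unconstrained, report natural)
# ---------------------------------------------------------------------

def _to_free(shape, bounds):
    out = []
    for s, (lo, hi) in zip(shape, bounds):
        if lo == 0.0 and hi is None:
            out.append(np.log(s))
        elif lo is not None and hi is not None:
            out.append(np.arctanh((2.0 * s - lo - hi) / (hi - lo)))
        else:
            out.append(s)
    return np.asarray(out)


def _to_natural(free, bounds):
    out = []
    for f, (lo, hi) in zip(free, bounds):
        if lo == 0.0 and hi is None:
            out.append(np.exp(f))
        elif lo is not None and hi is not None:
            out.append((lo + hi) / 2.0 + (hi - lo) / 2.0 * np.tanh(f))
        else:
            out.append(f)
    return tuple(out)


@dataclass
class BinomialLinkResults:
    """Fitted binary-regression results under a parametric link.

    Attributes
    ----------
    beta : estimated regression coefficients.
    shape : estimated link shape parameters (natural scale).
    llf : maximized Bernoulli-form log-likelihood.
    vcov : joint covariance of (beta, shape) from the inverse observed
        information, or None when the information is singular.
    converged : whether the optimizer met its loglik tolerance.
    """

    model: "BinomialLinkModel"
    beta: np.ndarray
    shape: tuple
    llf: float
    converged: bool
    vcov: np.ndarray = None
    trace: dict = field(default_factory=dict)

    @property
    def params(self) -> np.ndarray:
        """Concatenated (beta, shape) on the natural scale."""
        return np.concatenate([self.beta, np.asarray(self.shape)])

    @property
    def n_params(self) -> int:
        return self.beta.size + len(self.shape)

    @property
    def n_individuals(self) -> int:
        return self.model.data.n_individuals

    @property
    def bse(self):
        """Standard errors of (beta, shape), NaN where unavailable."""
        if self.vcov is None:
            return np.full(self.n_params, np.nan)
        d = np.diag(self.vcov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)

    def predict(self, X=None) -> np.ndarray:
        """Fitted probabilities at the data's (or new) design rows."""
        X = self.model.data.X if X is None else np.asarray(X, dtype=float)
        return np.atleast_1d(self.model.link.inverse(X @ self.beta, self.shape))

    def selection_stats(self):
        from .selection import stats_for_binomial_fit

        return stats_for_binomial_fit(self)

    def param_names(self):
        return list(self.model.data.names) + list(self.model.link.shape_names)

    def summary(self) -> str:
        import pandas as pd

        se = self.bse
        tab = pd.DataFrame(
            {"estimate": self.params, "std err": se}, index=self.param_names()
        )
        head = (
            f"Grouped binomial regression, {self.model.link.name} link\n"
            f"patterns: {self.model.data.n_patterns}   individuals: "
            f"{self.n_individuals}   params: {self.n_params}\n"
            f"log-likelihood: {self.llf:.4f}   converged: {self.converged}\n"
        )
        return head + tab.to_string(float_format=lambda v: f"{v:.4f}")


class BinomialLinkModel:
    """Grouped binary-response regression with a parametric link.

    Examples
    --------
    >>> from skewlink import BinomialLinkModel, load_poison
    >>> res = BinomialLinkModel(load_poison(), link="weibull").fit()
    >>> round(res.llf, 2)
    -370.33
    """

    def __init__(self, data: GroupedBinomialData, link="weibull"):
        data.check_full_rank()
        self.data = data
        self.link = get_link(link)

    @classmethod
    def from_dataframe(cls, df, covariates=None, link="weibull"):
        return cls(GroupedBinomialData.from_frame(df, covariates), link=link)

    def loglike(self, beta, shape=()):
        return log_likelihood(self.data, self.link, beta, shape)

    def fit(
        self,
        start=None,
        fix_shape=None,
        shape_starts=None,
        maxfev=10000,
        tol=1e-8,
        polish=True,
        compute_vcov=True,
    ) -> BinomialLinkResults:
        """Maximize the grouped log-likelihood.

        Nelder-Mead over (beta, transformed shape), restarted until the
        loglik improvement falls below ``tol``; Weibull-family fits are
        then polished by damped Newton-Raphson on the analytic
        score/Hessian.  ``fix_shape`` freezes the shape parameters
        (e.g. the Stukel link at (0, 0) is exactly the logit fit).
        """
        link, data = self.link, self.data
        p = data.X.shape[1]
        fixed = fix_shape is not None
        if fixed:
            fix_shape = link.validate_shape(fix_shape)

        def unpack(z):
            if fixed or link.n_shape_params == 0:
                return z, fix_shape if fixed else ()
            return z[:p], _to_natural(z[p:], link.shape_bounds)

        def nll(z):
            beta, shape = unpack(z)
            return -log_likelihood(data, link, beta, shape)

        starts = self._starting_points(start, fixed, shape_starts)
        smooth = link.supports_negative_eta  # no exterior penalty in the way
        best = None
        for z0 in starts:
            if smooth:
                res = optimize.minimize(nll, z0, method="BFGS",
                                        options={"maxiter": 500})
                res = self._nelder_mead(nll, res.x, maxfev, tol, rounds=2)
            else:
                res = self._nelder_mead(nll, z0, maxfev, tol, rounds=4)
            if best is None or res.fun < best.fun:
                best = res
        beta, shape = unpack(best.x)
        llf = -best.fun
        converged = bool(best.success)
        nfev = best.nfev

        if polish and link.name in ("weibull", "rweibull") and not fixed:
            beta, shape, llf, extra = self._newton_polish(beta, shape, llf)
            nfev += extra
            converged = converged or extra > 0

        llf_check = log_likelihood(data, link, beta, shape)
        if llf_check <= -_PENALTY:
            converged = False
        vcov = None
        if compute_vcov and converged:
            vcov = self._vcov(beta, shape, fixed)
        return BinomialLinkResults(
            model=self,
            beta=np.asarray(beta, dtype=float),
            shape=() if (fixed and link.n_shape_params == 0) else tuple(shape),
            llf=llf_check,
            converged=converged,
            vcov=vcov,
            trace={"nfev": nfev, "n_starts": len(starts)},
        )

    # -- internals ----------------------------------------------------
    def _starting_points(self, start, fixed, shape_starts):
        link, data = self.link, self.data
        p = data.X.shape[1]
        if start is not None:
            return [np.asarray(start, dtype=float)]
        starts = []
        if link.name in ("weibull", "rweibull"):
            beta0, g0, _ = initial_guess(data, flip=(link.name == "rweibull"))
            for g in shape_starts or (g0, 1.0, 0.25):
                starts.append(np.concatenate([beta0, [np.log(g)]]))
        else:
            free = [] if (fixed or link.n_shape_params == 0) else list(
                _to_free(link.default_shape, link.shape_bounds)
            )
            starts.append(np.concatenate([np.zeros(p), free]))
            if link.n_shape_params and not fixed:
                # shape families benefit from starting at the logit solution
                try:
                    starts.append(np.concatenate([self._quick_logit_beta(), free]))
                except Exception:
                    pass
        return starts

    def _quick_logit_beta(self):
        from scipy.special import expit

        data = self.data
        y, m, X = data.successes, data.trials, data.X

        def nll(b):
            mu = np.clip(expit(X @ b), _CLIP_LO, _CLIP_HI)
            return -float(np.sum(y * np.log(mu) + (m - y) * np.log1p(-mu)))

        return optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS").x

    @staticmethod
    def _nelder_mead(nll, z0, maxfev, tol, rounds=4):
        opts = {"maxfev": maxfev, "xatol": 1e-9, "fatol": tol * 1e-1}
        res = optimize.minimize(nll, z0, method="Nelder-Mead", options=opts)
        for _ in range(rounds):
            prev = res.fun
            res = optimize.minimize(nll, res.x, method="Nelder-Mead", options=opts)
            if prev - res.fun < tol:
                res.success = True
                break
        return res

    def _newton_polish(self, beta, shape, llf, max_iter=50):
        """Damped Newton on the analytic Weibull score/Hessian.

        The reflected link reuses the Weibull derivatives through the
        complement identity rweibull(y; beta, gamma) = weibull(m - y).
        """
        data, link = self.data, self.link
        flip = link.name == "rweibull"
        work = (
            GroupedBinomialData(
                data.X, data.trials - data.successes, data.trials, names=list(data.names)
            )
            if flip
            else data
        )
        beta = np.asarray(beta, dtype=float)
        (gamma,) = shape
        steps = 0
        for _ in range(max_iter):
            try:
                grad, H = score_and_hessian(work, beta, gamma)
            except EtaDomainError:
                break
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            improved = False
            for damp in (1.0, 0.5, 0.25, 0.1, 0.01):
                cand_b = beta - damp * step[:-1]
                cand_g = gamma - damp * step[-1]
                if cand_g <= 0:
                    continue
                cand_llf = log_likelihood(data, link, cand_b, (cand_g,))
                if cand_llf > llf:
                    beta, gamma, llf = cand_b, cand_g, cand_llf
                    improved = True
                    steps += 1
                    break
            if not improved or abs(damp * np.max(np.abs(step))) < 1e-12:
                break
            if np.max(np.abs(grad)) < 1e-10:
                break
        return beta, (gamma,), llf, steps

    def _vcov(self, beta, shape, fixed):
        link, data = self.link, self.data
        if link.name == "weibull" and not fixed:
            try:
                _, H = score_and_hessian(data, beta, shape[0])
            except EtaDomainError:
                H = self._numeric_hessian(beta, shape, fixed)
        elif link.name == "rweibull" and not fixed:
            work = GroupedBinomialData(
                data.X, data.trials - data.successes, data.trials, names=list(data.names)
            )
            try:
                _, H = score_and_hessian(work, beta, shape[0])
            except EtaDomainError:
                H = self._numeric_hessian(beta, shape, fixed)
        else:
            H = self._numeric_hessian(beta, shape, fixed)
        try:
            vcov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            warnings.warn("singular observed information; standard errors unavailable")
            return None
        if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) <= 0):
            warnings.warn("observed information not positive definite at the optimum")
        return vcov

    def _numeric_hessian(self, beta, shape, fixed):
        theta = np.concatenate([beta, [] if fixed else np.asarray(shape)])
        p = len(beta)

        def f(th):
            b = th[:p]
            s = shape if fixed else tuple(th[p:])
            return log_likelihood(self.data, self.link, b, s)

        n = theta.size
        H = np.empty((n, n))
        h = 1e-5 * np.maximum(1.0, np.abs(theta))
        if not fixed:
            # keep finite-difference points inside the shape space
            for j, (lo, hi) in enumerate(self.link.shape_bounds):
                i = p + j
                if lo is not None:
                    h[i] = min(h[i], 0.45 * (theta[i] - lo))
                if hi is not None:
                    h[i] = min(h[i], 0.45 * (hi - theta[i]))
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = h[i]
                ej = np.zeros(n); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4.0 * h[i] * h[j])
        return H


def fit_mle(data: GroupedBinomialData, link="weibull", **options) -> BinomialLinkResults:
    """Functional entry point: fit a grouped binary regression by ML."""
    return BinomialLinkModel(data, link=link).fit(**options)


def standard_errors(fit: BinomialLinkResults) -> np.ndarray:
    """Per-parameter standard errors of a converged fit (NaN if absent)."""
    if not fit.converged:
        raise ValueError("standard errors require a converged fit")
    return fit.bse
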