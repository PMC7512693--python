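"""Parametric inverse-link catalog for binary regression.

Each link maps a linear predictor eta to a success probability through a
cdf-shaped curve ``mu = inverse(eta, shape)``.  The Weibull link

    mu = 1 - exp(-eta**gamma),   eta > 0, gamma > 0,

carries its skewness entirely in the shape parameter ``gamma``; the
reflected Weibull ``mu = exp(-eta**gamma)`` is its decreasing, left-skew
mirror.  The catalog also holds the classical symmetric links (logit,
probit), the complementary log-log / log-log pair (the large-gamma limits
of the two Weibull forms), and the competing parametric families used for
model comparison: Aranda-Ordaz, Stukel, Prentice, skew-probit and the
asymmetric exponential power (AEP) link.

All links are vectorized over ``eta``.  Shape parameters are passed as a
flat tuple in the documented order.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

__all__ = [
    "LinkError",
    "EtaDomainError",
    "ShapeConstraintError",
    "LinkSpec",
    "get_link",
    "available_links",
]


class LinkError(ValueError):
    pass


class EtaDomainError(LinkError):
    """Linear predictor outside the link's domain (eta <= 0 for Weibull)."""


class ShapeConstraintError(LinkError):
    """Shape parameter violates the family's parametric space."""


def _as_eta(eta):
    return np.asarray(eta, dtype=float)


class LinkSpec:
    """Base class for a named inverse-link family.

    Attributes
    ----------
    name : str
        Registry identifier.
    n_shape_params : int
        Number of free shape parameters.
    shape_bounds : tuple of (low, high)
        Open-interval constraint per shape parameter (None = unbounded).
    shape_names : tuple of str
    supports_negative_eta : bool
        False for the Weibull pair, whose predictor must be positive.
    increasing : bool
        Orientation of ``inverse`` in eta (False for reflected Weibull
        and log-log, which are stored as decreasing links; no silent
        sign flip of eta is applied).
    default_shape : tuple
        Admissible reference point (used for round-trip tests and as a
        generic starting value).
    """

    name: str = ""
    n_shape_params: int = 0
    shape_bounds: tuple = ()
    shape_names: tuple = ()
    supports_negative_eta: bool = True
    increasing: bool = True
    default_shape: tuple = ()
    #: shape indices whose derivative is analytic (others use central differences)
    analytic_shape_grad: bool = True

    # -- validation ---------------------------------------------------
    def validate_shape(self, shape) -> tuple:
        shape = tuple(float(s) for s in np.atleast_1d(np.asarray(shape, dtype=float))) if self.n_shape_params else ()
        if len(shape) != self.n_shape_params:
            raise ShapeConstraintError(
                f"{self.name}: expected {self.n_shape_params} shape parameter(s), got {len(shape)}"
            )
        for s, (lo, hi), nm in zip(shape, self.shape_bounds, self.shape_names):
            if lo is not None and not s > lo:
                raise ShapeConstraintError(f"{self.name}: require {nm} > {lo}, got {s}")
            if hi is not None and not s < hi:
                raise ShapeConstraintError(f"{self.name}: require {nm} < {hi}, got {s}")
        return shape

    def check_eta(self, eta):
        eta = _as_eta(eta)
        if not self.supports_negative_eta and np.any(eta <= 0):
            raise EtaDomainError(
                f"{self.name}: linear predictor must be strictly positive "
                f"(min eta = {np.min(eta):.6g})"
            )
        return eta

    # -- interface ----------------------------------------------------
    def inverse(self, eta, shape=()):
        """Map linear predictor to probability, g^{-1}(eta; shape)."""
        shape = self.validate_shape(shape)
        scalar = np.isscalar(eta) or np.ndim(eta) == 0
        eta = self.check_eta(np.atleast_1d(eta))
        out = self._inverse(eta, shape)
        return float(out[0]) if scalar else out

    def forward(self, mu, shape=()):
        """Map probability in (0,1) to the linear predictor, g(mu; shape)."""
        shape = self.validate_shape(shape)
        scalar = np.isscalar(mu) or np.ndim(mu) == 0
        mu = np.atleast_1d(np.asarray(mu, dtype=float))
        if np.any(mu <= 0) or np.any(mu >= 1):
            raise LinkError(f"{self.name}: mu must lie strictly inside (0, 1)")
        out = self._forward(mu, shape)
        return float(out[0]) if scalar else out

    def derivatives(self, eta, shape=()):
        """Return (dmu/deta, dmu/dshape) at an interior admissible point.

        dmu/dshape is an array of shape ``eta.shape + (n_shape_params,)``.
        Families without closed-form shape gradients fall back to central
        finite differences on the shape axis.
        """
        shape = self.validate_shape(shape)
        eta = self.check_eta(np.atleast_1d(eta))
        d_eta = self._dmu_deta(eta, shape)
        if self.n_shape_params == 0:
            d_shape = np.zeros(np.shape(eta) + (0,))
        elif self.analytic_shape_grad:
            d_shape = self._dmu_dshape(eta, shape)
        else:
            d_shape = self._fd_shape_grad(eta, shape)
        return d_eta, d_shape

    def _fd_shape_grad(self, eta, shape):
        cols = []
        for j, s in enumerate(shape):
            h = 1e-6 * max(1.0, abs(s))
            up = list(shape)
            dn = list(shape)
            up[j] = s + h
            dn[j] = s - h
            cols.append((self._inverse(eta, tuple(up)) - self._inverse(eta, tuple(dn))) / (2 * h))
        return np.stack(cols, axis=-1)

    def __repr__(self):  # pragma: no cover
        return f"<LinkSpec {self.name!r} ({self.n_shape_params} shape param(s))>"


# ---------------------------------------------------------------------
# Weibull pair
# ---------------------------------------------------------------------

class WeibullLink(LinkSpec):
    """Right-skew Weibull link: mu = 1 - exp(-eta**gamma), eta > 0."""

    name = "weibull"
    n_shape_params = 1
    shape_bounds = ((0.0, None),)
    shape_names = ("gamma",)
    supports_negative_eta = False
    default_shape = (1.5,)

    def _inverse(self, eta, shape):
        (g,) = shape
        return -np.expm1(-eta ** g)

    def _forward(self, mu, shape):
        (g,) = shape
        return (-np.log1p(-mu)) ** (1.0 / g)

    def _dmu_deta(self, eta, shape):
        (g,) = shape
        t = eta ** g
        return g * eta ** (g - 1.0) * np.exp(-t)

    def _dmu_dshape(self, eta, shape):
        (g,) = shape
        t = eta ** g
        return (t * np.log(eta) * np.exp(-t))[..., None]


class ReflectedWeibullLink(LinkSpec):
    """Left-skew reflected Weibull link: mu = exp(-eta**gamma), decreasing."""

    name = "rweibull"
    n_shape_params = 1
    shape_bounds = ((0.0, None),)
    shape_names = ("gamma",)
    supports_negative_eta = False
    increasing = False
    default_shape = (1.5,)

    def _inverse(self, eta, shape):
        (g,) = shape
        return np.exp(-eta ** g)

    def _forward(self, mu, shape):
        (g,) = shape
        return (-np.log(mu)) ** (1.0 / g)

    def _dmu_deta(self, eta, shape):
        (g,) = shape
        t = eta ** g
        return -g * eta ** (g - 1.0) * np.exp(-t)

    def _dmu_dshape(self, eta, shape):
        (g,) = shape
        t = eta ** g
        return (-t * np.log(eta) * np.exp(-t))[..., None]


# ---------------------------------------------------------------------
# Fixed-shape classics
# ---------------------------------------------------------------------

class LogitLink(LinkSpec):
    name = "logit"

    def _inverse(self, eta, shape):
        return special.expit(eta)

    def _forward(self, mu, shape):
        return special.logit(mu)

    def _dmu_deta(self, eta, shape):
        mu = special.expit(eta)
        return mu * (1.0 - mu)


class ProbitLink(LinkSpec):
    name = "probit"

    def _inverse(self, eta, shape):
        return stats.norm.cdf(eta)

    def _forward(self, mu, shape):
        return stats.norm.ppf(mu)

    def _dmu_deta(self, eta, shape):
        return stats.norm.pdf(eta)


class CLogLogLink(LinkSpec):
    """Complementary log-log: mu = 1 - exp(-exp(eta)); gamma->inf Weibull limit."""

    name = "cloglog"

    def _inverse(self, eta, shape):
        return -np.expm1(-np.exp(eta))

    def _forward(self, mu, shape):
        return np.log(-np.log1p(-mu))

    def _dmu_deta(self, eta, shape):
        return np.exp(eta - np.exp(eta))


class LogLogLink(LinkSpec):
    """Log-log link mu = exp(-exp(eta)): decreasing, reflected-Weibull limit."""

    name = "loglog"
    increasing = False

    def _inverse(self, eta, shape):
        return np.exp(-np.exp(eta))

    def _forward(self, mu, shape):
        return np.log(-np.log(mu))

    def _dmu_deta(self, eta, shape):
        return -np.exp(eta - np.exp(eta))


# ---------------------------------------------------------------------
# Competing parametric families
# ---------------------------------------------------------------------

class ArandaOrdazLink(LinkSpec):
    """Aranda-Ordaz power family: mu = 1 - (alpha*exp(eta) + 1)^(-1/alpha).

    alpha = 1 recovers the logit link; alpha -> 0 the complementary
    log-log link.
    """

    name = "aranda"
    n_shape_params = 1
    shape_bounds = ((0.0, None),)
    shape_names = ("alpha",)
    default_shape = (1.0,)

    def _inverse(self, eta, shape):
        (a,) = shape
        # (a e^eta + 1)^(-1/a) via logs to survive large eta
        return -np.expm1(-np.log1p(a * np.exp(eta)) / a)

    def _forward(self, mu, shape):
        (a,) = shape
        return np.log(np.expm1(-a * np.log1p(-mu)) / a)

    def _dmu_deta(self, eta, shape):
        (a,) = shape
        s = a * np.exp(eta) + 1.0
        return np.exp(eta) * s ** (-1.0 / a - 1.0)

    def _dmu_dshape(self, eta, shape):
        (a,) = shape
        s = a * np.exp(eta) + 1.0
        d = s ** (-1.0 / a) * (-np.log(s) / a ** 2 + np.exp(eta) / (a * s))
        return d[..., None]


class StukelLink(LinkSpec):
    """Stukel's two-tail generalized logistic: mu = logistic(h(eta; a1, a2)).

    a1 bends the upper tail (eta > 0), a2 the lower tail; (0, 0) is the
    logit link exactly.  h is continuous with one-sided second
    derivatives at eta = 0 only, which is why the branch point is handled
    by assigning eta = 0 to the upper branch.
    """

    name = "stukel"
    n_shape_params = 2
    shape_bounds = ((None, None), (None, None))
    shape_names = ("alpha1", "alpha2")
    default_shape = (0.0, 0.0)

    @staticmethod
    def _h(eta, a1, a2):
        h = np.empty_like(eta)
        pos = eta >= 0
        ep, en = eta[pos], eta[~pos]
        with np.errstate(over="ignore"):  # inf tails map to {0, 1} via expit
            if a1 > 0:
                h[pos] = np.expm1(a1 * ep) / a1
            elif a1 == 0:
                h[pos] = ep
            else:
                h[pos] = -np.log1p(-a1 * ep) / a1
            if a2 > 0:
                h[~pos] = -np.expm1(-a2 * en) / a2
            elif a2 == 0:
                h[~pos] = en
            else:
                h[~pos] = np.log1p(a2 * en) / a2
        return h

    def _inverse(self, eta, shape):
        a1, a2 = shape
        return special.expit(self._h(eta, a1, a2))

    def _forward(self, mu, shape):
        a1, a2 = shape
        z = special.logit(mu)
        eta = np.empty_like(z)
        pos = z >= 0
        zp, zn = z[pos], z[~pos]
        if a1 > 0:
            eta[pos] = np.log1p(a1 * zp) / a1
        elif a1 == 0:
            eta[pos] = zp
        else:
            eta[pos] = -np.expm1(-a1 * zp) / a1
        if a2 > 0:
            eta[~pos] = -np.log1p(-a2 * zn) / a2
        elif a2 == 0:
            eta[~pos] = zn
        else:
            eta[~pos] = np.expm1(a2 * zn) / a2
        return eta

    def _dmu_deta(self, eta, shape):
        a1, a2 = shape
        mu = self._inverse(eta, shape)
        dh = np.empty_like(eta)
        pos = eta >= 0
        ep, en = eta[pos], eta[~pos]
        dh[pos] = np.exp(a1 * ep) if a1 > 0 else (1.0 if a1 == 0 else 1.0 / (1.0 - a1 * ep))
        dh[~pos] = np.exp(-a2 * en) if a2 > 0 else (1.0 if a2 == 0 else 1.0 / (1.0 + a2 * en))
        return mu * (1.0 - mu) * dh

    def _dmu_dshape(self, eta, shape):
        a1, a2 = shape
        mu = self._inverse(eta, shape)
        w = mu * (1.0 - mu)
        pos = eta >= 0
        ep, en = eta[pos], eta[~pos]
        d1 = np.zeros_like(eta)
        d2 = np.zeros_like(eta)
        if a1 > 0:
            d1[pos] = (a1 * ep * np.exp(a1 * ep) - np.expm1(a1 * ep)) / a1 ** 2
        elif a1 == 0:
            d1[pos] = ep ** 2 / 2.0
        else:
            d1[pos] = np.log1p(-a1 * ep) / a1 ** 2 + ep / (a1 * (1.0 - a1 * ep))
        if a2 > 0:
            d2[~pos] = (a2 * en * np.exp(-a2 * en) + np.expm1(-a2 * en)) / a2 ** 2
        elif a2 == 0:
            d2[~pos] = -(en ** 2) / 2.0
        else:
            d2[~pos] = -np.log1p(a2 * en) / a2 ** 2 + en / (a2 * (1.0 + a2 * en))
        return np.stack([w * d1, w * d2], axis=-1)


class PrenticeLink(LinkSpec):
    """Prentice's generalized log-F link: Beta(l1, l2) cdf of logistic(eta).

    (1, 1) is the logit link exactly.  Shape gradients have no closed
    form and are computed by central differences.
    """

    name = "prentice"
    n_shape_params = 2
    shape_bounds = ((0.0, None), (0.0, None))
    shape_names = ("lambda1", "lambda2")
    default_shape = (1.0, 1.0)
    analytic_shape_grad = False

    def _inverse(self, eta, shape):
        l1, l2 = shape
        return stats.beta.cdf(special.expit(eta), l1, l2)

    def _forward(self, mu, shape):
        l1, l2 = shape
        return special.logit(stats.beta.ppf(mu, l1, l2))

    def _dmu_deta(self, eta, shape):
        l1, l2 = shape
        s = special.expit(eta)
        return stats.beta.pdf(s, l1, l2) * s * (1.0 - s)


class SkewProbitLink(LinkSpec):
    """Skew-probit link: cdf of a skew-normal evaluated at eta.

    The direct parameterization is used: location 0, scale 1, slant
    lambda = delta / sqrt(1 - delta**2) with delta in (-1, 1).  The
    literal mean-zero / unit-variance centering of the underlying
    skew-normal is deliberately not applied (the centered and direct
    conventions differ only by an affine eta rescaling absorbed by the
    regression coefficients).
    """

    name = "skewprobit"
    n_shape_params = 1
    shape_bounds = ((-1.0, 1.0),)
    shape_names = ("delta",)
    default_shape = (0.0,)
    analytic_shape_grad = False

    @staticmethod
    def _slant(d):
        return d / np.sqrt(1.0 - d * d)

    def _inverse(self, eta, shape):
        (d,) = shape
        return stats.skewnorm.cdf(eta, self._slant(d))

    def _forward(self, mu, shape):
        (d,) = shape
        return stats.skewnorm.ppf(mu, self._slant(d))

    def _dmu_deta(self, eta, shape):
        (d,) = shape
        return stats.skewnorm.pdf(eta, self._slant(d))


class AEPLink(LinkSpec):
    """Asymmetric exponential power link.

    Two-piece exponential-power cdf with per-side mass 1/2, left tail
    shape theta1 and right tail shape theta2, each side scaled by
    2*Gamma(1 + 1/theta): for eta <= 0,

        F(eta) = Q(1/theta1, w) / 2,   w = (-2*eta*Gamma(1+1/theta1))**theta1,

    with Q the regularized upper incomplete gamma, and symmetrically
    above zero.  theta1 = theta2 = 1 gives the Laplace cdf; theta = 2 a
    rescaled normal.
    """

    name = "aep"
    n_shape_params = 2
    shape_bounds = ((0.0, None), (0.0, None))
    shape_names = ("theta1", "theta2")
    default_shape = (1.0, 1.0)
    analytic_shape_grad = False

    def _inverse(self, eta, shape):
        t1, t2 = shape
        eta1 = np.atleast_1d(eta)
        out = np.empty_like(eta1)
        neg = eta1 <= 0
        c1 = 2.0 * special.gamma(1.0 + 1.0 / t1)
        w1 = (-c1 * eta1[neg]) ** t1
        out[neg] = 0.5 * special.gammaincc(1.0 / t1, w1)
        c2 = 2.0 * special.gamma(1.0 + 1.0 / t2)
        w2 = (c2 * eta1[~neg]) ** t2
        out[~neg] = 1.0 - 0.5 * special.gammaincc(1.0 / t2, w2)
        return out.reshape(np.shape(eta))

    def _forward(self, mu, shape):
        t1, t2 = shape
        mu0 = mu
        mu = np.atleast_1d(mu)
        out = np.empty_like(mu)
        lo = mu <= 0.5
        c1 = 2.0 * special.gamma(1.0 + 1.0 / t1)
        w = special.gammainccinv(1.0 / t1, 2.0 * mu[lo])
        out[lo] = -(w ** (1.0 / t1)) / c1
        c2 = 2.0 * special.gamma(1.0 + 1.0 / t2)
        w = special.gammainccinv(1.0 / t2, 2.0 * (1.0 - mu[~lo]))
        out[~lo] = (w ** (1.0 / t2)) / c2
        return out.reshape(np.shape(mu0))

    def _dmu_deta(self, eta, shape):
        # the per-side normalization 2*Gamma(1+1/theta) makes the density
        # collapse to exp(-w): continuous with f(0) = 1 on both branches
        t1, t2 = shape
        eta = np.atleast_1d(eta)
        out = np.empty_like(eta)
        neg = eta < 0
        c1 = 2.0 * special.gamma(1.0 + 1.0 / t1)
        out[neg] = np.exp(-((-c1 * eta[neg]) ** t1))
        c2 = 2.0 * special.gamma(1.0 + 1.0 / t2)
        out[~neg] = np.exp(-((c2 * eta[~neg]) ** t2))
        return out


_REGISTRY = {
    cls.name: cls()
    for cls in (
        WeibullLink,
        ReflectedWeibullLink,
        LogitLink,
        ProbitLink,
        CLogLogLink,
        LogLogLink,
        ArandaOrdazLink,
        StukelLink,
        PrenticeLink,
        SkewProbitLink,
        AEPLink,
    )
}


def get_link(name) -> LinkSpec:
    """Look up a link family by registry name (or pass a LinkSpec through)."""
    if isinstance(name, LinkSpec):
        return name
    try:
        return _REGISTRY[name]
    except KeyError:
        raise LinkError(
            f"unknown link {name!r}; available: {', '.join(sorted(_REGISTRY))}"
        ) from None


def available_links():
    return sorted(_REGISTRY)
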