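"""Link catalog: values, inverses, derivatives, orientations, reductions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import expit

from skewlink import EtaDomainError, ShapeConstraintError, available_links, get_link

ALL_LINKS = available_links()

# admissible reference shapes per family (beyond the registry defaults)
SHAPES = {
    "weibull": [(0.5,), (1.0,), (2.0,), (3.60235,), (8.0,)],
    "rweibull": [(0.1742,), (0.5,), (1.0,), (2.3604,), (5.0,)],
    "logit": [()],
    "probit": [()],
    "cloglog": [()],
    "loglog": [()],
    "aranda": [(0.25,), (1.0,), (2.5,)],
    "stukel": [(0.0, 0.0), (0.5, -0.5), (-0.3, 0.8), (0.17, -0.97)],
    "prentice": [(1.0, 1.0), (0.5, 2.0), (3.0, 0.7)],
    "skewprobit": [(0.0,), (0.6,), (-0.9,)],
    "aep": [(1.0, 1.0), (0.5, 2.0), (2.0, 0.8)],
}


def _eta_grid(link):
    return np.linspace(0.01, 6.0, 500) if not link.supports_negative_eta else np.linspace(-8.0, 8.0, 500)


@pytest.mark.parametrize("name", ALL_LINKS)
def test_inverse_is_a_probability_and_monotone(name):
    link = get_link(name)
    eta = _eta_grid(link)
    for shape in SHAPES[name]:
        mu = link.inverse(eta, shape)
        assert np.all(mu >= 0) and np.all(mu <= 1)
        diffs = np.diff(mu)
        if link.increasing:
            assert np.all(diffs >= -1e-12)
        else:
            assert np.all(diffs <= 1e-12)


@pytest.mark.parametrize("name", ALL_LINKS)
def test_tail_limits(name):
    """inverse approaches {0, 1} toward the domain boundaries.

    The approach rate depends on the shape (a Weibull with gamma = 0.17
    needs eta ~ 50**(1/0.17) to saturate; Stukel with a negative tail
    parameter flattens logarithmically), so the probe point scales with
    the shape where needed.
    """
    link = get_link(name)
    for shape in SHAPES[name]:
        if name in ("weibull", "rweibull"):
            lo_eta = 1e-8 ** max(1.0, 1.0 / shape[0])
            hi_eta = 50.0 ** max(1.0, 1.0 / shape[0])
        elif name == "stukel":
            lo_eta, hi_eta = -1e6, 1e6
        else:
            lo_eta, hi_eta = -50.0, 50.0
        lo, hi = link.inverse(lo_eta, shape), link.inverse(hi_eta, shape)
        if not link.increasing:
            lo, hi = hi, lo
        assert lo < 1e-3
        assert hi > 1 - 1e-3


@pytest.mark.parametrize("name", ALL_LINKS)
def test_forward_inverse_round_trip(name):
    link = get_link(name)
    mu = np.array([0.05, 0.3, 0.5, 0.7, 0.95])
    for shape in SHAPES[name]:
        eta = link.forward(mu, shape)
        assert np.allclose(link.inverse(eta, shape), mu, atol=1e-10)


@settings(max_examples=200, derandomize=True)
@given(
    mu=st.floats(min_value=1e-6, max_value=1 - 1e-6),
    gamma=st.floats(min_value=0.2, max_value=20.0),
)
def test_weibull_round_trip_property(mu, gamma):
    """forward then inverse recovers any interior probability, any shape."""
    w = get_link("weibull")
    assert w.inverse(w.forward(mu, (gamma,)), (gamma,)) == pytest.approx(mu, abs=1e-9)
    rw = get_link("rweibull")
    assert rw.inverse(rw.forward(mu, (gamma,)), (gamma,)) == pytest.approx(mu, abs=1e-9)


@settings(max_examples=100, derandomize=True)
@given(
    eta=st.floats(min_value=-30.0, max_value=30.0),
    a1=st.floats(min_value=-1.5, max_value=1.5),
    a2=st.floats(min_value=-1.5, max_value=1.5),
)
def test_stukel_h_transform_is_monotone_property(eta, a1, a2):
    link = get_link("stukel")
    lo, hi = link.inverse(eta, (a1, a2)), link.inverse(eta + 0.01, (a1, a2))
    assert hi >= lo - 1e-12


def test_weibull_reference_values():
    w, rw = get_link("weibull"), get_link("rweibull")
    # vanishing predictor: cdf mass 0 (resp. 1) at the domain boundary
    assert w.inverse(1e-12, (2.0,)) < 1e-6
    assert rw.inverse(1e-12, (2.0,)) > 1 - 1e-6
    # fitted stage-1 snail parameters give the no-damage probability 0.595
    assert rw.inverse(0.0234, (0.1742,)) == pytest.approx(0.595, abs=5e-4)
    assert get_link("cloglog").inverse(0.0) == pytest.approx(1 - np.exp(-1), abs=1e-12)
    assert get_link("stukel").inverse(1.0, (0.0, 0.0)) == pytest.approx(expit(1.0), abs=1e-12)
    # closed-form forward values
    assert w.forward(1 - np.exp(-1), (1.0,)) == pytest.approx(1.0, abs=1e-12)
    assert w.forward(0.5, (2.0,)) == pytest.approx(np.sqrt(np.log(2.0)), abs=1e-12)


def test_special_case_reductions_match_reference_links():
    eta = np.linspace(-8, 8, 2001)
    logit_mu = expit(eta)
    assert np.max(np.abs(get_link("stukel").inverse(eta, (0.0, 0.0)) - logit_mu)) < 1e-12
    assert np.max(np.abs(get_link("prentice").inverse(eta, (1.0, 1.0)) - logit_mu)) < 1e-12
    assert np.max(np.abs(get_link("aranda").inverse(eta, (1.0,)) - logit_mu)) < 1e-12
    probit_mu = stats.norm.cdf(eta)
    assert np.max(np.abs(get_link("skewprobit").inverse(eta, (0.0,)) - probit_mu)) < 1e-12


def test_aep_is_continuous_at_zero_and_laplace_at_unit_shapes():
    aep = get_link("aep")
    for shape in SHAPES["aep"]:
        left = aep.inverse(-1e-12, shape)
        right = aep.inverse(1e-12, shape)
        assert left == pytest.approx(0.5, abs=1e-9)
        assert right == pytest.approx(0.5, abs=1e-9)
    # theta1 = theta2 = 1: two-sided exponential with scale 1/2
    eta = np.array([-0.7, -0.1, 0.3])
    expected = np.where(eta <= 0, np.exp(2 * eta) / 2, 1 - np.exp(-2 * eta) / 2)
    assert np.allclose(aep.inverse(eta, (1.0, 1.0)), expected, atol=1e-12)


@pytest.mark.parametrize("name", ALL_LINKS)
def test_eta_derivative_matches_finite_differences(name):
    link = get_link(name)
    eta = np.linspace(0.05, 3.0, 40) if not link.supports_negative_eta else np.linspace(-3.0, 3.0, 40)
    h = 1e-6
    for shape in SHAPES[name]:
        d_eta, _ = link.derivatives(eta, shape)
        fd = (link.inverse(eta + h, shape) - link.inverse(eta - h, shape)) / (2 * h)
        assert np.allclose(d_eta, fd, rtol=1e-5, atol=1e-8)


@pytest.mark.parametrize("name", ["weibull", "rweibull", "aranda", "stukel"])
def test_analytic_shape_gradients_match_finite_differences(name):
    link = get_link(name)
    eta = np.linspace(0.1, 3.0, 25) if not link.supports_negative_eta else np.linspace(-3.0, 3.0, 25)
    for shape in SHAPES[name]:
        _, d_shape = link.derivatives(eta, shape)
        for j, s in enumerate(shape):
            h = 1e-6 * max(1.0, abs(s))
            up = list(shape); up[j] = s + h
            dn = list(shape); dn[j] = s - h
            fd = (link.inverse(eta, tuple(up)) - link.inverse(eta, tuple(dn))) / (2 * h)
            assert np.allclose(d_shape[:, j], fd, rtol=2e-5, atol=1e-7), (name, j)


def test_weibull_derivative_reference_points():
    link = get_link("weibull")
    d_eta, d_shape = link.derivatives(1.0, (1.0,))
    assert d_eta[0] == pytest.approx(np.exp(-1.0), abs=1e-12)
    # at eta = 1, eta**gamma == 1 for all gamma, so dmu/dgamma = 0
    _, d_shape2 = link.derivatives(1.0, (2.0,))
    assert d_shape2[0, 0] == pytest.approx(0.0, abs=1e-14)


def test_domain_and_shape_errors_are_distinct():
    link = get_link("weibull")
    with pytest.raises(EtaDomainError):
        link.inverse(-0.5, (2.0,))
    with pytest.raises(ShapeConstraintError):
        link.inverse(0.5, (-1.0,))
    with pytest.raises(ShapeConstraintError):
        get_link("skewprobit").inverse(0.0, (1.5,))
    from skewlink import LinkError

    with pytest.raises(LinkError):
        get_link("logit").forward(1.2)
    with pytest.raises(LinkError):
        get_link("nosuch")
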