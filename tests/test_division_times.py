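"""Division-time distributions: densities, moments, transforms, sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from cyclostat import (BetaExponentialDivision, CustomDivision, DeltaDivision,
                       ErlangDivision, ExponentialDivision,
                       FluctuatingThresholdDivision,
                       GrowthRateHeterogeneityDivision,
                       calibrate_beta_exponential, division_model,
                       powell_age_weight)
from cyclostat.exceptions import ParameterError, UnsupportedOperationError

from conftest import MEAN_TS, standard_models


def continuous_models():
    return {
        "exponential": ExponentialDivision(20.0),
        "erlang": ErlangDivision(3, 0.15),
        "beta_exponential": calibrate_beta_exponential(20, 10, 20.0),
        "growth_rate_heterogeneity": GrowthRateHeterogeneityDivision(0.035, 0.0052),
        "fluctuating_threshold": FluctuatingThresholdDivision(0.035, 0.0052, 0.1),
    }


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def test_exponential_density_value():
    m = ExponentialDivision(20.0)
    assert m.density(20.0) == pytest.approx(math.exp(-1.0) / 20.0, rel=1e-12)


def test_erlang_n1_coincides_with_exponential():
    er = ErlangDivision(1, 0.05)
    ex = ExponentialDivision(20.0)
    for ts in (1.0, 10.0, 20.0, 75.0):
        assert er.density(ts) == pytest.approx(ex.density(ts), rel=1e-12)


@pytest.mark.parametrize("name", sorted(continuous_models()))
def test_density_normalized(name):
    m = continuous_models()[name]
    mass = integrate.quad(m.density, 0.0, m._upper(), limit=400,
                          points=list(m._points()))[0]
    assert mass == pytest.approx(1.0, abs=5e-9)


def test_delta_has_no_density():
    with pytest.raises(UnsupportedOperationError):
        DeltaDivision(20.0).density(20.0)


def test_invalid_parameters_rejected():
    with pytest.raises(ParameterError):
        BetaExponentialDivision(X=20, n0=20, beta=0.03)
    with pytest.raises(ParameterError):
        ErlangDivision(0, 0.1)
    with pytest.raises(ParameterError):
        division_model("no_such_family")


# ---------------------------------------------------------------------------
# moments and calibration
# ---------------------------------------------------------------------------

def test_moments_closed_forms():
    mean, cv2 = ErlangDivision(3, 0.15).moments()
    assert mean == pytest.approx(20.0, rel=1e-12)
    assert cv2 == pytest.approx(1.0 / 3.0, rel=1e-12)
    assert DeltaDivision(20.0).moments() == (20.0, 0.0)
    assert ExponentialDivision(20.0).moments() == (20.0, 1.0)


def test_beta_exponential_cv2_printed_value():
    # Beta-exponential with X = 20, n0 = X/2 calibrated to a 20-min mean has
    # CV^2 ~= 0.104, below the Erlang(3) value of 1/3
    m = calibrate_beta_exponential(20, 10, MEAN_TS)
    mean, cv2 = m.moments()
    assert mean == pytest.approx(MEAN_TS, rel=1e-12)
    assert round(cv2, 3) == 0.104


def test_calibrated_beta_matches_harmonic_mean_formula():
    m = calibrate_beta_exponential(20, 10, 20.0)
    harmonic = sum(1.0 / s for s in range(10, 20))
    assert m.beta == pytest.approx(harmonic / 20.0, rel=1e-14)
    # the calibrated mean must also come out of quadrature of the density
    quad_mean = integrate.quad(lambda t: t * m.density(t), 0, m._upper(), limit=400)[0]
    assert quad_mean == pytest.approx(20.0, rel=1e-8)


def test_calibrate_single_stage():
    m = calibrate_beta_exponential(2, 1, 1.0)
    assert m.beta == pytest.approx(1.0, rel=1e-14)
    assert m.moments() == (pytest.approx(1.0), pytest.approx(1.0))


# ---------------------------------------------------------------------------
# Laplace transform and Psi integrals
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name", sorted(standard_models()) +
                         ["growth_rate_heterogeneity", "fluctuating_threshold"])
def test_laplace_at_zero_is_one(name):
    m = {**standard_models(), **continuous_models()}[name]
    assert m.laplace(0.0) == pytest.approx(1.0, abs=1e-10)


def test_laplace_closed_forms():
    assert DeltaDivision(20.0).laplace(0.0) == 1.0
    assert ExponentialDivision(20.0).laplace(0.05) == pytest.approx(0.5, rel=1e-14)
    er = ErlangDivision(3, 0.15)
    assert er.laplace(0.01) == pytest.approx((0.15 / 0.16) ** 3, rel=1e-14)
    # closed form vs quadrature
    quad = integrate.quad(lambda t: math.exp(-0.01 * t) * er.density(t),
                          0, er._upper(), limit=400)[0]
    assert er.laplace(0.01) == pytest.approx(quad, rel=1e-10)


def test_beta_exponential_laplace_product_vs_quadrature():
    m = calibrate_beta_exponential(20, 10, 20.0)
    for s in (0.01, 0.02, 0.1):
        quad = integrate.quad(lambda t: math.exp(-s * t) * m.density(t),
                              0, m._upper(), limit=400)[0]
        assert m.laplace(s) == pytest.approx(quad, rel=1e-9)


def test_psi_delta_closed_form():
    m = DeltaDivision(20.0)
    g = 0.05
    e = math.exp(-g * 20.0)
    assert m.psi(2, 1, g) == pytest.approx(e * (1 - e), rel=1e-14)
    assert m.psi(0, 0, g) == 1.0


def test_psi_trivial_cases():
    for m in standard_models().values():
        assert m.psi(0, 0, 0.05) == 1.0
    assert ExponentialDivision(20.0).psi(1, 1, 0.05) == pytest.approx(0.5, rel=1e-12)


@pytest.mark.parametrize("name", ["exponential", "erlang", "beta_exponential",
                                  "fluctuating_threshold"])
def test_psi_expansion_matches_quadrature(name):
    # Psi_{k,j} by binomial Laplace expansion vs direct quadrature, k <= 10
    m = continuous_models()[name]
    g = 0.05
    for k in range(1, 11, 3):
        for j in range(0, k + 1, max(1, k // 2)):
            assert m.psi(k, j, g) == pytest.approx(m._psi_quad(k, j, g), abs=1e-8)


def test_psi_domain_errors():
    with pytest.raises(ParameterError):
        ExponentialDivision(20.0).psi(1, 2, 0.05)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(N=st.integers(1, 12), lam=st.floats(0.01, 1.0),
       s=st.floats(0.0, 0.5))
def test_laplace_bounds_and_monotonicity(N, lam, s):
    m = ErlangDivision(N, lam)
    L = m.laplace(s)
    assert 0.0 < L <= 1.0
    assert m.laplace(s + 0.1) < L or s + 0.1 == s


# ---------------------------------------------------------------------------
# Powell age weight
# ---------------------------------------------------------------------------

def test_powell_exponential_closed_form():
    w = powell_age_weight(ExponentialDivision(20.0))
    assert w.vm == pytest.approx(1.0 / 20.0, abs=1e-10)


def test_powell_erlang_closed_form():
    w = powell_age_weight(ErlangDivision(3, 0.15))
    assert w.vm == pytest.approx(0.15 * (2 ** (1.0 / 3.0) - 1.0), rel=1e-10)


def test_powell_delta_closed_form():
    w = powell_age_weight(DeltaDivision(20.0))
    assert w.vm == pytest.approx(math.log(2.0) / 20.0, rel=1e-10)


@pytest.mark.parametrize("name", sorted(standard_models()))
def test_powell_weight_normalized(name):
    w = powell_age_weight(standard_models()[name])
    assert w.norm_check == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def test_delta_sampling_is_constant():
    rng = np.random.default_rng(0)
    assert DeltaDivision(20.0).sample(rng) == 20.0
    assert np.all(DeltaDivision(20.0).sample(rng, 5) == 20.0)


def test_erlang_sampling_moments():
    rng = np.random.default_rng(1)
    s = ErlangDivision(3, 0.15).sample(rng, 100_000)
    assert s.mean() == pytest.approx(20.0, abs=0.1)
    assert s.var() / s.mean() ** 2 == pytest.approx(1.0 / 3.0, abs=0.01)


def test_beta_exponential_sampling_cv2():
    rng = np.random.default_rng(2)
    s = calibrate_beta_exponential(20, 10, 20.0).sample(rng, 100_000)
    assert s.var() / s.mean() ** 2 == pytest.approx(0.104, abs=0.005)


@pytest.mark.parametrize("name", ["exponential", "erlang", "beta_exponential",
                                  "fluctuating_threshold"])
def test_sampling_matches_density(name):
    # KS test of draws against the model's own distribution function
    m = continuous_models()[name]
    rng = np.random.default_rng(3)
    draws = np.asarray(m.sample(rng, 3000), dtype=float)

    if name == "erlang":
        res = stats.kstest(draws, lambda x: stats.gamma.cdf(x, 3, scale=1 / 0.15))
    else:
        grid = np.linspace(1e-6, m._upper(), 4000)
        pdf = np.array([m.density(t) for t in grid])
        cdf = integrate.cumulative_trapezoid(pdf, grid, initial=0.0)
        cdf /= cdf[-1]
        res = stats.kstest(draws, lambda x: np.interp(x, grid, cdf))
    assert res.pvalue > 1e-3


def test_custom_density_agrees_with_builtin():
    m = CustomDivision(lambda t: math.exp(-t / 20.0) / 20.0)
    ref = ExponentialDivision(20.0)
    assert m.laplace(0.05) == pytest.approx(ref.laplace(0.05), rel=1e-8)
    mean, cv2 = m.moments()
    assert mean == pytest.approx(20.0, rel=1e-6)
    assert cv2 == pytest.approx(1.0, rel=1e-5)
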