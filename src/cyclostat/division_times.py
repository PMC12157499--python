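r"""Cell-division-time distributions g(ts).

Every model exposes the handful of functionals the cyclo-stationary theory
actually consumes: the density g(ts), the Laplace transform
L(s) = E[exp(-s*ts)], the mixed integrals

    Psi_{k,j} = \int_0^inf g(ts) exp(-j*gamma*ts) (1 - exp(-gamma*ts))^{k-j} dts,

the first two moments, a sampler (for the kinetic Monte Carlo validator) and
the Powell age weight phi(tau) of an exponentially growing population.

Times are in minutes and rates in 1/min throughout.

Built-in families
-----------------
delta                       fixed division time T (point mass; no density)
exponential                 mean T, CV^2 = 1
erlang                      shape N, rate lam; mean N/lam, CV^2 = 1/N
beta_exponential            first passage of an autocatalytic process from n0
                            copies to a threshold X at rate beta; equivalently
                            a hypoexponential sum of X-n0 exponentials with
                            rates beta*s, s = n0..X-1
growth_rate_heterogeneity   deterministic exponential growth to a doubling
                            threshold with Gaussian growth rate N(beta0, sbeta^2)
fluctuating_threshold       as above but the log threshold also fluctuates,
                            Gaussian with SD sigma_x (normal-ratio density)
custom                      user-supplied density (and optional sampler)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import mpmath as mp
import numpy as np
from scipy import integrate, optimize, stats

from .exceptions import ParameterError, QuadratureError, UnsupportedOperationError

__all__ = [
    "DivisionTimeModel",
    "DeltaDivision",
    "ExponentialDivision",
    "ErlangDivision",
    "BetaExponentialDivision",
    "GrowthRateHeterogeneityDivision",
    "FluctuatingThresholdDivision",
    "CustomDivision",
    "AgeWeight",
    "division_model",
    "calibrate_beta_exponential",
    "powell_age_weight",
]

_QUAD_TOL = 1e-11


def _quad(f, lo, hi, points=None):
    kwargs = {"epsabs": 1e-13, "epsrel": 1e-11, "limit": 400}
    if points is not None and np.isfinite(hi):
        kwargs["points"] = [p for p in points if lo < p < hi]
    val, err = integrate.quad(f, lo, hi, **kwargs)
    if err > max(1e-8, 1e-6 * abs(val)):
        raise QuadratureError(
            f"quadrature error estimate {err:.3g} too large for value {val:.6g}"
        )
    return val


class DivisionTimeModel:
    """Base class: generic (quadrature-backed) implementations.

    Subclasses override with closed forms where they exist.
    """

    family: str = "custom"

    # -- density -----------------------------------------------------------
    def density(self, ts: float) -> float:
        raise NotImplementedError

    def _upper(self) -> float:
        """Upper integration limit with negligible tail mass."""
        raise NotImplementedError

    def _points(self) -> Sequence[float]:
        """Interior quadrature breakpoints (mode etc.)."""
        return (self.mean(),)

    # -- moments -----------------------------------------------------------
    def mean(self) -> float:
        return _quad(lambda t: t * self.density(t), 0.0, self._upper(),
                     self._points())

    def moments(self) -> tuple[float, float]:
        """Return (mean, CV^2)."""
        m = self.mean()
        m2 = _quad(lambda t: t * t * self.density(t), 0.0, self._upper(),
                   self._points())
        var = m2 - m * m
        return m, var / (m * m)

    # -- Laplace transform and Psi integrals --------------------------------
    def laplace(self, s: float) -> float:
        if s < 0:
            raise ParameterError("laplace argument must be >= 0")
        if s == 0:
            return 1.0
        return _quad(lambda t: math.exp(-s * t) * self.density(t),
                     0.0, self._upper(), self._points())

    def laplace_mp(self, s) -> mp.mpf:
        """High-precision Laplace value; closed-form families override.

        The generic fallback is the float quadrature lifted to an mpf, which
        bounds the attainable precision of downstream series at ~1e-12.
        """
        return mp.mpf(self.laplace(float(s)))

    def psi(self, k: int, j: int, gamma: float) -> float:
        """Psi_{k,j} via binomial expansion into Laplace values.

        (1-e^{-g t})^{k-j} = sum_r C(k-j,r) (-1)^r e^{-r g t}; compensated
        summation, with direct quadrature as a fallback when the alternating
        sum loses more than six digits.
        """
        if not (0 <= j <= k):
            raise ParameterError("psi requires 0 <= j <= k")
        if gamma <= 0:
            raise ParameterError("gamma must be positive")
        if k == j == 0:
            return 1.0
        terms = [
            (-1.0) ** r * math.comb(k - j, r) * self.laplace((j + r) * gamma)
            for r in range(k - j + 1)
        ]
        total = math.fsum(terms)
        scale = math.fsum(abs(t) for t in terms)
        if scale > 0 and abs(total) < 1e-6 * scale:
            return self._psi_quad(k, j, gamma)
        return total

    def _psi_quad(self, k: int, j: int, gamma: float) -> float:
        def f(t):
            e = math.exp(-gamma * t)
            return self.density(t) * math.exp(-j * gamma * t) * (1.0 - e) ** (k - j)

        return _quad(f, 0.0, self._upper(), self._points())

    def psi_mp(self, k: int, j: int, gamma) -> mp.mpf:
        """Psi_{k,j} at working mpmath precision (exact binomial expansion)."""
        if not (0 <= j <= k):
            raise ParameterError("psi requires 0 <= j <= k")
        if k == j == 0:
            return mp.mpf(1)
        total = mp.mpf(0)
        for r in range(k - j + 1):
            term = mp.mpf(math.comb(k - j, r)) * self.laplace_mp((j + r) * gamma)
            total += -term if r % 2 else term
        return total

    # -- survival and sampling ----------------------------------------------
    def survival(self, tau: float) -> float:
        """P(ts > tau)."""
        if tau <= 0:
            return 1.0
        hi = self._upper()
        if tau >= hi:
            return 0.0
        return _quad(self.density, tau, hi, self._points())

    def sample(self, rng: np.random.Generator, size=None):
        """Draw division times; generic route is inverse-CDF on a grid."""
        grid, cdf = self._cdf_grid()
        u = rng.random(size)
        return np.interp(u, cdf, grid)

    _grid_cache: Optional[tuple] = None

    def _cdf_grid(self, n: int = 10_000):
        if self._grid_cache is None:
            hi = self._upper()
            # log-spaced grid resolving both the head and the tail
            grid = np.concatenate(
                [[0.0], np.geomspace(hi * 1e-6, hi, n)]
            )
            pdf = np.array([self.density(max(t, 1e-300)) for t in grid])
            cdf = integrate.cumulative_trapezoid(pdf, grid, initial=0.0)
            cdf /= cdf[-1]
            self._grid_cache = (grid, cdf)
        return self._grid_cache

    # -- config -------------------------------------------------------------
    def config(self) -> dict:
        raise NotImplementedError

    def __repr__(self):  # pragma: no cover - cosmetic
        pairs = ", ".join(f"{k}={v}" for k, v in self.config()["params"].items())
        return f"{type(self).__name__}({pairs})"


class DeltaDivision(DivisionTimeModel):
    """Fixed division time: g(ts) = delta(ts - T).

    Represented symbolically; all integrals use closed forms and the density
    itself is deliberately not evaluable.
    """

    family = "delta"

    def __init__(self, T: float):
        if T <= 0:
            raise ParameterError("delta family requires T > 0")
        self.T = float(T)

    def density(self, ts):
        raise UnsupportedOperationError(
            "delta division-time model has no pointwise density; "
            "moments and transforms are computed analytically"
        )

    def mean(self):
        return self.T

    def moments(self):
        return self.T, 0.0

    def laplace(self, s):
        if s < 0:
            raise ParameterError("laplace argument must be >= 0")
        return math.exp(-s * self.T)

    def laplace_mp(self, s):
        return mp.e ** (-mp.mpf(s) * self.T)

    def psi(self, k, j, gamma):
        if not (0 <= j <= k):
            raise ParameterError("psi requires 0 <= j <= k")
        e = math.exp(-gamma * self.T)
        return e ** j * (1.0 - e) ** (k - j)

    def psi_mp(self, k, j, gamma):
        if not (0 <= j <= k):
            raise ParameterError("psi requires 0 <= j <= k")
        e = mp.e ** (-mp.mpf(gamma) * self.T)
        return e ** j * (1 - e) ** (k - j)

    def survival(self, tau):
        return 1.0 if tau < self.T else 0.0

    def sample(self, rng, size=None):
        if size is None:
            return self.T
        return np.full(size, self.T)

    def _upper(self):
        return self.T

    def config(self):
        return {"family": "delta", "params": {"T": self.T}}


class ExponentialDivision(DivisionTimeModel):
    """Exponential division times with mean T (CV^2 = 1)."""

    family = "exponential"

    def __init__(self, T: float):
        if T <= 0:
            raise ParameterError("exponential family requires mean T > 0")
        self.T = float(T)

    def density(self, ts):
        return math.exp(-ts / self.T) / self.T if ts > 0 else 0.0

    def mean(self):
        return self.T

    def moments(self):
        return self.T, 1.0

    def laplace(self, s):
        if s < 0:
            raise ParameterError("laplace argument must be >= 0")
        return 1.0 / (1.0 + s * self.T)

    def laplace_mp(self, s):
        return 1 / (1 + mp.mpf(s) * self.T)

    def survival(self, tau):
        return math.exp(-max(tau, 0.0) / self.T)

    def sample(self, rng, size=None):
        return rng.exponential(self.T, size)

    def _upper(self):
        return 60.0 * self.T

    def config(self):
        return {"family": "exponential", "params": {"T": self.T}}


class ErlangDivision(DivisionTimeModel):
    """Erlang(N, lam): sum of N exponential stages of rate lam.

    Mean N/lam, CV^2 = 1/N; interpolates between the exponential (N=1) and
    the fixed time (N -> inf).
    """

    family = "erlang"

    def __init__(self, N: int, lam: float):
        if int(N) != N or N < 1:
            raise ParameterError("erlang shape N must be a positive integer")
        if lam <= 0:
            raise ParameterError("erlang rate lam must be positive")
        self.N = int(N)
        self.lam = float(lam)

    def density(self, ts):
        if ts <= 0:
            return 0.0
        lg = (self.N * math.log(self.lam) + (self.N - 1) * math.log(ts)
              - self.lam * ts - math.lgamma(self.N))
        return math.exp(lg)

    def mean(self):
        return self.N / self.lam

    def moments(self):
        return self.N / self.lam, 1.0 / self.N

    def laplace(self, s):
        if s < 0:
            raise ParameterError("laplace argument must be >= 0")
        return (self.lam / (self.lam + s)) ** self.N

    def laplace_mp(self, s):
        lam = mp.mpf(self.lam)
        return (lam / (lam + mp.mpf(s))) ** self.N

    def survival(self, tau):
        return float(stats.gamma.sf(tau, self.N, scale=1.0 / self.lam))

    def sample(self, rng, size=None):
        return rng.gamma(self.N, 1.0 / self.lam, size)

    def _upper(self):
        return (self.N / self.lam) * (8.0 + 40.0 / self.N)

    def config(self):
        return {"family": "erlang", "params": {"N": self.N, "lam": self.lam}}


class BetaExponentialDivision(DivisionTimeModel):
    """First-passage time of autocatalytic growth from n0 to threshold X.

    g(ts) = beta exp(-beta n0 ts) (1 - exp(-beta ts))^(X-1-n0) / B(n0, X-n0).

    Equivalently the sum of X-n0 independent exponentials with rates beta*s,
    s = n0..X-1, which gives closed-form moments and Laplace transform:
    mean = (1/beta) sum 1/s, var = (1/beta^2) sum 1/s^2,
    L(u) = prod beta*s / (beta*s + u).
    """

    family = "beta_exponential"

    def __init__(self, X: int, n0: int, beta: float):
        if int(X) != X or int(n0) != n0:
            raise ParameterError("X and n0 must be integers")
        if not (0 < n0 < X):
            raise ParameterError("beta_exponential requires 0 < n0 < X")
        if beta <= 0:
            raise ParameterError("growth rate beta must be positive")
        self.X = int(X)
        self.n0 = int(n0)
        self.beta = float(beta)
        self._stages = np.arange(self.n0, self.X)  # rates beta*s

    def density(self, ts):
        if ts <= 0:
            return 0.0
        b, n0, X = self.beta, self.n0, self.X
        # log-safe: (1 - e^{-bt})^(X-1-n0)
        log1m = math.log1p(-math.exp(-b * ts)) if b * ts > 1e-12 else math.log(b * ts)
        lg = (math.log(b) - b * n0 * ts + (X - 1 - n0) * log1m
              - (math.lgamma(n0) + math.lgamma(X - n0) - math.lgamma(X)))
        return math.exp(lg)

    def mean(self):
        return float(np.sum(1.0 / self._stages)) / self.beta

    def moments(self):
        m = self.mean()
        var = float(np.sum(1.0 / self._stages.astype(float) ** 2)) / self.beta ** 2
        return m, var / (m * m)

    def laplace(self, s):
        if s < 0:
            raise ParameterError("laplace argument must be >= 0")
        r = self.beta * self._stages
        return float(np.exp(np.sum(np.log(r) - np.log(r + s))))

    def laplace_mp(self, s):
        s = mp.mpf(s)
        beta = mp.mpf(self.beta)
        out = mp.mpf(1)
        for st in self._stages:
            out *= beta * int(st) / (beta * int(st) + s)
        return out

    def survival(self, tau):
        if tau <= 0:
            return 1.0
        # partial fractions over distinct rates beta*s
        stages = self._stages.astype(float)
        terms = []
        for s in stages:
            others = stages[stages != s]
            coef = np.prod(others / (others - s))
            terms.append(coef * math.exp(-self.beta * s * tau))
        return min(1.0, max(0.0, math.fsum(terms)))

    def sample(self, rng, size=None):
        # first-passage construction: independent exponential stage times
        shape = (len(self._stages),) if size is None else (len(self._stages),) + tuple(np.atleast_1d(size))
        draws = rng.exponential(1.0, shape) / (self.beta * self._stages.reshape(
            (-1,) + (1,) * (len(shape) - 1)))
        tot = draws.sum(axis=0)
        return float(tot) if size is None else tot

    def _upper(self):
        return self.mean() + 60.0 / (self.beta * self.n0)

    def config(self):
        return {"family": "beta_exponential",
                "params": {"X": self.X, "n0": self.n0, "beta": self.beta}}


class FluctuatingThresholdDivision(DivisionTimeModel):
    """Division when exponential growth crosses a fluctuating threshold.

    Cell size grows deterministically as exp(beta t) with beta drawn
    N(beta0, sigma_beta^2) per cell; the log threshold ln(X/n0) fluctuates
    around ln 2 with SD sigma_x.  The division time is the normal ratio
    ln(X/n0)/beta with density

        g(ts) = (beta0 sx^2 + ln2 sb^2 ts) / sqrt(2 pi) / (sx^2+sb^2 ts^2)^1.5
                * exp( -(beta0 ts - ln2)^2 / (2 (sx^2 + sb^2 ts^2)) ).

    With sigma_x = 0 this reduces to the pure growth-rate-heterogeneity law.
    The far tail of a normal ratio decays only as ts^-2 with an exp(-beta0^2/
    (2 sigma_beta^2)) prefactor; the model is therefore truncated at a large
    upper limit where the residual mass is ~1e-10 at realistic parameters.
    """

    family = "fluctuating_threshold"

    def __init__(self, beta0: float, sigma_beta: float, sigma_x: float = 0.0):
        if beta0 <= 0:
            raise ParameterError("beta0 must be positive")
        if sigma_beta < 0 or sigma_x < 0:
            raise ParameterError("sigma_beta and sigma_x must be >= 0")
        if sigma_beta == 0 and sigma_x == 0:
            raise ParameterError("at least one of sigma_beta, sigma_x must be > 0")
        self.beta0 = float(beta0)
        self.sigma_beta = float(sigma_beta)
        self.sigma_x = float(sigma_x)

    _LN2 = math.log(2.0)

    def density(self, ts):
        if ts <= 0:
            return 0.0
        b0, sb, sx = self.beta0, self.sigma_beta, self.sigma_x
        v = sx * sx + sb * sb * ts * ts
        logpre = math.log(b0 * sx * sx + self._LN2 * sb * sb * ts) - 0.5 * math.log(
            2.0 * math.pi) - 1.5 * math.log(v)
        return math.exp(logpre - (b0 * ts - self._LN2) ** 2 / (2.0 * v))

    def _mode(self):
        return self._LN2 / self.beta0

    def _points(self):
        return (self._mode(),)

    def _upper(self):
        return 30.0 * self._LN2 / self.beta0

    def config(self):
        return {"family": self.family,
                "params": {"beta0": self.beta0, "sigma_beta": self.sigma_beta,
                           "sigma_x": self.sigma_x}}


class GrowthRateHeterogeneityDivision(FluctuatingThresholdDivision):
    """Fixed doubling threshold, Gaussian growth-rate heterogeneity."""

    family = "growth_rate_heterogeneity"

    def __init__(self, beta0: float, sigma_beta: float):
        if sigma_beta <= 0:
            raise ParameterError("sigma_beta must be positive")
        super().__init__(beta0, sigma_beta, 0.0)

    def config(self):
        return {"family": "growth_rate_heterogeneity",
                "params": {"beta0": self.beta0, "sigma_beta": self.sigma_beta}}


class CustomDivision(DivisionTimeModel):
    """User-supplied density on (0, inf), with optional sampler."""

    family = "custom"

    def __init__(self, density: Callable[[float], float],
                 sampler: Optional[Callable] = None,
                 upper: Optional[float] = None):
        self._density = density
        self._sampler = sampler
        self._upper_limit = upper

    def density(self, ts):
        return self._density(ts) if ts > 0 else 0.0

    def _upper(self):
        if self._upper_limit is not None:
            return self._upper_limit
        # expand until the tail is negligible
        hi = 1.0
        for _ in range(60):
            try:
                tail = integrate.quad(self._density, hi, 2 * hi, limit=200)[0]
                mass = integrate.quad(self._density, 0, hi, limit=200)[0]
            except Exception as exc:  # pragma: no cover
                raise QuadratureError(f"custom density not integrable: {exc}")
            if mass > 0.5 and tail < 1e-12 * mass:
                self._upper_limit = 2 * hi
                return self._upper_limit
            hi *= 2
        raise QuadratureError("could not bracket the tail of the custom density")

    def _points(self):
        return ()

    def sample(self, rng, size=None):
        if self._sampler is not None:
            return self._sampler(rng, size)
        return super().sample(rng, size)

    def config(self):
        return {"family": "custom", "params": {}}


_FAMILIES = {
    "delta": DeltaDivision,
    "exponential": ExponentialDivision,
    "erlang": ErlangDivision,
    "beta_exponential": BetaExponentialDivision,
    "growth_rate_heterogeneity": GrowthRateHeterogeneityDivision,
    "fluctuating_threshold": FluctuatingThresholdDivision,
    "custom": CustomDivision,
}


def division_model(family: str, **params) -> DivisionTimeModel:
    """Factory used by config files: division_model("erlang", N=3, lam=0.15)."""
    try:
        cls = _FAMILIES[family]
    except KeyError:
        raise ParameterError(
            f"unknown division-time family {family!r}; choose from {sorted(_FAMILIES)}"
        )
    return cls(**params)


def calibrate_beta_exponential(X: int, n0: int, target_mean: float) -> BetaExponentialDivision:
    """Choose beta so the first-passage mean (1/beta) sum_{s=n0}^{X-1} 1/s
    equals ``target_mean``."""
    if not (0 < n0 < X):
        raise ParameterError("calibration requires 0 < n0 < X")
    if target_mean <= 0:
        raise ParameterError("target_mean must be positive")
    harmonic = math.fsum(1.0 / s for s in range(n0, X))
    return BetaExponentialDivision(X, n0, harmonic / target_mean)


@dataclass
class AgeWeight:
    """Powell age density phi(tau) = 2 vm exp(-vm tau) P(ts > tau).

    ``vm`` is the population growth exponent solving 2 L(vm) = 1.
    """

    vm: float
    survival: Callable[[float], float]
    tau_max: float
    norm_check: float = field(default=float("nan"))

    def phi(self, tau: float) -> float:
        if tau < 0:
            return 0.0
        return 2.0 * self.vm * math.exp(-self.vm * tau) * self.survival(tau)


def powell_age_weight(model: DivisionTimeModel) -> AgeWeight:
    """Solve 2 L(vm) = 1 by bracketed root-finding and build the age weight."""
    mean = model.mean()
    lo, hi = 1e-12 / mean, 10.0 * math.log(2.0) / mean
    f = lambda v: 2.0 * model.laplace(v) - 1.0
    if f(lo) <= 0 or f(hi) >= 0:
        raise QuadratureError("could not bracket the Powell growth exponent vm")
    vm = optimize.brentq(f, lo, hi, xtol=1e-14, rtol=1e-14)

    if isinstance(model, DeltaDivision):
        tau_max = model.T
    else:
        # point where the survival drops below 1e-10
        hi_t = model._upper()
        tau_max = hi_t
        lo_t = 0.0
        for _ in range(200):
            mid = 0.5 * (lo_t + tau_max)
            if model.survival(mid) > 1e-10:
                lo_t = mid
            else:
                tau_max = mid
            if tau_max - lo_t < 1e-6 * tau_max:
                break

    weight = AgeWeight(vm=vm, survival=model.survival, tau_max=tau_max)
    weight.norm_check = _quad(weight.phi, 0.0, tau_max)
    return weight
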