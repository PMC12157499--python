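"""Cell-age-resolved and age-averaged cyclo-stationary distributions.

The distribution at age tau (time since the last division) follows from the
birth-state factorial moments F^(k)(1) by replacing them with the
age-propagated coefficients G^(k)(tau):

mRNA:     G^(k)(tau) = sum_j C(k,j) (km/gm)^(k-j) F^(j) e^(-j gm tau)
                       (1 - e^(-gm tau))^(k-j)
protein:  G^(k)(tau) = a k! sum_{l,j} (-1)^l b^(k-j) e^(-(l+j) gp tau)
                       (a+k-l-j-1)! F^(j) / [(a-l)! l! j! (k-l-j)!]

(with the same falling/rising-factorial evaluation as the recursion itself);
at tau = 0 these reduce to F^(k)(1).  The same series inversion as for the
birth state then yields Pss(y, tau).

Age-averaged distributions integrate Pss(y, tau) against the Powell age
weight phi(tau) of an exponentially growing population.

An independent *propagator* route is also provided: the distribution at age
tau is the birth distribution thinned binomially by molecule survival
e^(-gamma tau), convolved with the distribution of molecules made since
birth (Poisson for mRNA; for bursty proteins computed by FFT inversion of
the transient generating function).  Averaging the age-tau propagator over
g(ts) itself gives the pre-division distribution, which is the practical
route for protein parameters where the 2^k-rescaled series would need a very
large truncation order.
"""

from __future__ import annotations

import math
from typing import List, Optional

import mpmath as mp
import numpy as np
from scipy import stats

from .coefficients import CoefficientTable, GeneParams
from .division_times import AgeWeight, DeltaDivision, DivisionTimeModel
from .exceptions import ParameterError
from .series_inversion import PMFResult, _invert

__all__ = [
    "age_coefficients",
    "pmf_at_age",
    "age_averaged_pmf",
    "propagated_pmf_at_age",
    "propagated_pmf_before_division",
]


def age_coefficients(table: CoefficientTable, tau: float) -> List[mp.mpf]:
    """Coefficients G^(k)(tau), k = 0..K, of the age-tau distribution."""
    if tau < 0:
        raise ParameterError("cell age tau must be >= 0")
    K = table.K
    p = table.params
    with mp.workdps(table.dps):
        F = table.values
        if table.species == "mrna":
            gm = mp.mpf(p.gamma_m)
            c = mp.mpf(p.km) / gm
            e = mp.e ** (-gm * tau)
            G = []
            for k in range(K + 1):
                tot = mp.mpf(0)
                for j in range(k + 1):
                    tot += (mp.mpf(math.comb(k, j)) * c ** (k - j) * F[j]
                            * e ** j * (1 - e) ** (k - j))
                G.append(tot)
            return G
        # protein
        a = mp.mpf(p.km) / mp.mpf(p.gamma_p)
        b = mp.mpf(p.b)
        e = mp.e ** (-mp.mpf(p.gamma_p) * tau)
        epow = [e ** i for i in range(K + 1)]
        fact = [mp.factorial(i) for i in range(K + 1)]
        inv_fact = [1 / f for f in fact]
        w = [mp.mpf(1)]
        for l in range(1, K + 1):
            w.append(-w[-1] * (a - l + 1) / l)
        v = [mp.mpf(1)]
        for m in range(1, K + 1):
            v.append(v[-1] * (a + m - 1) / m)
        bpow = [b ** i for i in range(K + 1)]
        G = []
        for k in range(K + 1):
            tot = mp.mpf(0)
            for j in range(k + 1):
                s = mp.mpf(0)
                for l in range(k - j + 1):
                    s += epow[l + j] * w[l] * v[k - j - l]
                tot += fact[k] * inv_fact[j] * bpow[k - j] * s * F[j]
            G.append(tot)
        return G


def pmf_at_age(table: CoefficientTable, tau: float,
               ymax: Optional[int] = None) -> PMFResult:
    """Cyclo-stationary PMF at cell age tau; tau = 0 reproduces the birth PMF."""
    G = age_coefficients(table, tau)
    if ymax is None:
        with mp.workdps(table.dps):
            k1, k2 = G[1], G[1] + G[2] - G[1] ** 2
            ymax = max(5, int(mp.ceil(k1 + 8 * mp.sqrt(abs(k2)))))
    res = _invert(G, table.dps, int(ymax), "age")
    res.convergence["tau"] = float(tau)
    return res


def age_averaged_pmf(table: CoefficientTable, weight: AgeWeight,
                     ymax: Optional[int] = None, nodes: int = 64) -> PMFResult:
    """Population (age-averaged) PMF: int_0^inf phi(tau) Pss(y, tau) dtau.

    Gauss-Legendre quadrature on (0, tau_max) where the survival (hence phi)
    has decayed; the PMF is evaluated per node.
    """
    if ymax is None:
        # the age-averaged support is bounded by the pre-division one
        ymax = pmf_at_age(table, 0.0).support[-1] * 2
    x, wq = np.polynomial.legendre.leggauss(nodes)
    hi = weight.tau_max
    taus = 0.5 * hi * (x + 1.0)
    probs = np.zeros(int(ymax) + 1)
    wsum = 0.0
    for t, wi in zip(taus, wq):
        phi = weight.phi(float(t))
        if phi == 0.0:
            continue
        node_pmf = pmf_at_age(table, float(t), int(ymax))
        probs += 0.5 * hi * wi * phi * node_pmf.probabilities
        wsum += 0.5 * hi * wi * phi
    res = PMFResult(
        support=np.arange(int(ymax) + 1),
        probabilities=probs,
        state="age_averaged",
        method="quadrature",
        convergence={"nodes": nodes, "tau_max": hi, "weight_mass": wsum},
    )
    res.convergence["normalization_deficit"] = res.normalization_deficit
    return res


# ---------------------------------------------------------------------------
# propagator route (float precision, independent of the series inversion)
# ---------------------------------------------------------------------------

def _new_molecule_pmf(params: GeneParams, species: str, tau: float,
                      n: int) -> np.ndarray:
    """Distribution of molecules produced since birth, at age tau.

    mRNA: Poisson with mean (km/gm)(1 - e^(-gm tau)).  Protein: FFT
    inversion of the transient generating function
    [(1 - b(q-1)e^(-gp tau)) / (1 - b(q-1))]^a, analytic on |q| <= 1.
    """
    if species == "mrna":
        lam = params.km / params.gamma_m * (1.0 - math.exp(-params.gamma_m * tau))
        return stats.poisson.pmf(np.arange(n), lam)
    a, b = params.a, params.b
    e = math.exp(-params.gamma_p * tau)
    N = 1
    while N < 4 * n:
        N *= 2
    q = np.exp(2j * np.pi * np.arange(N) / N)
    H = ((1.0 - b * (q - 1.0) * e) / (1.0 - b * (q - 1.0))) ** a
    pmf = np.fft.fft(H).real / N
    return np.clip(pmf[:n], 0.0, None)


def propagated_pmf_at_age(birth: PMFResult, params: GeneParams, species: str,
                          tau: float, ymax: int) -> PMFResult:
    """Pss(y, tau) from the birth PMF via the exact within-cycle propagator:
    binomial thinning of survivors plus independent new production."""
    if tau < 0:
        raise ParameterError("cell age tau must be >= 0")
    p0 = birth.probabilities
    n0 = len(p0)
    esurv = math.exp(-(params.gamma_m if species == "mrna" else params.gamma_p) * tau)
    # survivor distribution: sum_n p0[n] Binomial(n, esurv)
    surv = np.zeros(n0)
    counts = np.arange(n0)
    for n, pn in enumerate(p0):
        if pn > 0:
            surv[: n + 1] += pn * stats.binom.pmf(counts[: n + 1], n, esurv)
    new = _new_molecule_pmf(params, species, tau, int(ymax) + 1)
    probs = np.convolve(surv, new)[: int(ymax) + 1]
    res = PMFResult(
        support=np.arange(int(ymax) + 1),
        probabilities=probs,
        state="age",
        method="propagator",
        convergence={"tau": float(tau), "birth_mass": float(p0.sum())},
    )
    res.convergence["normalization_deficit"] = res.normalization_deficit
    return res


def propagated_pmf_before_division(birth: PMFResult, params: GeneParams,
                                   species: str, model: DivisionTimeModel,
                                   ymax: int, nodes: int = 48) -> PMFResult:
    """Pre-division PMF as the g(ts)-weighted mixture of age-ts states.

    This is the float-precision alternative to the 2^k-rescaled series and
    is exact up to quadrature and the truncation of the birth support.
    """
    if isinstance(model, DeltaDivision):
        res = propagated_pmf_at_age(birth, params, species, model.T, ymax)
        res.state = "pre_division"
        return res
    x, wq = np.polynomial.legendre.leggauss(nodes)
    hi = model._upper()
    ts = 0.5 * hi * (x + 1.0)
    probs = np.zeros(int(ymax) + 1)
    wsum = 0.0
    for t, wi in zip(ts, wq):
        g = model.density(float(t))
        if g <= 0.0:
            continue
        node = propagated_pmf_at_age(birth, params, species, float(t), ymax)
        probs += 0.5 * hi * wi * g * node.probabilities
        wsum += 0.5 * hi * wi * g
    res = PMFResult(
        support=np.arange(int(ymax) + 1),
        probabilities=probs,
        state="pre_division",
        method="propagator",
        convergence={"nodes": nodes, "weight_mass": wsum},
    )
    res.convergence["normalization_deficit"] = res.normalization_deficit
    return res
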