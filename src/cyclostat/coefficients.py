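"""Derivative coefficients F^(k)(1) of the birth-state generating function.

In the cyclo-stationary state the generating function F(q) of the copy
number in newborn cells satisfies a fixed-point equation whose expansion
about q = 1,

    F(q) = sum_k (q-1)^k / k! * F^(k)(1),

turns into an exact linear recursion for the factorial moments F^(k)(1).
For mRNA the recursion couples through the mixed integrals Psi_{k,j} of the
division-time law; for bursty protein production it couples through the
Laplace transform values L_s = L(s * gamma_p) alone.

The printed recursions contain the unknown F^(k)(1) on both sides (the
j = k term); each order is solved as a one-variable linear equation, so no
fixed-point iteration is involved.  The coefficients grow super-exponentially
in k and are therefore computed and stored at configurable mpmath precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Optional

import mpmath as mp

from .division_times import DivisionTimeModel, division_model
from .exceptions import ParameterError

__all__ = [
    "GeneParams",
    "CoefficientTable",
    "mrna_coefficients",
    "protein_coefficients",
    "fixed_T_mrna_closed_form",
    "default_dps",
]


@dataclass(frozen=True)
class GeneParams:
    """Kinetic rates of the constitutive gene-expression model.

    km      transcription rate (mRNA) or burst-arrival rate (protein), 1/min
    gamma_m mRNA decay rate, 1/min
    b       mean geometric burst size (proteins per burst)
    gamma_p protein decay rate, 1/min

    The dimensionless ratio a = km/gamma_p sets the mean protein level.
    """

    km: float
    gamma_m: float = 1.0
    b: float = 1.0
    gamma_p: float = 1.0

    def __post_init__(self):
        if self.km < 0:
            raise ParameterError("km must be >= 0")
        for name in ("gamma_m", "b", "gamma_p"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")

    @property
    def a(self) -> float:
        return self.km / self.gamma_p

    def as_dict(self) -> dict:
        return {"km": self.km, "gamma_m": self.gamma_m,
                "b": self.b, "gamma_p": self.gamma_p}


def default_dps(K: int) -> int:
    """Working decimal digits for a truncation order K.

    200 digits are ample up to K ~ 150; beyond that the alternating sums in
    the protein recursion and the Borel transform lose ~2 digits per order.
    """
    return max(200, int(math.ceil(2.2 * K)))


@dataclass
class CoefficientTable:
    """F^(k)(1), k = 0..K, at mpmath precision ``dps`` (magnitude-safe)."""

    species: str                      # "mrna" | "protein"
    K: int
    values: List[mp.mpf]
    params: GeneParams
    model: Optional[DivisionTimeModel]
    dps: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.species not in ("mrna", "protein"):
            raise ParameterError("species must be 'mrna' or 'protein'")

    def __len__(self):
        return len(self.values)

    # -- serialization (sign, log10 magnitude) ------------------------------
    def to_json(self) -> str:
        with mp.workdps(self.dps + 10):
            vals = []
            for v in self.values:
                if v == 0:
                    vals.append([0, "0"])
                else:
                    vals.append([1 if v > 0 else -1,
                                 mp.nstr(mp.log10(abs(v)), self.dps, strip_zeros=False)])
        return json.dumps({
            "species": self.species,
            "K": self.K,
            "dps": self.dps,
            "params": self.params.as_dict(),
            "model": self.model.config() if self.model is not None else None,
            "log10_values": vals,
        })

    @classmethod
    def from_json(cls, text: str) -> "CoefficientTable":
        obj = json.loads(text)
        params = GeneParams(**obj["params"])
        model = None
        if obj["model"] is not None:
            model = division_model(obj["model"]["family"], **obj["model"]["params"])
        dps = obj["dps"]
        with mp.workdps(dps + 10):
            values = [mp.mpf(sign) * mp.power(10, mp.mpf(lg)) if sign else mp.mpf(0)
                      for sign, lg in obj["log10_values"]]
        return cls(species=obj["species"], K=obj["K"], values=values,
                   params=params, model=model, dps=dps)


def mrna_coefficients(params: GeneParams, model: DivisionTimeModel, K: int,
                      dps: Optional[int] = None) -> CoefficientTable:
    """mRNA factorial moments at birth from the exact Psi recursion:

        2^k F^(k) = sum_{j<=k} C(k,j) (km/gm)^(k-j) Psi_{k,j} F^(j),

    solved per order for F^(k) (the j=k term uses Psi_{k,k} = L(k gm))."""
    if K < 0:
        raise ParameterError("K must be >= 0")
    dps = default_dps(K) if dps is None else int(dps)
    if dps < 30:
        raise ParameterError("precision too low; use at least 30 digits")
    with mp.workdps(dps):
        gm = mp.mpf(params.gamma_m)
        c = mp.mpf(params.km) / gm
        L = [model.laplace_mp(i * gm) for i in range(K + 1)]

        def psi(k, j):
            tot = mp.mpf(0)
            for r in range(k - j + 1):
                t = mp.mpf(math.comb(k - j, r)) * L[j + r]
                tot += -t if r % 2 else t
            return tot

        F = [mp.mpf(1)]
        for k in range(1, K + 1):
            s = mp.mpf(0)
            for j in range(k):
                s += mp.mpf(math.comb(k, j)) * c ** (k - j) * psi(k, j) * F[j]
            F.append(s / (mp.mpf(2) ** k - L[k]))
    return CoefficientTable("mrna", K, F, params, model, dps)


def protein_coefficients(params: GeneParams, model: DivisionTimeModel, K: int,
                         dps: Optional[int] = None) -> CoefficientTable:
    """Protein (bursty production) factorial moments at birth.

    The exact recursion, solved per order for F^(k),

        2^k F^(k) = a k! sum_{l,j} (-1)^l b^(k-j) L_{l+j}
                    (a+k-l-j-1)! / [(a-l)! l! j! (k-l-j)!] F^(j),

    with the real-a factorial ratio evaluated as
    falling(a, l) * rising(a, k-l-j); for integer a the falling factorial
    vanishes for l > a, which is the reciprocal-gamma convention."""
    if K < 0:
        raise ParameterError("K must be >= 0")
    dps = default_dps(K) if dps is None else int(dps)
    if dps < max(30, K // 2):
        raise ParameterError(
            f"precision {dps} digits is insufficient for K={K}; "
            f"use at least {max(30, K // 2)} (default {default_dps(K)})")
    with mp.workdps(dps):
        gp = mp.mpf(params.gamma_p)
        a = mp.mpf(params.km) / gp
        b = mp.mpf(params.b)
        L = [model.laplace_mp(i * gp) for i in range(K + 1)]
        fact = [mp.factorial(i) for i in range(K + 1)]
        inv_fact = [1 / f for f in fact]
        # w[l] = (-1)^l falling(a,l)/l!,  v[m] = rising(a,m)/m!
        w = [mp.mpf(1)]
        for l in range(1, K + 1):
            w.append(-w[-1] * (a - l + 1) / l)
        v = [mp.mpf(1)]
        for m in range(1, K + 1):
            v.append(v[-1] * (a + m - 1) / m)
        bpow = [b ** i for i in range(K + 1)]

        F = [mp.mpf(1)]
        for k in range(1, K + 1):
            tot = mp.mpf(0)
            for j in range(k):
                s = mp.mpf(0)
                for l in range(k - j + 1):
                    s += L[l + j] * w[l] * v[k - j - l]
                tot += fact[k] * inv_fact[j] * bpow[k - j] * s * F[j]
            F.append(tot / (mp.mpf(2) ** k - L[k]))
    return CoefficientTable("protein", K, F, params, model, dps)


def fixed_T_mrna_closed_form(params: GeneParams, T: float) -> tuple[float, float]:
    """Poisson means of the mRNA count for a fixed division time T.

    Birth and pre-division states are exactly Poisson with means
    d = (km/gm)(1-e^{-gm T})/(2-e^{-gm T}) and 2d."""
    if T <= 0:
        raise ParameterError("T must be positive")
    e = math.exp(-params.gamma_m * T)
    d = (params.km / params.gamma_m) * (1.0 - e) / (2.0 - e)
    return d, 2.0 * d
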