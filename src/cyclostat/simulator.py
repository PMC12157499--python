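"""Kinetic Monte Carlo simulation of a single lineage across division cycles.

An exact stochastic simulation (Gillespie direct method) of constitutive
expression inside each cell cycle, punctuated by binomial partitioning of the
copy number at division, following one daughter per division.  Serves as the
independent validation oracle for the analytic series results.

Models (rates in 1/min):
  mRNA    : birth at km, first-order decay at gamma_m * m
  protein : bursty production in the fast-mRNA-turnover limit -- burst
            arrivals at km with geometric burst size P(r) = b^r/(1+b)^(1+r)
            (mean b), first-order decay at gamma_p * n

Division times are drawn from a DivisionTimeModel; successive cycle times may
be correlated through the AR(1)-style mixture
ts_i = (1-eps) * fresh draw + eps * ts_(i-1), which preserves the mean and has
lag-1 autocorrelation eps.

The per-cycle reaction loops are compiled with numba; division times and
per-history seeds are pre-drawn with a seeded numpy Generator so runs are
reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from numba import njit

from .coefficients import GeneParams
from .division_times import DivisionTimeModel
from .exceptions import ParameterError

__all__ = [
    "SimConfig",
    "Histogram",
    "simulate_cycle",
    "binomial_partition",
    "next_division_time",
    "draw_division_times",
    "run_lineage",
]


@dataclass
class SimConfig:
    """Configuration of a lineage simulation.

    Each of ``n_histories`` independent lineages runs ``burn_in_cycles``
    unrecorded cycles (forgetting the initial condition through repeated
    halving) followed by ``record_cycles`` recorded ones; every recorded
    cycle contributes one sample per requested state.
    """

    species: str
    params: GeneParams
    model: DivisionTimeModel
    n_histories: int = 100
    burn_in_cycles: int = 100
    record_cycles: int = 100
    taus: Sequence[float] = field(default_factory=tuple)  # ages to snapshot
    correlation_eps: float = 0.0
    seed: int = 0
    max_count: int = 1024

    def __post_init__(self):
        if self.species not in ("mrna", "protein"):
            raise ParameterError("species must be 'mrna' or 'protein'")
        if self.n_histories < 1 or self.burn_in_cycles < 1 or self.record_cycles < 1:
            raise ParameterError("histories and cycle counts must be >= 1")
        if not (0.0 <= self.correlation_eps < 1.0):
            raise ParameterError("correlation_eps must lie in [0, 1)")


@dataclass
class Histogram:
    """Counts per copy number for one recorded state."""

    counts: np.ndarray
    n_samples: int
    label: str

    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_samples

    def total_variation(self, pmf: np.ndarray) -> float:
        """TV distance to an analytic PMF (tail mass lumped into one bin)."""
        f = self.frequencies()
        n = max(len(f), len(pmf))
        fa = np.zeros(n)
        pa = np.zeros(n)
        fa[: len(f)] = f
        pa[: len(pmf)] = pmf
        return 0.5 * (np.abs(fa - pa).sum() + abs((1 - fa.sum()) - (1 - pa.sum())))


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=False)
def _cycle(y, ts, km, gamma, b, is_protein, taus, snap):
    """Gillespie direct method from age 0 to ts; fills ``snap`` with the
    copy number at each requested age < ts (-1 where ts <= tau)."""
    t = 0.0
    itau = 0
    ntau = taus.shape[0]
    for i in range(ntau):
        snap[i] = -1
    while True:
        rate = km + gamma * y
        if rate <= 0.0:
            dt = ts - t + 1.0
        else:
            dt = np.random.exponential(1.0 / rate)
        t_new = t + dt
        while itau < ntau and taus[itau] < ts and taus[itau] <= min(t_new, ts):
            snap[itau] = y
            itau += 1
        if t_new >= ts:
            return y
        t = t_new
        if np.random.random() * rate < km:
            if is_protein:
                y += np.random.geometric(1.0 / (1.0 + b)) - 1
            else:
                y += 1
        else:
            y -= 1


@njit(cache=False)
def _run(ts_mat, seeds, km, gamma, b, is_protein, burn_in, taus, max_count):
    n_hist, n_cycles = ts_mat.shape
    birth = np.zeros(max_count + 1, np.int64)
    pre = np.zeros(max_count + 1, np.int64)
    age = np.zeros((taus.shape[0], max_count + 1), np.int64)
    age_n = np.zeros(taus.shape[0], np.int64)
    snap = np.empty(taus.shape[0], np.int64)
    overflow = 0
    for h in range(n_hist):
        np.random.seed(seeds[h])
        y = 0
        for c in range(n_cycles):
            record = c >= burn_in
            if record:
                y = _cycle(y, ts_mat[h, c], km, gamma, b, is_protein, taus, snap)
                for i in range(taus.shape[0]):
                    if snap[i] >= 0:
                        if snap[i] <= max_count:
                            age[i, snap[i]] += 1
                        else:
                            overflow += 1
                        age_n[i] += 1
                if y <= max_count:
                    pre[y] += 1
                else:
                    overflow += 1
            else:
                y = _cycle(y, ts_mat[h, c], km, gamma, b, is_protein,
                           taus[:0], snap[:0])
            y = np.random.binomial(y, 0.5)
            if record:
                if y <= max_count:
                    birth[y] += 1
                else:
                    overflow += 1
    return birth, pre, age, age_n, overflow


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate_cycle(y0: int, ts: float, params: GeneParams, species: str,
                   rng: np.random.Generator,
                   taus: Sequence[float] = ()) -> tuple[int, np.ndarray]:
    """One exact SSA cycle from age 0 to ts starting at copy number y0.

    Returns (copy number at ts, snapshots at the requested ages; -1 where
    the cycle is shorter than the age)."""
    if ts <= 0:
        raise ParameterError("cycle duration must be positive")
    is_protein = species == "protein"
    gamma = params.gamma_p if is_protein else params.gamma_m
    np.random.seed(int(rng.integers(0, 2 ** 31 - 1)))
    snap = np.empty(len(taus), np.int64)
    y = _cycle(int(y0), float(ts), params.km, gamma, params.b,
               is_protein, np.asarray(taus, dtype=np.float64), snap)
    return int(y), snap


def binomial_partition(y: int, rng: np.random.Generator) -> int:
    """Binomial(y, 1/2) draw: the copy number inherited by the followed
    daughter."""
    if y < 0:
        raise ParameterError("copy number must be >= 0")
    return int(rng.binomial(y, 0.5))


def next_division_time(model: DivisionTimeModel, previous_ts: Optional[float],
                       eps: float, rng: np.random.Generator) -> float:
    """Division time of the next cycle.

    eps = 0 gives i.i.d. draws from g; eps > 0 mixes in the previous cycle
    time, ts_i = (1-eps) * draw + eps * ts_(i-1), preserving the mean and
    giving lag-1 autocorrelation eps.  The first cycle is a fresh draw."""
    if not (0.0 <= eps < 1.0):
        raise ParameterError("eps must lie in [0, 1)")
    fresh = float(model.sample(rng))
    if previous_ts is None or eps == 0.0:
        return fresh
    return (1.0 - eps) * fresh + eps * float(previous_ts)


def draw_division_times(model: DivisionTimeModel, n_hist: int, n_cycles: int,
                        eps: float, rng: np.random.Generator) -> np.ndarray:
    """Matrix of cycle times (n_hist, n_cycles) with optional correlation."""
    fresh = np.asarray(model.sample(rng, (n_hist, n_cycles)), dtype=np.float64)
    if eps == 0.0:
        return fresh
    ts = np.empty_like(fresh)
    ts[:, 0] = fresh[:, 0]
    for c in range(1, n_cycles):
        ts[:, c] = (1.0 - eps) * fresh[:, c] + eps * ts[:, c - 1]
    return ts


def run_lineage(config: SimConfig) -> Dict[str, Histogram]:
    """Simulate the lineage ensemble and return histograms of the birth,
    pre-division, and requested age-tau states (ages conditioned on
    ts > tau)."""
    rng = np.random.default_rng(config.seed)
    n_cycles = config.burn_in_cycles + config.record_cycles
    ts_mat = draw_division_times(config.model, config.n_histories, n_cycles,
                                 config.correlation_eps, rng)
    seeds = np.random.SeedSequence(config.seed).generate_state(
        config.n_histories).astype(np.int64) % (2 ** 31 - 1)
    taus = np.asarray(config.taus, dtype=np.float64)
    is_protein = config.species == "protein"
    gamma = config.params.gamma_p if is_protein else config.params.gamma_m
    birth, pre, age, age_n, overflow = _run(
        ts_mat, seeds, config.params.km, gamma, config.params.b,
        is_protein, config.burn_in_cycles, taus, config.max_count)
    if overflow:
        raise ParameterError(
            f"{overflow} samples exceeded max_count={config.max_count}; increase it")
    n = config.n_histories * config.record_cycles
    out = {
        "birth": Histogram(birth, n, "birth"),
        "pre_division": Histogram(pre, n, "pre_division"),
    }
    for i, tau in enumerate(taus):
        out[f"age_{tau:g}"] = Histogram(age[i], int(age_n[i]), f"age_{tau:g}")
    return out
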