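"""Shared fixtures: the reference parameter set and division-time models.

The kinetic parameters are the reference ones used throughout: km = 0.5/min,
gamma_m = 0.05/min for mRNA; burst arrivals at km = 0.5/min with mean burst
size b = 2 and gamma_p = 0.01/min for protein (a = km/gamma_p = 50); all
division-time models share a 20-minute mean cell cycle.
"""

import pytest

from cyclostat import (ErlangDivision, GeneParams, calibrate_beta_exponential,
                       division_model, pmf_at_birth, protein_coefficients)

GENE = GeneParams(km=0.5, gamma_m=0.05, b=2.0, gamma_p=0.01)
MEAN_TS = 20.0


def standard_models():
    """The four division-time laws with mean 20 min (CV^2 = 0, 0.104, 1/3, 1)."""
    return {
        "delta": division_model("delta", T=MEAN_TS),
        "beta_exponential": calibrate_beta_exponential(20, 10, MEAN_TS),
        "erlang": ErlangDivision(3, 0.15),
        "exponential": division_model("exponential", T=MEAN_TS),
    }


@pytest.fixture(scope="session")
def gene():
    return GENE


@pytest.fixture(scope="session")
def models():
    return standard_models()


@pytest.fixture(scope="session")
def protein_table():
    """High-order protein coefficient table for the Erlang(3) model.

    K = 350 is enough for the mapped resummation to stabilize over the full
    birth support (mean + 8 SD); computed once per session (~1 min).
    """
    return protein_coefficients(GENE, ErlangDivision(3, 0.15), 350)


@pytest.fixture(scope="session")
def protein_birth(protein_table):
    return pmf_at_birth(protein_table)
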