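"""Series inversion: PMFs, cumulants, and the resummation routines."""

import math

import mpmath as mp
import numpy as np
import pytest
from scipy import stats

from cyclostat import (DeltaDivision, ErlangDivision, ExponentialDivision,
                       GeneParams, borel_sum, compute_pmf, cumulants,
                       fixed_T_mrna_closed_form, mapped_sum, mrna_coefficients,
                       pmf_at_birth, pmf_before_division, protein_coefficients,
                       write_pmf)
from cyclostat.exceptions import ConvergenceError

from conftest import GENE, standard_models


def exp_mrna_oracle(state, ymax, T=20.0, K=220, dps=80):
    """Independent closed-form PMF for exponential division times:
    P(m) = sum_k C(k,m)(-1)^(k-m) km_eff^k prod_i 1/(1/T + gm i - 2^-i/T),
    with km_eff = km/2 at birth and km before division."""
    km_eff = GENE.km / 2 if state == "birth" else GENE.km
    out = []
    with mp.workdps(dps):
        prods = [mp.mpf(1)]
        for i in range(1, K + 1):
            prods.append(prods[-1] / (mp.mpf(1) / T + GENE.gamma_m * i
                                      - mp.mpf(2) ** -i / T))
        for m in range(ymax + 1):
            s = mp.mpf(0)
            for k in range(m, K + 1):
                t = mp.binomial(k, m) * mp.mpf(km_eff) ** k * prods[k]
                s += -t if (k - m) % 2 else t
            out.append(float(s))
    return np.array(out)


# ---------------------------------------------------------------------------
# Poisson exactness for fixed division times
# ---------------------------------------------------------------------------

def test_delta_mrna_pmf_is_poisson():
    d, d2 = fixed_T_mrna_closed_form(GENE, 20.0)
    tab = mrna_coefficients(GENE, DeltaDivision(20.0), 120)
    birth = pmf_at_birth(tab)
    ref = stats.poisson.pmf(birth.support, d)
    assert np.max(np.abs(birth.probabilities - ref)) < 1e-10
    pre = pmf_before_division(tab)
    ref2 = stats.poisson.pmf(pre.support, d2)
    assert np.max(np.abs(pre.probabilities - ref2)) < 1e-10


def test_empty_cell_pmf():
    p = GeneParams(km=0.0, gamma_m=0.05, b=2.0, gamma_p=0.01)
    tab = mrna_coefficients(p, DeltaDivision(20.0), 10, dps=40)
    pmf = pmf_at_birth(tab, 5)
    assert pmf.probabilities[0] == pytest.approx(1.0, abs=1e-12)
    assert np.all(pmf.probabilities[1:] < 1e-12)


def test_exponential_mrna_pmf_matches_closed_form():
    pmf = compute_pmf(GENE, ExponentialDivision(20.0), "mrna")
    oracle = exp_mrna_oracle("birth", len(pmf.probabilities) - 1)
    assert np.max(np.abs(pmf.probabilities - oracle)) < 1e-8
    pre = compute_pmf(GENE, ExponentialDivision(20.0), "mrna", state="pre_division")
    oracle_pre = exp_mrna_oracle("pre_division", len(pre.probabilities) - 1)
    assert np.max(np.abs(pre.probabilities - oracle_pre)) < 1e-8


# ---------------------------------------------------------------------------
# cumulants
# ---------------------------------------------------------------------------

def test_delta_mrna_cumulants_are_poissonian():
    tab = mrna_coefficients(GENE, DeltaDivision(20.0), 3, dps=60)
    ns = cumulants(tab)
    d, _ = fixed_T_mrna_closed_form(GENE, 20.0)
    assert ns.mean == pytest.approx(d, rel=1e-12)
    assert ns.variance == pytest.approx(d, rel=1e-12)
    assert ns.kappa3 == pytest.approx(d, rel=1e-10)
    assert ns.skewness == pytest.approx(1.0 / math.sqrt(d), rel=1e-10)


@pytest.mark.parametrize("name", sorted(standard_models()))
def test_protein_mean_cumulant(name):
    model = standard_models()[name]
    ns = cumulants(protein_coefficients(GENE, model, 3, dps=60))
    L1 = model.laplace(GENE.gamma_p)
    assert ns.mean == pytest.approx(GENE.a * GENE.b * (1 - L1) / (2 - L1), rel=1e-10)


def test_protein_erlang_cv2_printed_value():
    ns = cumulants(protein_coefficients(GENE, ErlangDivision(3, 0.15), 3, dps=60))
    assert round(ns.cv2, 3) == 0.229


# ---------------------------------------------------------------------------
# resummation routines
# ---------------------------------------------------------------------------

def test_borel_sum_geometric():
    with mp.workdps(60):
        terms = [mp.mpf("0.7") ** k for k in range(240)]
        assert float(borel_sum(terms, 60)) == pytest.approx(1 / 0.3, rel=1e-10)


def test_borel_sum_matches_poisson_ground_state():
    # terms of the birth series at y = 0 for a fixed division time are
    # (-d)^k / k!, whose (convergent) sum is e^(-d)
    d, _ = fixed_T_mrna_closed_form(GENE, 20.0)
    with mp.workdps(60):
        terms = [(-mp.mpf(d)) ** k / mp.factorial(k) for k in range(120)]
        assert float(borel_sum(terms, 60)) == pytest.approx(math.exp(-d), rel=1e-10)


def test_borel_sum_exponential_model_ground_state():
    tab = mrna_coefficients(GENE, ExponentialDivision(20.0), 120)
    with mp.workdps(tab.dps):
        fact = [mp.factorial(k) for k in range(121)]
        terms = [(-1) ** k * tab.values[k] / fact[k] for k in range(121)]
        val = float(borel_sum(terms, tab.dps))
    assert val == pytest.approx(exp_mrna_oracle("birth", 0)[0], abs=1e-8)


def test_borel_truncation_diagnosed():
    with mp.workdps(40):
        terms = [mp.mpf("0.9") ** k for k in range(25)]  # far too few terms
        with pytest.raises(ConvergenceError):
            borel_sum(terms, 40)


def test_mapped_sum_convergent_geometric():
    with mp.workdps(50):
        b = [mp.mpf("0.95") ** m for m in range(200)]
        assert float(mapped_sum(b, 1.0, 50)) == pytest.approx(1 / 1.95, rel=1e-11)


def test_mapped_sum_resums_divergent_geometric():
    # sum (-1)^m 1.3^m diverges; its analytic value is 1/2.3, singularity at
    # x = 1/1.3 on the positive axis
    with mp.workdps(60):
        b = [mp.mpf("1.3") ** m for m in range(200)]
        assert float(mapped_sum(b, 0.6, 60)) == pytest.approx(1 / 2.3, rel=1e-11)


# ---------------------------------------------------------------------------
# structural invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name", sorted(standard_models()))
def test_predivision_mean_doubles_birth_mean_mrna(name):
    pmf_b = compute_pmf(GENE, standard_models()[name], "mrna", state="birth")
    pmf_p = compute_pmf(GENE, standard_models()[name], "mrna", state="pre_division")
    assert abs(pmf_b.normalization_deficit) < 1e-4
    assert abs(pmf_p.normalization_deficit) < 1e-4
    assert pmf_p.mean() == pytest.approx(2 * pmf_b.mean(), rel=1e-6)


def test_moments_consistent_with_cumulants():
    tab = mrna_coefficients(GENE, ErlangDivision(3, 0.15), 130)
    pmf = pmf_at_birth(tab)
    ns = cumulants(tab)
    assert pmf.mean() == pytest.approx(ns.mean, abs=1e-6)
    assert pmf.variance() == pytest.approx(ns.variance, abs=1e-5)


def test_protein_birth_pmf_consistency(protein_table, protein_birth):
    ns = cumulants(protein_table)
    assert abs(protein_birth.normalization_deficit) < 1e-4
    assert protein_birth.mean() == pytest.approx(ns.mean, abs=1e-3)
    assert protein_birth.variance() == pytest.approx(ns.variance, rel=1e-3)
    assert not protein_birth.convergence["clipped_counts"]


def test_write_pmf_output(tmp_path):
    tab = mrna_coefficients(GENE, DeltaDivision(20.0), 80)
    pmf = pmf_at_birth(tab, 15)
    out = tmp_path / "pmf.tsv"
    write_pmf(pmf, out, metadata={"note": "unit test"})
    lines = out.read_text().splitlines()
    assert lines[0] == "count\tprobability"
    vals = np.array([float(l.split("\t")[1]) for l in lines[1:]])
    assert np.allclose(vals, pmf.probabilities)
    assert (tmp_path / "pmf.tsv.meta.json").exists()
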