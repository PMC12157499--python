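# cyclostat

Exact cyclo-stationary distributions of mRNA and protein copy numbers in
dividing cells with **random, uncorrelated division times**, plus a kinetic
Monte Carlo simulator for validation.

## The problem

Single-cell counts of mRNA and protein fluctuate because of three distinct
sources: the stochastic kinetics of gene expression itself, the binomial
partitioning of molecules between daughter cells at division, and the
randomness of the cell-cycle duration. After many divisions the population
reaches a *cyclo-stationary* state in which the copy-number distribution at
each fixed cell age no longer changes from cycle to cycle. Analytic results
for this state used to be limited to fixed division times (and, via
stage-expansion tricks, the Erlang family); `cyclostat` computes it for an
arbitrary division-time density g(ts) — Erlang, the Beta-exponential
first-passage law, fluctuating-threshold laws, or any user-supplied density —
and splits the resulting noise into its biological sources.

It is aimed at people analyzing single-cell expression data (smFISH,
scRNA-seq, proteomic imaging) who need to know how much of the observed
cell-to-cell variability is attributable to cell-cycle randomness rather than
transcription or translation.

## The method

Molecules are produced constitutively (mRNA: `m -> m+1` at rate `km`, decay
`gamma_m`; protein: geometric bursts of mean size `b` arriving at rate `km`,
decay `gamma_p`, in the fast-mRNA-turnover limit) and partition
binomially with p = 1/2 at division. Writing the generating function of the
newborn ("birth") state as a series about q = 1,

    F+(q) = sum_k (q-1)^k / k! * F+^(k)(1),

the cyclo-stationary condition becomes an exact linear recursion for the
factorial moments F+^(k)(1). The division-time law enters only through the
integrals Psi_{k,j} = ∫ g(ts) e^{-j·gm·ts} (1-e^{-gm·ts})^{k-j} dts (mRNA) or
through its Laplace transform L_k = L(k·gp) (protein). The PMFs follow by the
alternating series

    P+(y) = sum_{k>=y} C(k,y) (-1)^{k-y} F+^(k)(1) / k!,

(with 2^k inserted for the pre-division state), which the package sums in
high precision, resumming divergent cases (bursty proteins with b >= 1) by a
conformal Euler-type mapping with Borel summation as fallback. Cell-age
profiles, Powell age-averaged distributions, the closed-form CV² formulas,
and the additive decomposition CV² = CV²_BP + CV²_DT + CV²_GE (partitioning /
division-time / gene-expression noise) are built on the same coefficients.

## Worked example

Protein noise at cell birth for the four reference division-time laws
(mean cycle 20 min, burst arrivals km = 0.5/min, burst size b = 2, decay
gamma_p = 0.01/min, so a = km/gamma_p = 50):

```bash
cyclostat decompose --km 0.5 --gamma-p 0.01 --b 2 --out out/
```

prints

```
model             cv2      cv2_bp   cv2_dt   cv2_ge   share_bp share_dt share_ge
delta             0.149261 0.039143 0.000000 0.110119 26       0        74
beta_exponential  0.174997 0.039519 0.025153 0.110325 23       14       63
erlang            0.229277 0.040331 0.078115 0.110830 18       34       48
exponential       0.372609 0.042609 0.217391 0.112609 11       58       30
```

Reading the Erlang (N = 3) row: the total squared coefficient of variation of
the protein count in newborn cells is 0.229, of which 34% is caused purely by
the randomness of division times, 18% by binomial partitioning, and 48% by
bursty gene expression. For a fixed division time the DT component vanishes
identically; as cycle-time variability grows (delta → beta-exponential →
Erlang → exponential) the DT share rises toward ~60%.

The full distributions and the simulator cross-check:

```bash
cyclostat analytic --species mrna --km 0.5 --gamma-m 0.05 \
    --family erlang --param N=3 --param lam=0.15 --out out/
cyclostat compare --species mrna --km 0.5 --gamma-m 0.05 \
    --family erlang --param N=3 --param lam=0.15 --seed 1 --out out/
```

The `compare` report for this setting gives a total-variation distance of
~0.01 between the analytic birth-state PMF and a 4x10^4-sample lineage
simulation. For fixed division times the mRNA distribution is exactly Poisson
with mean d = (km/gm)(1-e^{-gm T})/(2-e^{-gm T}) (= 3.8730 here at T = 20);
departures from Poisson are therefore a direct signature of cycle-time
variability.

Library use mirrors the CLI:

```python
from cyclostat import (GeneParams, ErlangDivision, decompose_protein_noise)
gene = GeneParams(km=0.5, gamma_m=0.05, b=2.0, gamma_p=0.01)
dec = decompose_protein_noise(gene, ErlangDivision(3, 0.15))
dec.cv2_total, dec.cv2_dt      # (0.2293, 0.0781)
```

## Units

Times are minutes and rates 1/min throughout (CLI, library, and outputs).
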