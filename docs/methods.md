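# Methods

## Model and assumptions

`cyclostat` treats one gene expressed constitutively in a lineage of dividing
cells. Within a cycle the copy number evolves by a Markov jump process;
at division every molecule independently goes to either daughter with
probability 1/2 (symmetric binomial partitioning), and the followed daughter
defines the lineage. Division times ts are i.i.d. draws from a density g(ts)
— the built-in families are the fixed time, exponential, Erlang,
Beta-exponential (first passage of an autocatalytic process from n0 copies to
a threshold X at rate beta), growth-rate-heterogeneity and
fluctuating-threshold laws, plus user-supplied densities. Two species
models are implemented:

* **mRNA** — birth at rate km, decay at gamma_m per molecule. All mRNA
  results also describe a protein made one-at-a-time at a constant rate.
* **protein** — geometric bursts, P(r) = b^r/(1+b)^(1+r) with mean b,
  arriving at rate km, decay at gamma_p per molecule. This is the reduced
  bursty limit valid when mRNA turnover is much faster than protein turnover
  (gamma_m/gamma_p >> 1); the two-species coupled network is out of scope.
  The mean level is controlled by a = km/gamma_p, which may be non-integer.

Assumptions worth stating: no promoter switching, no gene replication during
the cycle, no size- or volume-dependent rates, symmetric partitioning, and
(for the analytics) uncorrelated successive cycle times. Correlated times are
available in the simulator only, via ts_i = (1-eps)·draw + eps·ts_{i-1},
which preserves the mean of g and has lag-1 autocorrelation eps.

## The coefficient recursion

In the cyclo-stationary state the birth-state generating function F+(q)
satisfies a fixed-point equation whose expansion about q = 1 closes order by
order. The package solves, exactly and without iteration,

* mRNA: `2^k F^(k) = sum_{j<=k} C(k,j) (km/gm)^(k-j) Psi_{k,j} F^(j)` with
  `Psi_{k,j} = ∫ g(ts) e^(-j gm ts) (1-e^(-gm ts))^(k-j) dts`;
* protein: the analogous double sum whose coefficients involve only
  b, a, and the Laplace values `L_s = L(s gamma_p)`, s = 0..K.

The unknown appears on both sides (the j = k term, with coefficient
Psi_{k,k}/2^k, resp. L_k/2^k < 1); each order is a one-variable linear solve.
The real-a factorial ratio a·(a+k-l-j-1)!/(a-l)! is evaluated as
`falling(a,l)·rising(a,k-l-j)` — finite products that vanish for integer a
when l > a and continue smoothly to real a (tested by a midpoint-continuity
check across a = 50).

Coefficients grow super-exponentially and are computed and stored as
arbitrary-precision mpmath floats (sign, mantissa, unbounded exponent) —
magnitude-safe without a log/exp round trip — and serialize to JSON as
(sign, log10 magnitude). Working precision defaults to 200 decimal digits up
to K = 150 and ~2.2·K digits beyond; the recursion itself is numerically
benign (tables computed at 120 vs 300 digits agree to ~1e-99), the precision
is consumed by the series inversion below.

## Series inversion and resummation

The PMFs are alternating series over the coefficients. For mRNA the
generating function is entire and direct high-precision summation converges
(partial sums are accepted when the last max(10, K/10) of them oscillate by
< 1e-12). For bursty proteins with b >= 1 the generating function has its
nearest singularity on the real axis at x = q-1 = 2/b (birth) or 1/b
(pre-division rescaling), at or inside the evaluation distance |x| = 1: the
series is divergent-alternating and is resummed. Two routes exist:

1. **Conformal (Euler-type) mapping** — production route. With the
   singularities confined to a real ray [s, inf), the Moebius map
   x = w/(1+w/(2s)) carries the half-plane Re x < s onto |w| < 2s; the
   re-expanded series at w(-1) converges geometrically at ratio 1/(2s+1).
   The scale s is estimated from the table's own tail coefficient ratios
   (a Domb–Sykes fit r_k = s(1+c/k)) times a 0.72 safety factor — an
   underestimate of s only changes the rate, never the limit, while an
   overestimate is caught by the stabilization monitor. Failure to stabilize
   raises a convergence error and the driver doubles K (twice at most).
2. **Borel summation** — fallback and cross-check. The sum equals
   ∫ e^(-t) B(t) dt with B the (entire) truncated Borel transform, evaluated
   at full precision on Gauss-Legendre panels with explicit diagnostics: the
   damped truncation error of B and its rounding level must stay below
   1e-25 on the probability scale, otherwise the routine refuses rather than
   return a plausible-looking number. For large counts the truncated
   transform cannot reach the t where the integrand has decayed at an
   affordable K, which is why the mapped route is preferred; where both
   converge they agree to ~1e-9.

Negative probabilities of magnitude < 1e-8 are clipped to zero and recorded;
anything larger raises. The normalization deficit |1 - sum P| is always
reported in the result metadata (flagged beyond 1e-4, never silently fixed).
Default support is mean + 8 SD from the exact cumulants
k1 = F1, k2 = F1+F2-k1², k3 = 3F2+F3+F1-3k1k2-k1³.

## Age profiles and the propagator route

The distribution at cell age tau uses the same inversion with the
age-propagated coefficients G^(k)(tau) (which reduce to F^(k)(1) at tau = 0);
age-averaged distributions integrate against the Powell weight
phi(tau) = 2 vm e^(-vm tau) P(ts > tau), with vm solving 2 L(vm) = 1 by
bracketed root-finding (64-node Gauss-Legendre in tau by default, tau_max at
survival < 1e-10).

Independently of the series, the package propagates the birth PMF through a
cycle exactly in float precision: survivors are a binomial thinning with
probability e^(-gamma·tau), newly made molecules are Poisson (mRNA) or
obtained by FFT inversion of the transient burst generating function
(protein, analytic on the unit disc), and the pre-division distribution is
the g(ts)-weighted mixture of age-ts states. This route is used for the
pre-division protein distribution at large a — where the 2^k-rescaled series
would need K ~ 500+ — and doubles as an internal cross-check: it matches the
mapped series to ~1e-9 at small counts and to 1e-6 across the support at
moderate parameters.

## Noise decomposition

Total protein CV² at birth, and its additive split into binomial-partitioning
(BP), division-time (DT) and gene-expression (GE) components, are closed
forms in a, b, L1, L2 obtained by solving the recursion at orders 1–2 (BP:
replace the binomial partition by exact halving; DT: additionally make
expression deterministic). For a fixed division time L2 = L1² makes DT vanish
identically. GE is computed as total - BP - DT and cross-checked against its
own closed form (mismatch beyond 1e-6 raises). The closed forms must agree
with the high-precision cumulant pipeline to 1e-10 — this dual route is the
package's defense against transcription errors in the algebra. Long-cycle
limits (CV² -> 2gm/km and skewness -> sqrt(2gm/km) for mRNA;
CV² -> (b+2)/(ab), skewness -> 2(1+b)/sqrt(ab(2+b)) for protein) are computed
by running the same pipeline with a degenerate "infinite-mean" model whose
Laplace values vanish, not by hard-coding the formulas.

## Division-time numerics

Closed forms are used wherever they exist: the fixed-time family is symbolic
(its Dirac density is deliberately not evaluable; all integrals are
analytic), the Erlang Laplace transform is (lam/(lam+s))^N, and the
Beta-exponential is handled through its first-passage representation as a
hypoexponential sum of exponentials with rates beta·s, s = n0..X-1 — giving
the mean (1/beta)·sum 1/s used for calibration, the variance, the product
Laplace transform, a partial-fraction survival, and an exact sampler. The
fluctuating-threshold law is the normal-ratio density of ln(X/n0)/beta; as a
ratio distribution its far tail decays only as ts^-2 with an
exp(-beta0²/2·sigma_beta²) prefactor (~1e-10 at realistic parameters), so
integrals are truncated at 30·ln2/beta0 and the residual ~1e-10 tail is the
attainable normalization accuracy for this family. Psi_{k,j} defaults to the
finite binomial expansion into Laplace values with compensated summation,
falling back to direct adaptive quadrature when the alternating sum loses
more than six digits. Sampling uses the native construction where one exists
and inverse-CDF on a 10^4-point grid otherwise.

## Simulator

The validator is an exact Gillespie (direct-method) simulation of the same
reduced models, one daughter followed per division. Default burn-in is 100
cycles (the initial condition is forgotten geometrically through halving at
division); each recorded cycle contributes one sample per state, and age-tau
snapshots are recorded only in cycles with ts > tau, matching the
conditioning of the age-resolved analytics. Within-lineage samples are weakly
correlated across cycles, which is irrelevant for histogram comparisons but
means the effective sample count for error bars is slightly below the nominal
one. Inner loops are numba-compiled; division times and per-history seeds are
pre-drawn from a single seeded numpy Generator, so results are reproducible
bit for bit at a fixed seed.

## Problem sizes used in the test suite

Tests validate against simulations of 10^5 recorded samples (400 histories x
250 cycles), where the expected statistical total-variation distance to the
truth is ~0.005-0.01, against analytic tolerances of 0.02. The protein
reference case (a = 50, b = 2, Erlang mean 20 min) uses a coefficient table
of order K = 350 at 771 digits, computed once per test session (~1 min);
published-scale figures with 5x10^7 histories would only sharpen the
histograms, not change any analytic number. Goodness of fit of age-resolved
histograms uses a chi-square test with bins pooled to expected counts >= 5 at
alpha = 0.01.

## Known limitations

* The protein model is the reduced bursty one; the full mRNA->protein network
  is validated only through its limit.
* Asymmetric partitioning, promoter switching, gene replication, and
  size-coupled division ("sizer"/"adder" feedback on the simulated state) are
  out of scope; division times are exogenous draws.
* Correlated cycle times are simulated but not treated analytically; the
  analytic PMFs are the eps = 0 reference the simulation is compared against.
* For user-supplied densities all transforms fall back to adaptive
  quadrature at float precision, which bounds the attainable accuracy of the
  downstream series at ~1e-10.
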