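# Methods

## The model ensemble

`photoensemble` implements the enzyme-kinetic C3 leaf photosynthesis model as
a factorial ensemble of hypothesis combinations rather than a single fixed
model. Net assimilation is

    A = A_g (1 − Γ*/Ci) − R_d                                   (µmol CO2 m⁻² s⁻¹)

with Γ* the photorespiratory CO2 compensation point (Pa), computed from the
RuBisCO turnover-number ratio as Γ* = (k_o:k_c)·K_c·O_i/(2·K_o). The gross
rate A_g is built from up to three potentially limiting rates:

* **Carboxylation (RuBisCO-limited):** A_c,g = V_cmax·Ci/(Ci + K_c(1 + O_i/K_o)).
  One representation only.
* **RuBP regeneration (light-limited):** A_j,g = (J/4)·Ci/(Ci + 2Γ*), with three
  alternative electron-transport hypotheses:
  1. non-rectangular hyperbola — smaller root of
     θ_j J² − (aα_iI + J_max)J + aα_iI·J_max = 0;
  2. asymptotic hyperbola — J = aα_iI/√(1 + (aα_iI/J_max)²);
  3. linear — J = aα_iI, with no maximum.
  The intrinsic quantum efficiency is derived, α_i = 0.5(1 − f), never stored.
  J_max,25 = a_jv + b_jv·V_cmax,25 unless a preset fixes it directly.
* **Triose-phosphate use (TPU):** A_p,g = 3·TPU·Ci/(Ci − (1+3α_tpu)Γ*),
  included or excluded. TPU25 = b_tv·V_cmax,25.

Two **limiting-rate selection** hypotheses combine the rates: the strict
minimum, or two-stage quadratic (non-rectangular hyperbola) smoothing — the
smaller root of θz² − (x1+x2)z + x1x2 = 0 applied first to (A_c,g, A_j,g)
with curvature θ_cj and then to the result against A_p,g with θ_cjp. The
minimum is the θ = 1 special case; θ = 0 degenerates to the rectangular
hyperbola. 2 (TPU) × 2 (selection) × 3 (electron transport) = 12 members,
labelled M1xyz (x = TPU, y = selection, z = electron transport).

Two formulation details deserve a flag, because printed versions of these
equations circulate with inconsistent operators:

* The TPU denominator uses a **minus** sign, Ci − (1+3α_tpu)Γ*. This is the
  only sign consistent with the check that a closed photorespiratory cycle
  (α_tpu = 0) yields A = 3·TPU after multiplication by (1 − Γ*/Ci).
* The non-rectangular electron-transport quadratic is
  θ_j J² − (aα_iI + J_max)J + aα_iI·J_max = 0, verified by the θ_j = 1 limit
  factorizing into min(aα_iI, J_max).

With the minus-sign TPU form and α_tpu > 0, the TPU-limited net rate
*declines* with rising Ci (reversed sensitivity). This is a real, intended
feature of the formulation, so "A is monotone in Ci" holds for the ensemble
only where TPU does not limit or when α_tpu = 0; the test suite asserts
monotonicity under a closed cycle. Likewise "smoothing never exceeds the
minimum" is a statement about A_g; it transfers to net A only for Ci > Γ*
(below Γ* the photorespiration factor is negative and the ordering flips).

Everything is evaluated at a 25 °C reference; no temperature response
functions are included.

## Stomatal coupling

Ci is not prescribed in the ensemble analyses but solved from the supply
balance with the unified (Medlyn) stomatal model:

    g_s = g0 + 1.6(1 + g1/√D)·max(A, 0)/C_a,    Ci = C_a − 1.6·A/g_s

with g1 = 4.3 (global C3 mean), g0 = 0.01 mol m⁻² s⁻¹, D = 1 kPa, zero
boundary-layer and mesophyll resistance. Because the minimum rule makes
A(Ci) only piecewise smooth, the solver is a safeguarded bisection on the
supply–demand residual, vectorized over parameter/environment arrays: the
residual is positive as Ci → 0 (negative A inflates supply above C_a) and
negative at an upper bracket C_a + 1.6(R_d + V_cmax Γ*/K_m)/g0 + 10, so a
sign change is guaranteed; 52 bisections leave the bracket at machine level
(|residual| ≪ 10⁻⁸·C_a). Ci-independent quantities (Γ*, K_m, J, R_d, TPU)
are hoisted out of the iteration.

Defaults not fixed elsewhere: O_i = 21 kPa (standard atmospheric O2 partial
pressure), air pressure 101.325 kPa for the µmol/mol ↔ Pa conversion; both
configurable on `Environment`.

## Sensitivity analysis

All 14 parameters vary independently and uniformly within ±10% of central,
commonly used values (e.g. V_cmax 45–55, K_c 36.4–44.5 Pa, all three θ
0.81–0.99 around 0.9 — the θ central value is pulled to 0.9 so the ±10% band
stays inside [0, 1]). Nine scenarios combine C_a ∈ {280, 400, 600} µmol/mol
with I ∈ {200, 500, 1000} µmol m⁻² s⁻¹; the CO2-response output
ΔA = A(C_a,high) − A(C_a,low) uses the pairs 280→400 and 400→600 at the same
three light levels, with common random numbers across the pair.

**Parameter SA** computes first-order Sobol indices per model and scenario
with the Saltelli two-matrix scheme, S_i = E[(f_B − μ)(f_AB_i − f_A)]/Var(Y)
(centring f_B leaves the expectation unchanged but removes the mean-level
noise term, which otherwise dominates because |E A| ≈ 11 ≫ sd(A) ≈ 1).
Indices pool across the 12 members weighted by member variance, members
entering with equal probability; this captures within-model variance only.

**Process SA** treats each of four processes — carboxylation {V_cmax, K_c,
K_o, k_o:k_c, b_rv}, electron transport {a, f, θ_j, a_jv, b_jv}, TPU {b_tv,
α_tpu}, limiting-rate selection {θ_cj, θ_cjp} — as a composite factor
(hypothesis choice + member parameters). R_d scales with V_cmax, so b_rv is
grouped with carboxylation. For process k with m_k hypotheses, n outer draws
of the member parameters are crossed with each hypothesis stratum (uniform
weight 1/m_k); the conditional mean per outer sample enumerates all 12/m_k
complementary hypothesis combinations with n shared draws of the remaining
parameters (common random numbers across strata, and a single shared inner
sample across outer points, which keeps the inner-loop noise common rather
than inflating the conditional-mean variance). S_k = Var(E[Y | factor_k]) /
Var(Y), with the total variance pooled over every execution, so it contains
both between-hypothesis and parametric variance. The exact published variant
of this stratified estimator is not restated anywhere we could check it
from, so the construction above is this package's declared interpretation;
it reproduces the reference toy-lattice enumeration to ±0.01 and the
reported ensemble indices within the stated tolerances.

**Integration across scenarios:** indices are averaged weighted by scenario
variance; means and variances integrate as plain scenario averages (this
convention exactly reconstructs the reported integrated rows from the
per-scenario rows, which is itself a test). **Convergence** is assessed by
bootstrap over the sample draws, with the declared criterion that all index
SDs fall below 0.001 at production sample sizes.

Problem sizes: one process-SA scenario costs 12·n² coupled solves per
process; the package defaults use n = 50 for quick runs, the test suite
n = 100–150, and `scripts/acceptance.py` n = 200 (A and ΔA) with 15,000
Saltelli base samples — sizes at which every reported index has Monte-Carlo
SD below ~0.01. The production-scale figures (n = 300 process, 300,000
parameter) are a `--n` flag away but change the estimates by less than the
bootstrap noise at n = 200.

## Smoothing-reduction analysis

At exact two-rate co-limitation the smoothing scalar has the closed form
(1 − √(1−θ))/θ, implemented in the cancellation-free equivalent
1/(1 + √(1−θ)); the two-stage scalar at triple co-limitation follows by
smoothing the first-stage value against the (equal) third rate on
rates normalized to 1 — Eqs. 3a/3b are exactly scale-invariant, which is
asserted in tests. Reference values: θ = (0.95, 0.98) → scalar 0.77
(23% reduction); θ_cj = 0.95 alone → 18%; 0.99 → 9.1%; 0.998 → 4.3%;
θ = (0.9, 0.9) → 36%. The reduction surface reports
100·(min − smoothed)/min over an (A_c,g, A_j,g) grid at fixed A_p,g.

The two-stage ordering is fixed as (A_c, A_j) first, then A_p. Published
single-θ reductions for models that smooth with θ = 0.83 at both stages do
not reproduce under this ordering from a single scalar (the two stages do
not commute), so no such value is asserted.

## Synthetic A-Ci curves

The generator emulates a high-resolution gas-exchange protocol: C_a stepped
400 → 50 µmol/mol (7 conventional setpoints), then a dense scan 305 → 1,000
in 5 µmol/mol increments (140 setpoints spanning the co-limitation
transition), then a high extension (1,100–1,800). Chamber light is
saturating (I = 2,000 µmol m⁻² s⁻¹). For each setpoint the coupled model
yields (Ci, A_true); the observation adds iid Gaussian noise with
sd = 0.3 µmol m⁻² s⁻¹ (typical instrument noise; configurable), which is
precisely the error structure the fitting likelihood assumes. The
descending-leg and high-extension setpoints follow common practice and are
configurable; only the transition scan is prescribed exactly.

What the generator does *not* emulate: instrument drift, leak/match
corrections, humidity dynamics, chloroplast-population heterogeneity, or any
temperature response (generation and fitting share the 25 °C reference — a
deliberate simplification, so recovery tests validate the inference
machinery, not field-data fidelity). Passing recovery tests therefore show
that the estimator is calibrated *when the model is true*, not that real
leaves satisfy the model.

## Bayesian θ_cj estimation

The fitted model is the two-limitation (A_c, A_j) demand model with θ_cj
smoothing and TPU excluded, evaluated at each record's measured Ci (the
instrument reports Ci; no stomatal solve enters, and the likelihood is
provably invariant to stomatal parameters). J enters through the
non-rectangular hyperbola with θ_j fixed at its central 0.9 and J_max,25
sampled directly. Kinetic constants and the R_d scaling are fixed at central
values. Uniform priors: V_cmax,25 ∈ [100, 200], J_max,25 ∈ [70, 400],
θ_cj ∈ [0.9, 1.0], σ ∈ (0, 5] (σ is a sampled nuisance; the Gaussian-iid
"standard error" likelihood leaves its handling open, and sampling it is the
simplest fully Bayesian choice).

Records above the onset of a sustained decline of A with C_a (five
consecutive decreasing smoothed points) are truncated before fitting, which
removes TPU-affected high-C_a tails without touching the transition scan.

DREAM settings: 7 chains; δ ∈ {1..3} chain pairs per proposal (capped at
(n_chains−1)/2); γ = 2.38/√(2δd′) with γ = 1 every fifth generation;
crossover probabilities over {1/3, 2/3, 1} adapted from normalized squared
jump distances over the first 20% of the run; proposals reflected at the
prior bounds; outlier chains (mean log-posterior below Q1 − 2·IQR over the
second half of history) reset to a healthy chain's state during adaptation.
Convergence: Gelman–Rubin R̂ < 1.1 (the statistic is standard; the cutoff is
this package's choice) on the earliest 10%-granularity suffix; the retained
draws are thinned to 1% with a floor of 400 retained samples so short
test-budget runs still yield stable quantiles. Test budgets use 7 × 3,000
iterations, at which a 4-parameter posterior on a 151-record curve converges
in ~2 s; production-scale budgets (7 × 80,000, 25,000 post-convergence
draws per chain) are a settings change.

Numerical edge cases: forward-model failures map to log-likelihood −∞; a
θ_cj truth of 1.0 piles posterior mass against the upper prior bound and the
reported interval includes 1.0 (the estimator cannot, and should not,
exclude the minimum rule from inside its support).

## Known limitations

* C4 photosynthesis, mesophyll/boundary-layer resistance, temperature
  response and soil-water limitation are out of scope.
* The process-SA estimator variant is an interpretation (see above).
* Between-model weights are uniform; no model-probability weighting.
* Only first-order indices are computed — no interaction terms — consistent
  with first-order sums landing near 0.95 on this ensemble.
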