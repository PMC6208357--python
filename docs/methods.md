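# Methods

## Model and conventions

Underdamped Langevin dynamics,

    dx = v dt,
    dv = −M⁻¹∇U(x) dt − γ v dt + √(2γ/(βM)) dW,

has the canonical density π(x, v) ∝ e^(−βU(x)) e^(−βK(v)),
K(v) = vᵀMv/2, as its stationary law. All energies, heats and works in the
package are *reduced* (multiples of kT = 1/β): the reduced potential is
u(x) = βU(x), the reduced kinetic energy t(v) = βvᵀMv/2, and the reduced
Hamiltonian h = u + t. β is carried explicitly on every `SystemSpec` so the
reduced-unit convention is a presentation choice, not a loss of generality.
Masses are diagonal; coordinates are flat vectors; there are no periodic
boundaries or constraints.

A finite timestep Δt makes the integrator sample a perturbed stationary
density ρ(x, v) ≠ π. The package measures that perturbation as a
KL divergence — D_KL(ρ‖π) in phase space, or D_KL(ρₓ‖πₓ) for the
configuration marginal, which is what configurational averages actually feel.

## Splitting integrators and shadow work

A splitting string over {R, V, O} is parsed into an ordered substep list;
every occurrence of a letter receives time fraction 1/count(letter), which
reproduces the standard OVRVO (O, V at Δt/2; R at Δt) and VRORV (V, R at
Δt/2; O at Δt) update sequences. Only *palindromic* strings are accepted:
the work identity below relies on the substep sequence being its own
time-reverse, and accepting an asymmetric string with silently wrong
accounting would be worse than rejecting it.

For a palindromic splitting the deterministic R/V kernels cancel between a
trajectory and its velocity-negated reverse, and the O-kernel log-ratio
telescopes into kinetic-energy differences. The shadow work of a trajectory
therefore reduces to

    w = Δh − Δq,

with Δh the reduced Hamiltonian change over the whole trajectory and Δq the
summed reduced kinetic-energy change across O substeps. `WorkLedger` stores
Δh and Δq and defines `shadow_work` as exactly their difference; γ = 0
forces Δq = 0 and w = Δh. Accounting needs no extra force evaluations —
exactly one per V substep, never cached across cycles (correctness over
speed). A state is declared unstable when any coordinate is non-finite or
|x| > 10⁶ in reduced units.

Noise handling: one standard-normal vector per O substep, consumed in
substep order from a seeded generator, so trajectories and ledgers are
bitwise reproducible. The 1D built-in potentials additionally run through
numba kernels (the generic numpy path is the reference implementation; the
two are cross-checked statistically in the tests — their noise streams
differ, so agreement is at the level of work distributions, not bits).

## Systems

* `double_well` — U(x) = x⁶ + 2cos(5(x+1)), defaults β = 1, m = 10,
  studied at γ = 10. The benchmark for everything quantitative: stability
  limit, KL scaling, sandwich validation, GHMC analysis. Note the cosine
  breaks x → −x symmetry (mean x ≈ −0.07); its empirical maximum stable
  timestep under the operational criterion below is 0.70–0.75.
* `quartic` — U(x) = Σxᵢ⁴, any dimension; ⟨x²⟩ = Γ(3/4)/Γ(1/4) at β = 1
  gives a closed-form moment for sampler checks.
* `lj_cluster` — a synthetic 5-particle Lennard-Jones cluster (ε = σ = 1)
  under a harmonic restraint of stiffness k (default 1) on every particle.
  It is a native toy with molecular geometry — pair repulsion, a disordered
  energy landscape — not a molecular-mechanics model; it supports the
  generic-path machinery and qualitative experiments only.

### Quadrature and exact 1D sampling

The configuration marginal of a 1D system is tabulated by trapezoidal
quadrature of e^(−u(x)): the support is expanded until u exceeds its
minimum by 60 (truncated tail mass ≲ 1e−26), and each histogram bin is
subdivided into 10⁴ panels; bin masses are invariant to grid refinement at
the 1e−8 level, and a coarse grid triggers a warning. Phase-space reference
masses are the outer product of the quadrature x-masses with exact Gaussian
bin masses for v (normal CDF differences — exact and cheap, so no reason to
re-quadrature a Gaussian).

Equilibrium positions in 1D are drawn by inverse-CDF interpolation on a
200 001-point cumulative-trapezoid table — i.i.d. and exact up to quadrature
error. Velocities are i.i.d. N(0, (βm)⁻¹) per degree of freedom. For n-D
systems, equilibrium sampling delegates to a Metropolized GHMC chain (exact
stationary law) thinned by 10·(1/γ)/Δt integrator steps, with a split-half
batch-mean diagnostic that raises on gross non-equilibration.

## Near-equilibrium estimator

The length-2T protocol draws (x₀, v₀) ~ π, runs T cycles (work w₁; the
endpoint approximates a ρ draw), and runs T more cycles (work w₂). Then

    D_KL(ρ‖π) ≈ (⟨w₁⟩ − ⟨w₂⟩)/2.

In configuration mode the midpoint velocities are redrawn from π(v|x) —
this costs no work and turns the midpoint into a draw from
ω(x, v) = ρₓ(x)π(v|x), whose divergence from π equals D_KL(ρₓ‖πₓ). The 95%
CI comes from the paired per-trajectory differences dᵢ = (w₁ᵢ − w₂ᵢ)/2,
which uses the strong correlation between the two halves. Negative point
estimates near zero divergence are reported as-is; plotting floors
log-scaled values at 1e−4.

**Protocol length.** The default T spans two collision times,
ceil((2/γ)/Δt). On the double well at γ = 10 that is a single step, and the
estimate is visibly unconverged (0.025 vs a ground truth of 0.041 at OVRVO
Δt = 0.5): relaxation into ρ is gradual, with increments per doubling of T
comparable to the statistical error of moderate sample sizes. The package
therefore validates T by concordance — `check_protocol_length` compares
estimates at T and 2T (flagging |difference| > 2 combined SE), and
`auto_protocol_length` doubles T until the difference falls below *one*
combined SE at 10⁵ samples. The stricter stopping factor and the large
sample count are deliberate: with weaker settings the doubling stops one
octave early and the residual truncation bias (~0.005 nats here) exceeds
the noise. On the double well this lands at T = 4 for Δt = 0.5 and T ≈ 8
for Δt = 0.3 (protocol time ≈ 2 reduced time units). Even at validated T
the estimator retains a small truncation error (it is a near-equilibrium
approximation); the sandwich below is the check that this error is
contained.

## Nested Monte Carlo estimator and Jensen bound

The ratio ρ(z)/π(z) equals ⟨e^(−w)⟩_z, the exponential work average over
T-step protocol realizations started from z (same T as above). Averaging
its log over N steady-state draws gives the nested estimator

    D̂ = (1/N) Σᵢ ln[(1/Mᵢ) Σⱼ e^(−wᵢⱼ)].

Outer draws are equilibrium samples relaxed for `decorrelation_steps`
cycles (default: the validated protocol length; in configuration mode the
velocity is then replaced by a fresh π(v|x) draw). The inner loop is
adaptive: samples arrive in batches of 100 (at least 50 before any
decision), and stop when the first-order Taylor estimate of the inner
log-mean's standard deviation, sd(e^(−w))/(mean·√M), falls below the
threshold (0.01 default; 0.02 in the validation runs) or a 5·10⁴-sample
budget is exhausted — exhausted rows are kept and flagged, never dropped.

Bias directions, stated rather than corrected:

* Each inner log-mean is an exponential-average (EXP-type) under-estimate,
  ≈ σ²_inner/2M low; controlling the precision controls the bias.
* In configuration mode the outer start fixes one velocity draw per row, so
  the estimator converges to ⟨ln ρ/π⟩_ω, which under-shoots D_KL(ω‖π) by
  the mean conditional-velocity divergence ⟨D_KL(π(v|x)‖ρ(v|x))⟩. This is
  visible where superconvergence makes the marginal divergence ≈ 0 (VRORV
  at large Δt: nested ≈ −0.03). It is harmless for the sandwich logic —
  nested is the *lower* reference by construction.
* The Jensen bound is computed as ln of the *row-balanced* mean,
  ln[(1/N) Σᵢ mᵢ] with mᵢ the inner means: each outer draw contributes
  equal weight, which is the faithful estimate of ln⟨e^(−w)⟩_ρ and keeps
  the bound algebraically ≥ the nested estimate for jagged rows (a pooled
  mean weighted by row length does not). In configuration mode the bound
  remains valid for the marginal: the conditional-velocity factor
  integrates out of ⟨e^(−w)⟩_ω exactly. With equal-length rows the
  row-balanced and pooled forms coincide.

Uncertainties for both estimators come from a two-level bootstrap (rows
with replacement, then columns within rows; 100 resamples by default),
reported as 2.5/97.5 percentile intervals.

**Sandwich validation.** `sandwich_validation` runs, per condition, the
nested estimate, the near-equilibrium estimate, the Jensen bound, and the
histogram ground truth, and checks nested ≤ near-eq ≤ Jensen within the
95% intervals, plus bracketing of the ground truth. On the double well this
holds in all 16 conditions (4 splittings × Δt ∈ {0.3, 0.5} × 2 modes) at
N = 200 outer draws and σ-threshold 0.02.

## Histogram ground truth

Steady-state histograms use 100 bins per dimension with edges fixed by the
bounding box (plus 5% pad) of a trial run at the largest timestep of a
sweep, shared across conditions so divergences are comparable. The raw
divergence Σ p ln(p/q) (`histogram_kl`) is the plain plug-in formula; bins
with p > 0 where q = 0 raise with the offending indices.

The plug-in estimator has an O(1/n) positive bias of roughly
(occupied bins)/(2 n_eff), where n_eff accounts for autocorrelation — on
the double well the slowly decorrelating well occupancies make this
substantial (~5e−3 at 10⁶ samples over a 100×100 grid), flooring small
divergences. `histogram_kl_estimate` therefore jackknife-extrapolates each
chain in sample size (2·KL_full − mean of the two half-chain KLs), which
removes the leading bias term including its autocorrelation inflation;
chains start from exact equilibrium draws and the CI is the normal interval
over per-chain values.

**Sample-size scaling.** The phase-space divergence shrinks as Δt⁴ while the
debiased noise floor shrinks only as n^(−1/2), so scaling-law runs budget
samples per condition as ∝ Δt⁻² (3.2·10⁷ at Δt = 0.2, split over 8 chains).
With this schedule every grid point on Δt ∈ {0.2, …, 0.6} is resolved an
order of magnitude above its noise (KL(0.2) = 0.00112 with seed spread
~1e−4) and the fitted log-log slope is stable at ≈ 4.3 ± 0.2 across seeds.

## GHMC

`ghmc_acceptance_rate` draws a fresh equilibrium start per proposal, runs
`steps_per_proposal` cycles, and averages α = min{1, e^(−w)} (diverged
proposals count as α = 0); fresh starts isolate the rate from chain
autocorrelation, and no momentum flip is needed since only α is recorded.
`run_ghmc_chain` is the full Metropolized chain — accept on shadow work,
negate the velocity on rejection (required for detailed balance) — whose
stationary law is exactly π; it doubles as the n-D equilibrium sampler and
warns when acceptance drops below 1%. Velocity refreshment happens entirely
through the O substeps inside proposals.

The chain reproduces the quadrature density on the double well (KL < 10⁻²
at 10⁶ iterations for all four splittings at Δt = 0.3), and the acceptance
analysis reproduces the decoupling result: at Δt = 0.6 the four splittings'
rejection rates (0.14–0.18) rank differently from their configuration-space
divergences (5·10⁻⁴ to 0.11) — a low rejection rate neither implies nor is
implied by low marginal bias, and the Metropolis test is decidedly
conservative for VRORV.

## Stability

"Maximum stable timestep" is operational: Δt is stable when all of
10 independent 10⁴-step trajectories from equilibrium starts stay finite
with |x| < 10⁶. On the double well benchmark this yields 0.70–0.75 on a
0.05-spaced grid (the boundary is stochastic; 0.80 already diverges in a
few of ten trajectories).

## What the toy systems do and do not show

All quantitative validation runs on 1D systems where quadrature ground
truth exists. Passing tests demonstrate that the work accounting is exact,
that the three estimators agree where they must, and that the known
qualitative integrator phenomenology (Δt⁴ phase-space scaling, VRORV
superconvergence across collision rates, GHMC decoupling) emerges. They do
not demonstrate force-field realism: the LJ cluster is a geometric stand-in
for solvated molecular systems, and femtosecond-scale molecular-mechanics
numbers are out of scope. Constrained systems (where π(v|x) depends on x),
non-palindromic splittings, multiple-timestep schemes and barostats are
likewise out of scope; the parser and the samplers refuse rather than
approximate where these arise.
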