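# splitkl

Quantify the sampling bias that a finite timestep introduces into Langevin
dynamics, for any integrator built from a symmetric operator splitting.

Numerical Langevin integrators sample a timestep-dependent stationary
density ρ(x, v) that differs from the canonical target
π(x, v) ∝ e^(−βU(x)) e^(−βK(v)). For molecular simulation the quantity that
matters is usually the error in the *configuration marginal* ρₓ, not the full
phase-space density, and some splittings (notably VRORV, a.k.a. BAOAB) keep
the marginal error dramatically smaller than the phase-space error at the
same cost. `splitkl` builds integrators from splitting strings over
{R, V, O}, accounts their shadow work exactly, and turns work statistics
into KL-divergence estimates D_KL(ρ‖π) and D_KL(ρₓ‖πₓ) — with an exact
histogram/quadrature reference available for 1D systems, and a GHMC layer
for Metropolized (exact) sampling and acceptance-rate analysis.

## The integrators

A splitting string defines one cycle of duration Δt from three exactly
solvable sub-propagators (each letter occurring k times runs for Δt/k):

- **R** (drift): x ← x + v τ
- **V** (kick): v ← v − M⁻¹∇U(x) τ
- **O** (Ornstein–Uhlenbeck): v ← a v + √((1−a²)/(βM)) ξ, a = e^(−γτ), ξ ∼ N(0, I)

`OVRVO` (Bussi–Parrinello / VVVR), `VRORV` (BAOAB), `ORVRO`, `RVOVR` are the
four schemes studied throughout; any palindromic string is accepted. For a
palindromic splitting the **shadow work** of a trajectory is

    w = Δh − Δq,

the change in reduced Hamiltonian h = βU(x) + βvᵀMv/2 minus the reduced heat
exchanged across the O substeps, and `run_steps` returns it in an exact
per-trajectory ledger.

## The estimators

- **Near-equilibrium** (`near_equilibrium`): run a length-2T protocol —
  T steps from an equilibrium start (work w₁), T more from the midpoint
  (work w₂); then D_KL(ρ‖π) ≈ (⟨w₁⟩ − ⟨w₂⟩)/2. Redrawing the midpoint
  velocities from π(v|x) instead yields D_KL(ρₓ‖πₓ). Cheap, slightly
  approximate; the protocol length is validated by requiring estimates at T
  and 2T to agree.
- **Nested Monte Carlo + Jensen bound** (`reference_estimators`):
  asymptotically exact D_KL = ⟨ln⟨e^(−w)⟩_z⟩_ρ with an adaptive inner loop
  (a finite-sample under-estimate), and the Jensen upper bound ln⟨e^(−w)⟩.
  Together they sandwich the near-equilibrium estimate; uncertainties come
  from a two-level jagged bootstrap.
- **Histogram ground truth** (`reference_estimators` + `experiments`): for
  1D systems, exact bin-mass divergence of long steady-state trajectories
  against trapezoidal quadrature of the target, with jackknife debiasing of
  the plug-in estimator.
- **GHMC** (`ghmc`): Metropolize any of these integrators with
  α = min{1, e^(−w)} for exact canonical sampling, and estimate acceptance
  rates from equilibrium starts.

Built-in systems: a 1D quartic U(x) = x⁴, the 1D double well
U(x) = x⁶ + 2cos(5(x+1)) (the benchmark used throughout, with β = 1,
γ = 10, m = 10), a separable n-D quartic, and a harmonically restrained
Lennard-Jones cluster. 1D systems run through jit-compiled kernels
(millions of steps per second); anything else uses the generic path.

## Worked example

Compare the configuration-space bias of OVRVO and VRORV on the double well
at a large timestep (Δt = 0.6, close to the stability limit):

```python
import splitkl as sk

system = sk.make_system("double_well")          # beta=1, m=10
for splitting in ("OVRVO", "VRORV"):
    config = sk.IntegratorConfig(splitting, dt=0.6, gamma=10.0)
    est = sk.estimate_kl(system, config, mode="configuration",
                         n_steps_T=4, n_samples=50_000, rng_seed=1)
    print(f"{splitting}: D_KL(rho_x || pi_x) = {est.value:.4f} "
          f"[{est.ci_low:.4f}, {est.ci_high:.4f}]")
```

prints

```
OVRVO: D_KL(rho_x || pi_x) = 0.0837 [0.0765, 0.0910]
VRORV: D_KL(rho_x || pi_x) = -0.0003 [-0.0049, 0.0043]
```

OVRVO's sampled x-marginal is measurably biased (≈0.08 nats from the
target), while VRORV's is indistinguishable from zero at the same timestep —
the superconvergence that makes BAOAB-type schemes attractive for
configurational averages. A small negative estimate is ordinary sampling
noise around a near-zero divergence and is reported unclamped.

The same analyses are scriptable from the shell:

```bash
splitkl stability --dt-grid 0.5,0.55,0.6,0.65,0.7,0.75,0.8 --seed 1
splitkl neareq --system double_well --splitting VRORV --dt 0.5 --gamma 10 \
               --mode configuration --n 50000 --T 4 --seed 1 --out results.csv
splitkl sandwich --out sandwich.csv --seed 1
splitkl ghmc-rate --splitting RVOVR --dt 0.5 --n 10000 --seed 1
```

## Documentation

`docs/methods.md` describes the model, the estimators and their bias
directions, the numerical choices (protocol-length validation, histogram
debiasing, sample-size scaling), and known limitations.
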