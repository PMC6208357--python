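"""Metropolization of splitting integrators (generalized hybrid Monte Carlo).

A GHMC proposal runs one or more cycles of a symmetric-splitting Langevin
integrator and is accepted with probability alpha = min{1, e^-w_shad}.
Accepting on the shadow work makes the chain's stationary distribution
exactly the canonical density; the price is that rejections must negate the
velocity to maintain detailed balance, which inflates autocorrelation.

Two entry points:

* :func:`ghmc_acceptance_rate` estimates the mean acceptance ratio from
  *fresh equilibrium starts* (one per proposal), isolating the rate from
  chain autocorrelation.
* :func:`run_ghmc_chain` runs the full Metropolized chain (with momentum
  flips), usable as an exact equilibrium sampler, e.g. for systems whose
  marginals cannot be tabulated by quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .integrators import InstabilityError, IntegratorConfig, run_steps
from .near_equilibrium import _child_seeds
from .systems import (PhasePoint, SystemSpec, sample_equilibrium_positions,
                      sample_velocities)

__all__ = ["AcceptanceReport", "ghmc_acceptance_rate", "run_ghmc_chain"]


@dataclass(frozen=True)
class AcceptanceReport:
    """Mean Metropolis acceptance ratio with its standard error."""

    acceptance_rate: float
    n_proposals: int
    se: float
    n_unstable: int = 0

    @property
    def rejection_rate(self) -> float:
        return 1.0 - self.acceptance_rate


def _alpha_from_works(works: np.ndarray, ok: np.ndarray) -> np.ndarray:
    alpha = np.where(ok, np.exp(-np.clip(np.where(ok, works, 0.0), 0.0, None)), 0.0)
    return alpha


def ghmc_acceptance_rate(system: SystemSpec, config: IntegratorConfig,
                         steps_per_proposal: int = 1, n_proposals: int = 10_000,
                         rng_seed=0) -> AcceptanceReport:
    """Mean acceptance ratio over proposals originating from equilibrium.

    Each proposal draws (x0, v0) ~ pi, runs ``steps_per_proposal`` integrator
    cycles, and contributes alpha = min{1, e^-w_shad}; diverged proposals
    count as alpha = 0.
    """
    s_x, s_v, s_run = _child_seeds(rng_seed, 3)
    if system.dimension == 1 and system.pot_id >= 0:
        from ._kernels import batch_work, compile_scheme
        pot_id, beta, m, codes, taus, a_coef, sigma = compile_scheme(system, config)
        x0 = sample_equilibrium_positions(system, n_proposals, s_x)
        v0 = sample_velocities(system, n_proposals, s_v)
        _, _, works, ok = batch_work(pot_id, beta, m, codes, taus, a_coef,
                                     sigma, x0, v0, steps_per_proposal, s_run)
    else:
        x0 = np.atleast_2d(sample_equilibrium_positions(system, n_proposals, s_x))
        v0 = np.atleast_2d(sample_velocities(system, n_proposals, s_v))
        works = np.zeros(n_proposals)
        ok = np.ones(n_proposals, dtype=bool)
        for i, seed in enumerate(_child_seeds(s_run, n_proposals)):
            try:
                _, ledger = run_steps(system, config,
                                      PhasePoint(x=x0[i], v=v0[i]),
                                      steps_per_proposal, seed)
                works[i] = ledger.shadow_work
            except InstabilityError:
                ok[i] = False
    alpha = _alpha_from_works(works, ok)
    rate = float(alpha.mean())
    se = float(alpha.std(ddof=1) / np.sqrt(n_proposals))
    return AcceptanceReport(acceptance_rate=rate, n_proposals=n_proposals,
                            se=se, n_unstable=int(np.sum(~ok)))


def run_ghmc_chain(system: SystemSpec, config: IntegratorConfig,
                   steps_per_proposal: int = 1, n_iterations: int = 10_000,
                   rng_seed=0, x0=None, thin: int = 1):
    """Full GHMC chain; returns (positions, AcceptanceReport).

    Velocity randomization happens through the O substeps inside each
    proposal; the Metropolis test is on the proposal's shadow work, and a
    rejection restores the previous state with negated velocity.  Positions
    are recorded every ``thin`` iterations.  A warning is issued if fewer
    than 1% of proposals are accepted (frozen chain).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    s_x, s_v, s_run = _child_seeds(rng_seed, 3)
    if x0 is None:
        # a cold but cheap start; the Metropolis test keeps the chain exact
        from .systems import initial_position
        x0 = initial_position(system)
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    v0 = np.atleast_1d(sample_velocities(system, 1, s_v)[0])

    if system.dimension == 1 and system.pot_id >= 0:
        from ._kernels import compile_scheme, ghmc_chain
        pot_id, beta, m, codes, taus, a_coef, sigma = compile_scheme(system, config)
        xs, n_accept = ghmc_chain(pot_id, beta, m, codes, taus, a_coef, sigma,
                                  float(x0[0]), float(v0[0]), n_iterations,
                                  steps_per_proposal, s_run)
        positions = xs[thin - 1::thin]
    else:
        positions_list = []
        z = PhasePoint(x=x0, v=v0)
        rng = np.random.default_rng(s_run)
        n_accept = 0
        for it in range(n_iterations):
            seed = int(rng.integers(2**31 - 1))
            try:
                z_prop, ledger = run_steps(system, config, z,
                                           steps_per_proposal, seed)
                w = ledger.shadow_work
                accept = w <= 0 or rng.random() < np.exp(-w)
            except InstabilityError:
                accept = False
            if accept:
                z = z_prop
                n_accept += 1
            else:
                z = PhasePoint(x=z.x, v=-z.v)
            if (it + 1) % thin == 0:
                positions_list.append(z.x.copy())
        positions = np.asarray(positions_list)

    rate = n_accept / n_iterations
    if n_iterations >= 1000 and rate < 0.01:
        warnings.warn(f"GHMC chain nearly frozen: acceptance {rate:.3%}",
                      stacklevel=2)
    se = float(np.sqrt(max(rate * (1 - rate), 0.0) / n_iterations))
    report = AcceptanceReport(acceptance_rate=float(rate),
                              n_proposals=n_iterations, se=se)
    return positions, report
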