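"""Experiment drivers: timestep sweeps, collision-rate sweeps, sandwich
validation of the estimators, and stability scans.

All drivers return pandas DataFrames with one row per condition (failed /
unstable conditions carry a flag rather than being dropped) and are
reproducible given their seed.  Tables round-trip exactly through the CSV
writer/reader pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .integrators import InstabilityError, IntegratorConfig, run_steps
from .near_equilibrium import (KLEstimate, _child_seeds, default_protocol_length,
                               estimate_kl)
from .reference_estimators import (Histogram, InnerLoopController,
                                   equilibrium_density_1d, histogram_kl,
                                   phase_space_reference, run_nested_estimate)
from .systems import (PhasePoint, SystemSpec, sample_equilibrium_positions,
                      sample_velocities)

__all__ = [
    "SweepConfig",
    "determine_edges",
    "histogram_kl_estimate",
    "sweep_timesteps",
    "sweep_collision_rates",
    "sandwich_validation",
    "stability_scan",
    "write_table",
    "read_table",
]


@dataclass
class SweepConfig:
    """Shared sweep settings.

    ``dt_grid`` and ``gamma_grid`` must be non-empty and strictly increasing;
    the timestep sweep runs over ``dt_grid`` at ``gamma_grid[0]``, the
    collision-rate sweep over ``gamma_grid`` at ``dt_grid[0]``.
    """

    system: SystemSpec
    splittings: Sequence[str] = ("OVRVO", "ORVRO", "RVOVR", "VRORV")
    dt_grid: Sequence[float] = (0.2, 0.3, 0.4, 0.5, 0.6)
    gamma_grid: Sequence[float] = (10.0,)
    modes: Sequence[str] = ("phase", "configuration")
    estimator: str = "auto"          # histogram | near_eq | auto
    n_steps: int = 1_000_000         # histogram-chain length per condition
    burn_in: int = 10_000
    n_chains: int = 5
    n_samples: int = 50_000          # near-equilibrium protocol samples
    n_steps_T: int | None = None     # protocol half-length; None = default rule
    n_outer: int = 200               # nested-MC outer draws
    sigma_threshold: float = 0.01
    budget: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        for grid in (self.dt_grid, self.gamma_grid):
            g = np.asarray(grid, float)
            if g.size == 0 or np.any(np.diff(g) <= 0):
                raise ValueError("grids must be non-empty and strictly increasing")

    def pick_estimator(self) -> str:
        if self.estimator != "auto":
            return self.estimator
        return "histogram" if self.system.dimension == 1 else "near_eq"


# ---------------------------------------------------------------------------
# histogram steady-state estimator (1D ground truth)


def determine_edges(system: SystemSpec, splitting: str, dt_max: float,
                    gamma: float, n_bins: int = 100, n_steps: int = 100_000,
                    rng_seed=0, pad: float = 0.05):
    """Bin edges from the bounding box of a trial run at the largest timestep.

    Shared across all conditions of a sweep so divergences are comparable.
    A small relative pad keeps later samples inside the box.
    """
    from ._kernels import compile_scheme, run_record

    config = IntegratorConfig(splitting=splitting, dt=dt_max, gamma=gamma)
    pot_id, beta, m, codes, taus, a_coef, sigma = compile_scheme(system, config)
    s_x, s_v, s_run = _child_seeds(rng_seed, 3)
    x0 = float(sample_equilibrium_positions(system, 1, s_x)[0])
    v0 = float(sample_velocities(system, 1, s_v)[0])
    xs, vs, _, ok = run_record(pot_id, beta, m, codes, taus, a_coef, sigma,
                               x0, v0, n_steps, 1, s_run)
    if not ok or xs.size == 0:
        raise InstabilityError(f"trial run at dt={dt_max} diverged")

    def padded(lo, hi):
        span = hi - lo
        return np.linspace(lo - pad * span, hi + pad * span, n_bins + 1)

    return padded(xs.min(), xs.max()), padded(vs.min(), vs.max())


def histogram_kl_estimate(system: SystemSpec, config: IntegratorConfig,
                          mode: str = "configuration", n_steps: int = 1_000_000,
                          burn_in: int = 10_000, n_chains: int = 5,
                          edges=None, rng_seed=0, debias: bool = True) -> KLEstimate:
    """Exact-reference KL estimate from long steady-state trajectories (1D).

    Runs ``n_chains`` independent chains of ``n_steps`` cycles (after
    ``burn_in``) from equilibrium starts, histograms the steady state on
    ``edges`` (derived from a trial run when omitted), and evaluates the
    divergence against the quadrature equilibrium density -- the full
    phase-space density in ``phase`` mode, the x-marginal in
    ``configuration`` mode.  The CI is the normal interval over the
    per-chain divergences.

    The plug-in histogram divergence carries an O(1/n) positive bias of
    roughly (occupied bins)/(2 n_eff), which floors small divergences; with
    ``debias`` (default) each chain's estimate is jackknife-extrapolated in
    sample size (2*KL_full - mean of the two half-chain KLs), which removes
    the leading bias term including its autocorrelation inflation.
    """
    from ._kernels import compile_scheme, run_record

    if edges is None:
        edges = determine_edges(system, config.name, config.dt, config.gamma,
                                rng_seed=rng_seed)
    x_edges, v_edges = edges
    pot_id, beta, m, codes, taus, a_coef, sigma = compile_scheme(system, config)
    reference = (phase_space_reference(system, x_edges, v_edges)
                 if mode == "phase"
                 else equilibrium_density_1d(system, x_edges,
                                             check_refinement=False))

    def _kl(xs, vs):
        if mode == "phase":
            hist = Histogram.from_samples(np.column_stack([xs, vs]),
                                          (x_edges, v_edges))
        else:
            hist = Histogram.from_samples(xs, (x_edges,))
        return histogram_kl(hist, reference)

    kls = np.empty(n_chains)
    for c, seed in enumerate(_child_seeds(rng_seed, n_chains)):
        s_x, s_v, s_run = _child_seeds(seed, 3)
        x0 = float(sample_equilibrium_positions(system, 1, s_x)[0])
        v0 = float(sample_velocities(system, 1, s_v)[0])
        xs, vs, _, ok = run_record(pot_id, beta, m, codes, taus, a_coef, sigma,
                                   x0, v0, n_steps + burn_in, 1, s_run)
        if not ok:
            raise InstabilityError(
                f"steady-state chain diverged (dt={config.dt}, {config.name})")
        xs, vs = xs[burn_in:], vs[burn_in:]
        full = _kl(xs, vs)
        if debias:
            h = xs.size // 2
            halves = 0.5 * (_kl(xs[:h], vs[:h]) + _kl(xs[h:], vs[h:]))
            kls[c] = 2.0 * full - halves
        else:
            kls[c] = full
    value = float(kls.mean())
    half = 1.96 * float(kls.std(ddof=1)) / np.sqrt(n_chains) if n_chains > 1 else 0.0
    return KLEstimate(value=value, ci_low=value - half, ci_high=value + half,
                      estimator="histogram", n=n_chains * n_steps,
                      meta={"mode": mode, "n_chains": n_chains,
                            "per_chain": kls.tolist()})


# ---------------------------------------------------------------------------
# sweeps


_ROW_COLUMNS = ["system", "splitting", "dt", "gamma", "mode", "estimator",
                "kl", "ci_low", "ci_high", "n", "unstable", "seed"]


def _estimate_row(cfg: SweepConfig, splitting, dt, gamma, mode, edges, seed):
    config = IntegratorConfig(splitting=splitting, dt=dt, gamma=gamma)
    estimator = cfg.pick_estimator()
    row = dict(system=cfg.system.name, splitting=splitting, dt=dt, gamma=gamma,
               mode=mode, estimator=estimator, kl=np.nan, ci_low=np.nan,
               ci_high=np.nan, n=0, unstable=False, seed=seed)
    try:
        if estimator == "histogram":
            est = histogram_kl_estimate(cfg.system, config, mode,
                                        n_steps=cfg.n_steps, burn_in=cfg.burn_in,
                                        n_chains=cfg.n_chains, edges=edges,
                                        rng_seed=seed)
        else:
            est = estimate_kl(cfg.system, config, mode,
                              n_steps_T=cfg.n_steps_T,
                              n_samples=cfg.n_samples, rng_seed=seed)
        row.update(kl=est.value, ci_low=est.ci_low, ci_high=est.ci_high, n=est.n)
    except InstabilityError:
        row["unstable"] = True
    return row


def _sweep(cfg: SweepConfig, conditions):
    edges = None
    if cfg.pick_estimator() == "histogram":
        dt_max = max(dt for _, dt, _, _ in conditions)
        gamma0 = cfg.gamma_grid[0]
        edges = determine_edges(cfg.system, cfg.splittings[0], dt_max, gamma0,
                                rng_seed=cfg.seed)
    seeds = _child_seeds(cfg.seed, len(conditions))
    rows = [_estimate_row(cfg, splitting, dt, gamma, mode, edges, seed)
            for (splitting, dt, gamma, mode), seed in zip(conditions, seeds)]
    return pd.DataFrame(rows, columns=_ROW_COLUMNS)


def sweep_timesteps(cfg: SweepConfig) -> pd.DataFrame:
    """KL estimates over (splitting, dt, mode) at gamma = gamma_grid[0]."""
    gamma = cfg.gamma_grid[0]
    conditions = [(s, dt, gamma, mode) for s in cfg.splittings
                  for dt in cfg.dt_grid for mode in cfg.modes]
    return _sweep(cfg, conditions)


def sweep_collision_rates(cfg: SweepConfig) -> pd.DataFrame:
    """KL estimates over (splitting, gamma, mode) at dt = dt_grid[0]."""
    dt = cfg.dt_grid[0]
    conditions = [(s, dt, gamma, mode) for s in cfg.splittings
                  for gamma in cfg.gamma_grid for mode in cfg.modes]
    return _sweep(cfg, conditions)


# ---------------------------------------------------------------------------
# sandwich validation


def sandwich_validation(cfg: SweepConfig) -> pd.DataFrame:
    """Nested-MC / near-equilibrium / Jensen comparison per condition (1D).

    One row per (splitting, dt, mode) at gamma = gamma_grid[0] holding all
    three estimates with CIs plus the histogram ground truth, and a boolean
    ``sandwiched`` column: nested <= near-eq <= Jensen within the 95%
    intervals.

    When ``cfg.n_steps_T`` is None the protocol half-length of each
    (splitting, dt) pair is chosen by :func:`auto_protocol_length`, doubling
    from the two-collision-time default until estimates at T and 2T are
    concordant; the same length is used as the steady-state decorrelation
    time.
    """
    from .near_equilibrium import auto_protocol_length
    if cfg.system.dimension != 1:
        raise ValueError("sandwich validation needs a 1D system (histogram truth)")
    gamma = cfg.gamma_grid[0]
    controller = InnerLoopController(sigma_threshold=cfg.sigma_threshold,
                                     budget=cfg.budget)
    edges = determine_edges(cfg.system, cfg.splittings[0], max(cfg.dt_grid),
                            gamma, rng_seed=cfg.seed)
    lengths: dict[tuple[str, float], int] = {}
    if cfg.n_steps_T is None:
        for s in cfg.splittings:
            for dt in cfg.dt_grid:
                config = IntegratorConfig(splitting=s, dt=dt, gamma=gamma)
                lengths[(s, dt)] = auto_protocol_length(
                    cfg.system, config, "phase",
                    n_samples=max(100_000, cfg.n_samples), rng_seed=cfg.seed)
    conditions = [(s, dt, mode) for s in cfg.splittings
                  for dt in cfg.dt_grid for mode in cfg.modes]
    seeds = _child_seeds(cfg.seed, len(conditions))
    rows = []
    for (splitting, dt, mode), seed in zip(conditions, seeds):
        config = IntegratorConfig(splitting=splitting, dt=dt, gamma=gamma)
        s_nest, s_neq, s_hist = _child_seeds(seed, 3)
        T = cfg.n_steps_T or lengths[(splitting, dt)]
        result = run_nested_estimate(cfg.system, config, mode, n_steps_T=T,
                                     n_outer=cfg.n_outer, controller=controller,
                                     decorrelation_steps=T, rng_seed=s_nest)
        neq = estimate_kl(cfg.system, config, mode, n_steps_T=T,
                          n_samples=cfg.n_samples, rng_seed=s_neq)
        hist = histogram_kl_estimate(cfg.system, config, mode,
                                     n_steps=cfg.n_steps, burn_in=cfg.burn_in,
                                     n_chains=cfg.n_chains, edges=edges,
                                     rng_seed=s_hist)
        nested, jensen = result.nested, result.jensen
        sandwiched = (nested.ci_low <= neq.ci_high
                      and neq.ci_low <= jensen.ci_high)
        brackets = (nested.ci_low <= hist.ci_high
                    and hist.ci_low <= jensen.ci_high)
        rows.append(dict(
            system=cfg.system.name, splitting=splitting, dt=dt, gamma=gamma,
            mode=mode, n_steps_T=T,
            nested=nested.value, nested_lo=nested.ci_low, nested_hi=nested.ci_high,
            near_eq=neq.value, near_eq_lo=neq.ci_low, near_eq_hi=neq.ci_high,
            jensen=jensen.value, jensen_lo=jensen.ci_low, jensen_hi=jensen.ci_high,
            hist_truth=hist.value, hist_lo=hist.ci_low, hist_hi=hist.ci_high,
            n_outer=cfg.n_outer,
            n_unconverged=sum(1 for m_ in result.jagged.row_meta
                              if not m_.get("converged", True)),
            sandwiched=sandwiched, brackets_truth=brackets, seed=seed))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stability scan


def stability_scan(system: SystemSpec, splitting: str, dt_grid, gamma: float,
                   n_trajectories: int = 10, n_steps: int = 10_000,
                   rng_seed=0, return_table: bool = False):
    """Empirical maximum stable timestep.

    For each dt on the (increasing) grid, runs ``n_trajectories`` independent
    trajectories of ``n_steps`` cycles from equilibrium starts; dt is stable
    iff every trajectory stays finite with |x| < 1e6.  Returns the largest
    stable grid point (and the per-dt table when requested).
    """
    dt_grid = np.asarray(dt_grid, float)
    if np.any(np.diff(dt_grid) <= 0):
        raise ValueError("dt_grid must be strictly increasing")
    records = []
    for dt, seed in zip(dt_grid, _child_seeds(rng_seed, dt_grid.size)):
        config = IntegratorConfig(splitting=splitting, dt=float(dt), gamma=gamma)
        s_x, s_v, s_run = _child_seeds(seed, 3)
        if system.dimension == 1 and system.pot_id >= 0:
            from ._kernels import batch_work, compile_scheme
            pot_id, beta, m, codes, taus, a_coef, sigma = \
                compile_scheme(system, config)
            x0 = sample_equilibrium_positions(system, n_trajectories, s_x)
            v0 = sample_velocities(system, n_trajectories, s_v)
            _, _, _, ok = batch_work(pot_id, beta, m, codes, taus, a_coef,
                                     sigma, x0, v0, n_steps, s_run)
            n_stable = int(np.sum(ok))
        else:
            x0 = np.atleast_2d(sample_equilibrium_positions(system,
                                                            n_trajectories, s_x))
            v0 = np.atleast_2d(sample_velocities(system, n_trajectories, s_v))
            n_stable = 0
            for i, s in enumerate(_child_seeds(s_run, n_trajectories)):
                try:
                    run_steps(system, config, PhasePoint(x=x0[i], v=v0[i]),
                              n_steps, s)
                    n_stable += 1
                except InstabilityError:
                    pass
        records.append(dict(dt=float(dt), n_stable=n_stable,
                            n_trajectories=n_trajectories,
                            stable=n_stable == n_trajectories))
    table = pd.DataFrame(records)
    stable_dts = table.loc[table["stable"], "dt"]
    if stable_dts.empty:
        raise InstabilityError("no stable timestep on the supplied grid")
    max_stable = float(stable_dts.max())
    return (max_stable, table) if return_table else max_stable


# ---------------------------------------------------------------------------
# table IO


def write_table(df: pd.DataFrame, path) -> None:
    """Write a results table as CSV with full float precision."""
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a results table written by :func:`write_table`."""
    return pd.read_csv(path)
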