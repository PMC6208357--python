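"""Reference KL-divergence estimators: nested Monte Carlo, Jensen bound,
and exact histogram/quadrature divergences for 1D systems.

The nested estimator uses the identity rho(z)/pi(z) = <e^-w>_z, the
conditional exponential work average over T-step protocol realizations
started from z.  Averaging its log over steady-state draws gives

    D_KL = < ln <e^-w>_z >_rho  ~=  (1/N) sum_i ln[ (1/M_i) sum_j e^-w_ij ],

asymptotically exact as both the outer count N and inner counts M_i grow,
and a finite-sample *under*-estimate (each inner log-mean is biased low by
roughly sigma_inner^2 / 2M).  An adaptive inner loop draws work samples until
the Taylor-propagated uncertainty of each inner log-mean falls below a
threshold or a budget is exhausted.  Applying Jensen's inequality instead
yields the upper bound ln <e^-w>_rho, estimated here by averaging the inner
means with equal weight per outer draw, which keeps the bound algebraically
above the nested estimate even for jagged rows.

Uncertainties come from a two-level bootstrap: rows (outer draws) are
resampled with replacement, then columns within each row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .integrators import IntegratorConfig, run_steps
from .near_equilibrium import KLEstimate, _child_seeds, default_protocol_length
from .systems import (DensityGrid1D, PhasePoint, SystemSpec,
                      equilibrium_density_1d, sample_equilibrium_positions,
                      sample_velocities)

__all__ = [
    "JaggedWorkSamples",
    "InnerLoopController",
    "Histogram",
    "InfiniteDivergenceError",
    "sample_steady_state_start",
    "collect_inner_work",
    "nested_mc_kl",
    "jensen_upper_bound",
    "histogram_kl",
    "bootstrap_jagged",
    "run_nested_estimate",
    "NestedResult",
    "phase_space_reference",
    "velocity_bin_masses",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class JaggedWorkSamples:
    """Variable-length rows of work samples, one row per outer-loop draw."""

    rows: list[np.ndarray]
    row_meta: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rows = [np.asarray(r, dtype=float) for r in self.rows]
        for i, r in enumerate(self.rows):
            if r.size == 0:
                raise ValueError(f"row {i} is empty")
            if not np.all(np.isfinite(r)):
                raise ValueError(f"row {i} contains non-finite work values")
        if not self.row_meta:
            self.row_meta = [{} for _ in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.rows)


@dataclass(frozen=True)
class InnerLoopController:
    """Adaptive inner-loop settings for the nested estimator.

    ``sigma_threshold`` is the target standard deviation of each inner
    log-mean estimate; ``budget`` caps the samples per row; ``batch`` sets
    the check cadence; at least ``min_samples`` are always drawn so the
    uncertainty is estimable before any stop decision.
    """

    sigma_threshold: float = 0.01
    budget: int = 50_000
    batch: int = 100
    min_samples: int = 50

    def __post_init__(self) -> None:
        if not self.sigma_threshold > 0:
            raise ValueError("sigma_threshold must be positive")
        if not (self.budget >= self.batch >= 1):
            raise ValueError("need budget >= batch >= 1")


@dataclass
class Histogram:
    """Binned probability masses on a rectilinear grid (any dimension)."""

    edges: tuple[np.ndarray, ...]
    masses: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        self.edges = tuple(np.asarray(e, dtype=float) for e in self.edges)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != tuple(e.size - 1 for e in self.edges):
            raise ValueError("masses shape does not match bin edges")
        if self.normalized and abs(self.masses.sum() - 1.0) > 1e-12:
            raise ValueError("normalized masses must sum to 1 within 1e-12")

    @classmethod
    def from_samples(cls, samples, edges) -> "Histogram":
        """Bin samples (shape (n,) or (n, d)) onto the given edges."""
        samples = np.asarray(samples, dtype=float)
        if samples.ndim == 1:
            samples = samples[:, None]
        edges = [np.asarray(e, dtype=float) for e in edges]
        counts, _ = np.histogramdd(samples, bins=edges)
        total = counts.sum()
        if total == 0:
            raise ValueError("no samples fell inside the histogram edges")
        return cls(edges=tuple(edges), masses=counts / total)


class InfiniteDivergenceError(ValueError):
    """Sample mass found where the reference density has none."""

    def __init__(self, bins):
        self.bins = bins
        super().__init__(f"sample mass in zero-reference bins {bins[:10]!r}"
                         + ("..." if len(bins) > 10 else ""))


# ---------------------------------------------------------------------------
# histogram / quadrature reference machinery


def velocity_bin_masses(system: SystemSpec, edges) -> np.ndarray:
    """Maxwell-Boltzmann bin masses on ``edges`` (1D), renormalized to the grid."""
    from scipy.stats import norm

    sig = 1.0 / np.sqrt(system.beta * system.masses[0])
    cdf = norm.cdf(np.asarray(edges, float), scale=sig)
    masses = np.diff(cdf)
    return masses / masses.sum()


def phase_space_reference(system: SystemSpec, x_edges, v_edges) -> Histogram:
    """Equilibrium phase-space bin masses pi(x, v) for a 1D system.

    The position factor comes from trapezoidal quadrature of e^-u(x); the
    velocity factor is the exact Gaussian bin mass.  Both are renormalized
    over the grid so the product is a probability table.
    """
    px = equilibrium_density_1d(system, x_edges, check_refinement=False).masses
    pv = velocity_bin_masses(system, v_edges)
    return Histogram(edges=(np.asarray(x_edges, float), np.asarray(v_edges, float)),
                     masses=np.outer(px, pv))


def _as_masses(obj):
    if isinstance(obj, DensityGrid1D):
        return (obj.edges,), obj.masses
    return obj.edges, obj.masses


def histogram_kl(sample_hist: Histogram, reference) -> float:
    """KL divergence sum_b p_b ln(p_b / q_b) between aligned histograms.

    ``reference`` may be a :class:`Histogram` or a 1D
    :class:`~splitkl.systems.DensityGrid1D`.  Bins with p = 0 contribute
    zero; p > 0 where q = 0 raises :class:`InfiniteDivergenceError` with the
    offending bin indices.
    """
    p_edges, p = _as_masses(sample_hist)
    q_edges, q = _as_masses(reference)
    if len(p_edges) != len(q_edges) or any(
            pe.size != qe.size or not np.allclose(pe, qe)
            for pe, qe in zip(p_edges, q_edges)):
        raise ValueError("sample and reference histograms must share bin edges")
    support = p > 0
    bad = support & (q == 0)
    if np.any(bad):
        raise InfiniteDivergenceError([tuple(i) for i in np.argwhere(bad)])
    return float(np.sum(p[support] * np.log(p[support] / q[support])))


# ---------------------------------------------------------------------------
# nested Monte Carlo machinery


def sample_steady_state_start(system: SystemSpec, config: IntegratorConfig,
                              mode: str = "phase",
                              decorrelation_steps: int | None = None,
                              rng_seed=0) -> PhasePoint:
    """One approximate draw from rho (phase mode) or omega (configuration mode).

    Draws (x, v) ~ pi and relaxes it with ``decorrelation_steps`` integrator
    cycles (default: steps spanning two collision times); configuration mode
    then replaces the velocity with a fresh pi(v|x) draw.
    """
    if decorrelation_steps is None:
        decorrelation_steps = default_protocol_length(config)
    s_x, s_v, s_run, s_mid = _child_seeds(rng_seed, 4)
    x0 = np.atleast_1d(sample_equilibrium_positions(system, 1, s_x)[0])
    v0 = np.atleast_1d(sample_velocities(system, 1, s_v)[0])
    z = PhasePoint(x=x0, v=v0)
    if decorrelation_steps > 0:
        z, _ = run_steps(system, config, z, decorrelation_steps, s_run)
    if mode == "configuration":
        v = np.atleast_1d(sample_velocities(system, 1, s_mid)[0])
        z = PhasePoint(x=z.x, v=v)
    return z


def _inner_sigma(works: np.ndarray) -> float:
    """First-order Taylor propagation: sd of ln(mean e^-w) ~ sd(e^-w)/(mean sqrt(M))."""
    y = np.exp(-works)
    m = y.mean()
    return float(y.std(ddof=1) / (m * np.sqrt(y.size)))


def collect_inner_work(system: SystemSpec, config: IntegratorConfig,
                       start: PhasePoint, n_steps_T: int,
                       controller: InnerLoopController | None = None,
                       rng_seed=0):
    """Adaptive inner loop: T-step work samples from one fixed start.

    Repeatedly runs the protocol from ``start`` with fresh noise, in batches,
    until the Taylor-propagated uncertainty of the inner log-mean falls below
    ``controller.sigma_threshold`` or the budget is exhausted.  Returns
    ``(works, sigma_inner, converged)``; budget-exhausted rows are retained
    and flagged rather than discarded.
    """
    controller = controller or InnerLoopController()
    fast = system.dimension == 1 and system.pot_id >= 0
    if fast:
        from ._kernels import batch_work, compile_scheme
        kern_args = compile_scheme(system, config)

    seeds = iter(_child_seeds(rng_seed, 2**12))
    works: list[np.ndarray] = []
    total = 0

    def draw(count: int) -> np.ndarray:
        if fast:
            pot_id, beta, m, codes, taus, a_coef, sigma = kern_args
            x0 = np.full(count, float(start.x[0]))
            v0 = np.full(count, float(start.v[0]))
            _, _, w, ok = batch_work(pot_id, beta, m, codes, taus, a_coef,
                                     sigma, x0, v0, n_steps_T, next(seeds))
            if not np.all(ok):
                raise RuntimeError("inner-loop realization diverged")
            return w
        out = np.empty(count)
        for i in range(count):
            _, ledger = run_steps(system, config, start, n_steps_T, next(seeds))
            out[i] = ledger.shadow_work
        return out

    while True:
        need = max(controller.batch,
                   controller.min_samples - total if total == 0 else 0)
        need = min(need, controller.budget - total)
        works.append(draw(need))
        total += need
        all_works = np.concatenate(works)
        sigma_inner = _inner_sigma(all_works)
        if total >= controller.min_samples and sigma_inner <= controller.sigma_threshold:
            return all_works, sigma_inner, True
        if total >= controller.budget:
            return all_works, sigma_inner, False


def _row_log_means(jagged: JaggedWorkSamples) -> np.ndarray:
    return np.array([logsumexp(-r) - np.log(r.size) for r in jagged.rows])


def nested_mc_kl(jagged: JaggedWorkSamples, n_boot: int = 100,
                 rng_seed=0) -> KLEstimate:
    """Nested Monte Carlo estimate (1/N) sum_i ln mean_j e^-w_ij.

    A finite-sample under-estimate of the KL divergence; the 95% CI comes
    from the two-level jagged bootstrap.
    """
    if jagged.n_rows < 2:
        raise ValueError("need at least 2 outer-loop rows")
    value = float(_row_log_means(jagged).mean())
    lo, hi = bootstrap_jagged(jagged, "nested", n_boot=n_boot, rng_seed=rng_seed)
    return KLEstimate(value=value, ci_low=min(lo, value), ci_high=max(hi, value),
                      estimator="nested_mc", n=jagged.n_rows,
                      meta={"bias_direction": "under-estimate",
                            "inner_counts": [int(r.size) for r in jagged.rows]})


def jensen_upper_bound(jagged: JaggedWorkSamples, n_boot: int = 100,
                       rng_seed=0) -> KLEstimate:
    """Upper bound ln <e^-w>: log of the row-balanced mean of e^-w.

    Each outer draw contributes its inner mean with equal weight, so the
    bound dominates the nested estimate by Jensen's inequality regardless of
    row lengths.
    """
    row_means = _row_log_means(jagged)
    value = float(logsumexp(row_means) - np.log(row_means.size))
    if jagged.n_rows >= 2:
        lo, hi = bootstrap_jagged(jagged, "jensen", n_boot=n_boot, rng_seed=rng_seed)
    else:
        lo = hi = value
    return KLEstimate(value=value, ci_low=min(lo, value), ci_high=max(hi, value),
                      estimator="jensen_bound", n=jagged.n_rows)


_STATISTICS = {
    "nested": lambda j: float(_row_log_means(j).mean()),
    "jensen": lambda j: float(logsumexp(_row_log_means(j))
                              - np.log(len(j.rows))),
}


def bootstrap_jagged(jagged: JaggedWorkSamples, statistic: str,
                     n_boot: int = 100, rng_seed=0):
    """Two-level bootstrap 95% interval: resample rows, then columns within rows."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    stat = _STATISTICS[statistic]
    rng = np.random.default_rng(rng_seed)
    n = jagged.n_rows
    values = np.empty(n_boot)
    for b in range(n_boot):
        rows = []
        for i in rng.integers(0, n, size=n):
            r = jagged.rows[i]
            rows.append(r[rng.integers(0, r.size, size=r.size)])
        values[b] = stat(JaggedWorkSamples(rows=rows))
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# end-to-end driver


@dataclass(frozen=True)
class NestedResult:
    """Jagged work samples with their nested estimate and Jensen bound."""

    jagged: JaggedWorkSamples
    nested: KLEstimate
    jensen: KLEstimate


def run_nested_estimate(system: SystemSpec, config: IntegratorConfig,
                        mode: str = "phase", n_steps_T: int | None = None,
                        n_outer: int = 100,
                        controller: InnerLoopController | None = None,
                        decorrelation_steps: int | None = None,
                        n_boot: int = 100, rng_seed=0) -> NestedResult:
    """Collect a jagged work array and evaluate both reference estimators."""
    if n_steps_T is None:
        n_steps_T = default_protocol_length(config)
    if decorrelation_steps is None:
        # relax at least as long as the (validated) protocol half-length
        decorrelation_steps = max(n_steps_T, default_protocol_length(config))
    controller = controller or InnerLoopController()
    s_starts, s_inner, s_boot = _child_seeds(rng_seed, 3)

    starts = _batch_starts(system, config, mode, decorrelation_steps,
                           n_outer, s_starts)
    rows, meta = [], []
    inner_seeds = _child_seeds(s_inner, n_outer)
    for start, seed in zip(starts, inner_seeds):
        w, sig, converged = collect_inner_work(system, config, start,
                                               n_steps_T, controller, seed)
        rows.append(w)
        meta.append({"sigma_inner": sig, "converged": converged,
                     "inner_count": int(w.size),
                     "start": (start.x.tolist(), start.v.tolist())})
    jagged = JaggedWorkSamples(rows=rows, row_meta=meta)
    nested = nested_mc_kl(jagged, n_boot=n_boot, rng_seed=s_boot)
    jensen = jensen_upper_bound(jagged, n_boot=n_boot, rng_seed=s_boot)
    for est in (nested, jensen):
        est.meta.update(system=system.name, splitting=config.name,
                        dt=config.dt, gamma=config.gamma, mode=mode,
                        n_steps_T=n_steps_T,
                        decorrelation_steps=decorrelation_steps)
    return NestedResult(jagged=jagged, nested=nested, jensen=jensen)


def _batch_starts(system, config, mode, decorrelation_steps, n_outer, seed):
    """n_outer approximate steady-state draws, batched on the fast path."""
    if system.dimension == 1 and system.pot_id >= 0:
        from ._kernels import batch_work, compile_scheme
        pot_id, beta, m, codes, taus, a_coef, sigma = compile_scheme(system, config)
        s_x, s_v, s_run, s_mid = _child_seeds(seed, 4)
        x0 = sample_equilibrium_positions(system, n_outer, s_x)
        v0 = sample_velocities(system, n_outer, s_v)
        if decorrelation_steps > 0:
            x0, v0, _, ok = batch_work(pot_id, beta, m, codes, taus, a_coef,
                                       sigma, x0, v0, decorrelation_steps, s_run)
            if not np.all(ok):
                raise RuntimeError("steady-state decorrelation diverged")
        if mode == "configuration":
            v0 = sample_velocities(system, n_outer, s_mid)
        return [PhasePoint(x=[x], v=[v]) for x, v in zip(x0, v0)]
    seeds = _child_seeds(seed, n_outer)
    return [sample_steady_state_start(system, config, mode,
                                      decorrelation_steps, s) for s in seeds]
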