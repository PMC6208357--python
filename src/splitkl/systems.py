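"""Potential-energy models, target densities, and equilibrium sampling.

All energies are *reduced* (unitless): the reduced potential is
``u(x) = beta * U(x)`` and the reduced kinetic energy is
``t(v) = beta * v^T M v / 2``, so works and Hamiltonians are measured in
units of kT throughout.  ``beta`` is carried explicitly on every system so
physical-unit wrappers can be layered on later.

Built-in models
---------------
``quartic``
    U(x) = sum_i x_i^4.  One-dimensional by default; any dimension gives the
    separable n-D analogue.
``double_well``
    U(x) = x^6 + 2 cos(5 (x + 1)), a 1D double well with an x^6 confining
    envelope.  Defaults beta=1, m=10.
``lj_cluster``
    A small Lennard-Jones cluster (epsilon = sigma = 1) of ``n_particles``
     3D particles held together by a harmonic restraint of stiffness ``k``
    centred at the origin.  A native n-D toy with molecular geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "SystemSpec",
    "PhasePoint",
    "DensityGrid1D",
    "make_system",
    "system_from_config",
    "register_system",
    "potential_energy",
    "force",
    "kinetic_energy",
    "reduced_hamiltonian",
    "support_1d",
    "equilibrium_density_1d",
    "sample_equilibrium_positions",
    "sample_velocities",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SystemSpec:
    """A potential model plus diagonal mass matrix and inverse temperature."""

    name: str
    dimension: int
    potential_params: Mapping[str, float]
    masses: np.ndarray
    beta: float
    # integer id of a jit-compiled 1D potential, or -1 for the generic path
    pot_id: int = -1

    def __post_init__(self) -> None:
        masses = np.atleast_1d(np.asarray(self.masses, dtype=float))
        if masses.size == 1 and self.dimension > 1:
            masses = np.full(self.dimension, masses[0])
        object.__setattr__(self, "masses", masses)
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if masses.shape != (self.dimension,):
            raise ValueError("masses must have one entry per degree of freedom")
        if not np.all(masses > 0):
            raise ValueError("all masses must be positive")
        if not self.beta > 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class PhasePoint:
    """A phase-space point z = (x, v) with positions and velocities."""

    x: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        x = np.atleast_1d(np.asarray(self.x, dtype=float))
        v = np.atleast_1d(np.asarray(self.v, dtype=float))
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "v", v)
        if x.shape != v.shape:
            raise ValueError("x and v must have identical shapes")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
            raise ValueError("phase point components must be finite")


@dataclass(frozen=True)
class DensityGrid1D:
    """Per-bin probability masses of a 1D density on a fixed grid."""

    edges: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        masses = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "masses", masses)
        if masses.size != edges.size - 1:
            raise ValueError("need len(masses) == len(edges) - 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if abs(masses.sum() - 1.0) > 1e-12:
            raise ValueError("masses must sum to 1 within 1e-12")


# ---------------------------------------------------------------------------
# potential registry

# name -> (U(x, params), gradU(x, params), default factory kwargs, pot_id)
_REGISTRY: dict[str, tuple[Callable, Callable, dict, int]] = {}


def register_system(name, potential, gradient, defaults=None, pot_id=-1):
    """Register a potential model under ``name``.

    ``potential(x, params) -> float`` and ``gradient(x, params) -> array``
    operate on flat coordinate vectors.  ``defaults`` may carry ``beta``,
    ``mass``, ``dimension`` and potential parameters.
    """
    _REGISTRY[name] = (potential, gradient, dict(defaults or {}), pot_id)


def _quartic_U(x, params):
    return float(np.sum(x**4))


def _quartic_grad(x, params):
    return 4.0 * x**3


def _double_well_U(x, params):
    xx = float(x[0])
    return xx**6 + 2.0 * np.cos(5.0 * (xx + 1.0))


def _double_well_grad(x, params):
    xx = float(x[0])
    return np.array([6.0 * xx**5 - 10.0 * np.sin(5.0 * (xx + 1.0))])


def _lj_cluster_U(x, params):
    k = params.get("k", 1.0)
    r = x.reshape(-1, 3)
    u = 0.5 * k * float(np.sum(r * r))
    n = r.shape[0]
    for i in range(n - 1):
        d = r[i + 1 :] - r[i]
        r2 = np.sum(d * d, axis=1)
        inv6 = 1.0 / r2**3
        u += float(np.sum(4.0 * (inv6 * inv6 - inv6)))
    return u


def _lj_cluster_grad(x, params):
    k = params.get("k", 1.0)
    r = x.reshape(-1, 3)
    g = k * r.copy()
    n = r.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            d = r[j] - r[i]
            r2 = float(d @ d)
            inv2 = 1.0 / r2
            inv6 = inv2**3
            # dU/dr2 * 2 = 4(-12 r^-14 + 6 r^-8) vector coefficient
            coef = 24.0 * inv2 * inv6 * (1.0 - 2.0 * inv6)
            g[j] += coef * d
            g[i] -= coef * d
    return g.reshape(-1)


register_system("quartic", _quartic_U, _quartic_grad,
                {"beta": 1.0, "mass": 1.0, "dimension": 1}, pot_id=0)
register_system("double_well", _double_well_U, _double_well_grad,
                {"beta": 1.0, "mass": 10.0, "dimension": 1}, pot_id=1)
register_system("lj_cluster", _lj_cluster_U, _lj_cluster_grad,
                {"beta": 1.0, "mass": 1.0, "n_particles": 5, "k": 1.0})


def initial_position(system: SystemSpec) -> np.ndarray:
    """A finite-energy starting configuration for chains and trajectories."""
    if system.name == "lj_cluster":
        # particles on a loose cubic lattice near the pair-potential minimum
        n = system.dimension // 3
        side = int(np.ceil(n ** (1.0 / 3.0)))
        spacing = 2.0 ** (1.0 / 6.0)
        pts = [(i, j, k) for i in range(side) for j in range(side)
               for k in range(side)][:n]
        r = spacing * (np.array(pts, dtype=float) - (side - 1) / 2.0)
        return r.reshape(-1)
    return np.zeros(system.dimension)


def make_system(name: str, beta=None, masses=None, **params) -> SystemSpec:
    """Instantiate a registered system, overriding defaults as needed."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown system {name!r}; known: {sorted(_REGISTRY)}")
    _, _, defaults, pot_id = _REGISTRY[name]
    merged = dict(defaults)
    merged.update(params)
    beta = merged.pop("beta") if beta is None else beta
    mass = merged.pop("mass", 1.0)
    if name == "lj_cluster":
        dimension = 3 * int(merged.get("n_particles", 5))
    else:
        dimension = int(merged.pop("dimension", 1))
    if masses is None:
        masses = np.full(dimension, float(mass))
    # jit fast path only applies to the 1D form of a potential
    pid = pot_id if dimension == 1 else -1
    return SystemSpec(name=name, dimension=dimension, potential_params=merged,
                      masses=np.asarray(masses, float), beta=float(beta),
                      pot_id=pid)


def system_from_config(config: Mapping) -> SystemSpec:
    """Build a system from a ``{"system": {...}}`` or flat config block."""
    block = dict(config.get("system", config))
    name = block.pop("name")
    beta = block.pop("beta", None)
    masses = block.pop("masses", None)
    block.update(block.pop("params", {}))
    return make_system(name, beta=beta, masses=masses, **block)


# ---------------------------------------------------------------------------
# energies and forces


def _check_x(system: SystemSpec, x) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape != (system.dimension,):
        raise ValueError(
            f"position has shape {x.shape}, expected ({system.dimension},)")
    if not np.all(np.isfinite(x)):
        raise ValueError("position must be finite")
    return x


def potential_energy(system: SystemSpec, x) -> float:
    """Reduced potential u(x) = beta * U(x)."""
    x = _check_x(system, x)
    U = _REGISTRY[system.name][0]
    return system.beta * U(x, system.potential_params)


def force(system: SystemSpec, x) -> np.ndarray:
    """Unreduced force -grad U(x) (mass division happens in the V substep)."""
    x = _check_x(system, x)
    grad = _REGISTRY[system.name][1]
    return -np.asarray(grad(x, system.potential_params), dtype=float)


def kinetic_energy(system: SystemSpec, v) -> float:
    """Reduced kinetic energy t(v) = beta * v^T M v / 2."""
    v = np.atleast_1d(np.asarray(v, dtype=float))
    return 0.5 * system.beta * float(np.sum(system.masses * v * v))


def reduced_hamiltonian(system: SystemSpec, z: PhasePoint) -> float:
    """h(z) = u(x) + t(v), the reduced Hamiltonian."""
    return potential_energy(system, z.x) + kinetic_energy(system, z.v)


# ---------------------------------------------------------------------------
# 1D quadrature machinery


def support_1d(system: SystemSpec, tail_log: float = 60.0) -> tuple[float, float]:
    """Bounded domain outside which the Boltzmann density is negligible.

    Expands symmetrically until the reduced potential at both ends exceeds
    its interior minimum by ``tail_log`` (e^-60 ~ 1e-26, so the truncated
    tail mass is far below 1e-12).
    """
    if system.dimension != 1:
        raise ValueError("support_1d requires a 1D system")
    half = 1.0
    for _ in range(200):
        grid = np.linspace(-half, half, 4001)
        u = np.array([potential_energy(system, [g]) for g in grid])
        umin = u.min()
        if u[0] > umin + tail_log and u[-1] > umin + tail_log:
            return float(grid[0]), float(grid[-1])
        half *= 1.4
    raise RuntimeError("could not bound the density support (unconfined potential?)")


def _u_on_grid(system: SystemSpec, xs: np.ndarray) -> np.ndarray:
    # vectorized fast paths for the built-in 1D forms
    if system.pot_id == 0:
        return system.beta * xs**4
    if system.pot_id == 1:
        return system.beta * (xs**6 + 2.0 * np.cos(5.0 * (xs + 1.0)))
    U = _REGISTRY[system.name][0]
    p = system.potential_params
    return system.beta * np.array([U(np.array([g]), p) for g in xs])


def equilibrium_density_1d(system: SystemSpec, edges, points_per_bin: int = 10_000,
                           check_refinement: bool = True) -> DensityGrid1D:
    """Per-bin masses of the configuration marginal pi_x by trapezoidal quadrature.

    Each bin is subdivided into ``points_per_bin`` trapezoid panels; masses are
    normalized over the grid.  A coarse grid (bin mass shifting > 1e-4 under
    refinement) triggers a warning.
    """
    if system.dimension != 1:
        raise ValueError("equilibrium_density_1d requires a 1D system")
    edges = np.asarray(edges, dtype=float)

    def bin_integrals(npts: int) -> np.ndarray:
        out = np.empty(edges.size - 1)
        # subtract the global minimum before exponentiating for stability
        probe = np.linspace(edges[0], edges[-1], 4001)
        u0 = _u_on_grid(system, probe).min()
        for i in range(edges.size - 1):
            xs = np.linspace(edges[i], edges[i + 1], npts + 1)
            dens = np.exp(-(_u_on_grid(system, xs) - u0))
            out[i] = np.trapezoid(dens, xs)
        return out

    raw = bin_integrals(points_per_bin)
    masses = raw / raw.sum()
    if check_refinement:
        raw2 = bin_integrals(2 * points_per_bin)
        masses2 = raw2 / raw2.sum()
        if np.max(np.abs(masses - masses2)) > 1e-4:
            warnings.warn("quadrature grid too coarse to resolve the density; "
                          "increase points_per_bin", stacklevel=2)
    return DensityGrid1D(edges=edges, masses=masses)


def _inverse_cdf_table(system: SystemSpec, n_grid: int = 200_001):
    lo, hi = support_1d(system)
    xs = np.linspace(lo, hi, n_grid)
    u = _u_on_grid(system, xs)
    dens = np.exp(-(u - u.min()))
    dx = xs[1] - xs[0]
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * dx)])
    cdf /= cdf[-1]
    return xs, cdf


def sample_equilibrium_positions(system: SystemSpec, n: int, seed: int,
                                 **ghmc_kwargs) -> np.ndarray:
    """Draw ``n`` equilibrium position samples from pi_x.

    1D systems use exact inverse-CDF sampling on a dense quadrature grid
    (deterministic given ``seed``).  Higher-dimensional systems delegate to a
    Metropolized GHMC chain (exact stationary distribution) and thin it; the
    chain is checked for gross non-equilibration before returning.

    Returns an array of shape ``(n,)`` for 1D systems, else ``(n, dimension)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if system.dimension == 1:
        xs, cdf = _inverse_cdf_table(system)
        u = rng.random(n)
        return np.interp(u, cdf, xs)
    return _sample_equilibrium_nd(system, n, rng, **ghmc_kwargs)


def _sample_equilibrium_nd(system, n, rng, splitting="VRORV", dt=0.002,
                           gamma=1.0, steps_per_proposal=10, thin=None):
    from .ghmc import run_ghmc_chain
    from .integrators import IntegratorConfig

    config = IntegratorConfig(splitting=splitting, dt=dt, gamma=gamma)
    if thin is None:
        thin = max(1, int(np.ceil(10.0 * (1.0 / gamma) / dt / steps_per_proposal)))
    burn = 50 * thin
    n_iter = burn + n * thin
    seed = int(rng.integers(2**31 - 1))
    positions, _report = run_ghmc_chain(
        system, config, steps_per_proposal=steps_per_proposal,
        n_iterations=n_iter, rng_seed=seed, x0=None, thin=1)
    samples = positions[burn::thin][:n]
    _check_equilibration(samples)
    return samples


def _check_equilibration(samples: np.ndarray, n_batches: int = 10) -> None:
    """Split-half mean diagnostic with batch-mean standard errors.

    Batch means absorb residual autocorrelation; a first/second-half mean
    discrepancy beyond 3 SE flags a non-equilibrated chain.
    """
    if len(samples) < 4 * n_batches:
        return
    batches = np.array_split(np.asarray(samples, float), 2 * n_batches)
    means = np.stack([b.mean(axis=0) for b in batches])
    a, b = means[:n_batches], means[n_batches:]
    se = np.sqrt(a.var(axis=0, ddof=1) / n_batches + b.var(axis=0, ddof=1) / n_batches)
    se = np.where(se > 0, se, np.inf)
    if np.any(np.abs(a.mean(axis=0) - b.mean(axis=0)) > 3.0 * se):
        raise RuntimeError("equilibrium chain failed the split-half mean check; "
                           "increase chain length or thinning")


def sample_velocities(system: SystemSpec, n: int, seed: int) -> np.ndarray:
    """I.i.d. Maxwell-Boltzmann draws: each component ~ N(0, 1/(beta*m)).

    Returns shape ``(n,)`` for 1D systems, else ``(n, dimension)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sig = 1.0 / np.sqrt(system.beta * system.masses)
    out = rng.standard_normal((n, system.dimension)) * sig
    return out[:, 0] if system.dimension == 1 else out
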