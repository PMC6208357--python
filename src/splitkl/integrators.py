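"""Operator-splitting Langevin integrators with shadow-work accounting.

A splitting string over the alphabet {R, V, O} defines one integrator cycle:

* ``R`` — deterministic position drift, x' = x + v*tau;
* ``V`` — deterministic velocity kick, v' = v - M^-1 grad U(x) * tau;
* ``O`` — Ornstein-Uhlenbeck partial velocity randomization,
  v' = a v + sqrt((1 - a^2)/(beta M)) xi with a = e^(-gamma tau),
  xi ~ N(0, I).

Each letter occurring ``k`` times receives time fraction ``1/k`` of the full
timestep, so OVRVO executes O and V for dt/2 each and R for dt, while VRORV
executes V and R for dt/2 each and O for dt.

For a *symmetric* (palindromic) splitting the shadow work of a trajectory is
``w = dh - dq``: the change in reduced Hamiltonian minus the reduced heat
exchanged across the O substeps.  Only palindromic strings are accepted —
the work accounting implemented here is not valid for asymmetric ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .systems import (PhasePoint, SystemSpec, force, kinetic_energy,
                      potential_energy)

__all__ = [
    "SplittingScheme",
    "IntegratorConfig",
    "WorkLedger",
    "InstabilityError",
    "parse_splitting",
    "substep_R",
    "substep_V",
    "substep_O",
    "run_steps",
    "shadow_work",
    "STANDARD_SPLITTINGS",
]

#: the four schemes studied throughout the package
STANDARD_SPLITTINGS = ("OVRVO", "ORVRO", "RVOVR", "VRORV")

#: reduced-unit bound beyond which a trajectory is declared unstable
POSITION_BOUND = 1e6


class InstabilityError(RuntimeError):
    """A trajectory left the finite / bounded region of phase space."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


@dataclass(frozen=True)
class SplittingScheme:
    """An ordered substep sequence with per-substep time fractions."""

    letters: str
    fractions: tuple[float, ...]

    def __iter__(self):
        return iter(zip(self.letters, self.fractions))

    def __len__(self) -> int:
        return len(self.letters)


def parse_splitting(spec: str) -> SplittingScheme:
    """Parse a splitting string like ``"OVRVO"`` into a substep sequence.

    Each occurrence of a letter receives time fraction 1/count(letter), so
    per cycle every letter advances its sub-propagator by a full timestep.
    Non-palindromic strings are rejected: the shadow-work identity
    w = dh - dq assumes a symmetric splitting.
    """
    if not spec:
        raise ValueError("empty splitting string")
    letters = spec.upper()
    bad = set(letters) - set("RVO")
    if bad:
        raise ValueError(f"illegal splitting characters {sorted(bad)!r}; "
                         "allowed: R, V, O")
    if letters != letters[::-1]:
        raise ValueError(
            f"splitting {letters!r} is not palindromic; shadow-work "
            "accounting is only defined here for symmetric splittings")
    counts = {c: letters.count(c) for c in set(letters)}
    fractions = tuple(1.0 / counts[c] for c in letters)
    return SplittingScheme(letters=letters, fractions=fractions)


@dataclass
class IntegratorConfig:
    """Timestep, collision rate, and splitting of one integrator."""

    splitting: str | SplittingScheme
    dt: float
    gamma: float

    def __post_init__(self) -> None:
        if isinstance(self.splitting, str):
            self.splitting = parse_splitting(self.splitting)
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")

    @property
    def scheme(self) -> SplittingScheme:
        return self.splitting

    @property
    def name(self) -> str:
        return self.scheme.letters


@dataclass
class WorkLedger:
    """Per-trajectory energy bookkeeping.

    ``delta_h`` is the total change in reduced Hamiltonian, ``delta_q`` the
    reduced heat summed over O substeps; the shadow work is their difference,
    computed exactly as ``delta_h - delta_q``.
    """

    delta_h: float = 0.0
    delta_q: float = 0.0
    substep_records: list[tuple[str, float]] | None = None

    @property
    def shadow_work(self) -> float:
        return self.delta_h - self.delta_q


def shadow_work(ledger: WorkLedger) -> float:
    """Shadow work w = dh - dq of a finalized ledger."""
    return ledger.shadow_work


# ---------------------------------------------------------------------------
# substeps (generic, any dimension)


def substep_R(system: SystemSpec, z: PhasePoint, tau: float) -> PhasePoint:
    """Position drift x' = x + v * tau."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return PhasePoint(x=z.x + z.v * tau, v=z.v)


def substep_V(system: SystemSpec, z: PhasePoint, tau: float) -> PhasePoint:
    """Velocity kick v' = v - M^-1 grad U(x) * tau."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return PhasePoint(x=z.x, v=z.v + force(system, z.x) / system.masses * tau)


def substep_O(system: SystemSpec, z: PhasePoint, tau: float, gamma: float,
              xi: np.ndarray) -> PhasePoint:
    """Ornstein-Uhlenbeck velocity mixing with a fresh standard normal xi."""
    if tau < 0 or gamma < 0:
        raise ValueError("tau and gamma must be non-negative")
    xi = np.atleast_1d(np.asarray(xi, dtype=float))
    if xi.shape != z.v.shape:
        raise ValueError("xi must have the system dimension")
    a = np.exp(-gamma * tau)
    sig = np.sqrt((1.0 - a * a) / (system.beta * system.masses))
    return PhasePoint(x=z.x, v=a * z.v + sig * xi)


# ---------------------------------------------------------------------------
# trajectory driver


def run_steps(system: SystemSpec, config: IntegratorConfig, z0: PhasePoint,
              n_steps: int, rng_seed=None, *, return_trajectory: bool = False,
              record_substeps: bool = False):
    """Run ``n_steps`` full integrator cycles from ``z0``.

    One fresh standard-normal vector is consumed per O substep, in substep
    order, from a generator seeded with ``rng_seed`` (an int, Generator, or
    SeedSequence), so trajectories are reproducible.  Returns
    ``(z_final, ledger)`` or ``(z_final, ledger, trajectory)`` where the
    trajectory holds the state after every cycle (including the start).

    Raises :class:`InstabilityError` if the state leaves the finite region
    ``|x| <= 1e6``.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    rng = np.random.default_rng(rng_seed)
    scheme = config.scheme
    dt, gamma = config.dt, config.gamma
    z = PhasePoint(x=z0.x.copy(), v=z0.v.copy())
    ledger = WorkLedger(substep_records=[] if record_substeps else None)
    h0 = potential_energy(system, z.x) + kinetic_energy(system, z.v)
    traj = [z] if return_trajectory else None

    for step in range(n_steps):
        for letter, fraction in scheme:
            tau = fraction * dt
            try:
                if letter == "R":
                    z_new = substep_R(system, z, tau)
                elif letter == "V":
                    z_new = substep_V(system, z, tau)
                else:
                    xi = rng.standard_normal(system.dimension)
                    t_before = kinetic_energy(system, z.v)
                    z_new = substep_O(system, z, tau, gamma, xi)
                    ledger.delta_q += kinetic_energy(system, z_new.v) - t_before
            except (ValueError, FloatingPointError) as exc:
                # PhasePoint rejects non-finite components mid-flight
                raise InstabilityError(
                    f"trajectory diverged at step {step}", step=step) from exc
            if record_substeps:
                de = ((kinetic_energy(system, z_new.v) - kinetic_energy(system, z.v))
                      if letter != "R" else
                      (potential_energy(system, z_new.x) - potential_energy(system, z.x)))
                ledger.substep_records.append((letter, de))
            z = z_new
            if not (np.all(np.isfinite(z.x)) and np.all(np.isfinite(z.v))) \
                    or np.any(np.abs(z.x) > POSITION_BOUND):
                raise InstabilityError(
                    f"trajectory diverged at step {step}", step=step)
        if return_trajectory:
            traj.append(z)

    h1 = potential_energy(system, z.x) + kinetic_energy(system, z.v)
    ledger.delta_h = h1 - h0
    if return_trajectory:
        return z, ledger, traj
    return z, ledger
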