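"""Near-equilibrium work estimators of the KL divergence from equilibrium.

The length-2T protocol: draw (x0, v0) from the canonical density pi, run T
integrator cycles accumulating shadow work (``w_first``; the endpoint is then
an approximate draw from the integrator's steady state rho), and run T more
cycles accumulating ``w_second``.  Near equilibrium,

    D_KL(rho || pi) ~= ( <w>_pi - <w>_rho ) / 2,

the halved difference of the two work averages.  In *configuration* mode the
midpoint velocities are redrawn from pi(v|x) before the second half, which
does no work but turns the midpoint into a draw from
omega(x, v) = rho_x(x) pi(v|x); the same halved difference then estimates
D_KL(rho_x || pi_x), the configuration-marginal divergence.

The protocol length T defaults to the number of steps spanning two collision
times, ceil((2/gamma)/dt), and should be validated with
:func:`check_protocol_length` (estimates at T and 2T must be concordant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .integrators import InstabilityError, IntegratorConfig, run_steps
from .systems import (PhasePoint, SystemSpec, sample_equilibrium_positions,
                      sample_velocities)

__all__ = [
    "ProtocolSpec",
    "ProtocolSample",
    "KLEstimate",
    "ConcordanceReport",
    "default_protocol_length",
    "run_protocol_sample",
    "collect_protocol_samples",
    "estimate_kl_near_eq",
    "estimate_kl",
    "check_protocol_length",
    "auto_protocol_length",
]

MODES = ("phase", "configuration")


@dataclass(frozen=True)
class ProtocolSpec:
    """Length-2T protocol settings: steps per half, mode, outer sample count."""

    n_steps_T: int
    mode: str = "phase"
    n_samples: int = 10_000

    def __post_init__(self) -> None:
        if self.n_steps_T < 1:
            raise ValueError("n_steps_T must be >= 1")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass(frozen=True)
class ProtocolSample:
    """Paired shadow works from the two halves of one protocol realization."""

    w_first: float
    w_second: float


@dataclass(frozen=True)
class KLEstimate:
    """A KL-divergence point estimate with a 95% interval, in nats."""

    value: float
    ci_low: float
    ci_high: float
    estimator: str
    n: int
    meta: dict = field(default_factory=dict)

    @property
    def se(self) -> float:
        return (self.ci_high - self.ci_low) / (2.0 * 1.96)


def default_protocol_length(config: IntegratorConfig) -> int:
    """Steps spanning two collision times: ceil((2/gamma)/dt), at least 1."""
    if config.gamma <= 0:
        return 1
    return max(1, int(np.ceil(2.0 / (config.gamma * config.dt))))


def _child_seeds(rng_seed, n: int) -> list[int]:
    ss = np.random.SeedSequence(rng_seed)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32) % (2**31 - 1)]


def run_protocol_sample(system: SystemSpec, config: IntegratorConfig,
                        spec: ProtocolSpec, rng_seed) -> ProtocolSample:
    """One length-2T protocol realization (generic path, any dimension)."""
    s_x, s_v, s_a, s_mid, s_b = _child_seeds(rng_seed, 5)
    x0 = np.atleast_1d(sample_equilibrium_positions(system, 1, s_x)[0])
    v0 = np.atleast_1d(sample_velocities(system, 1, s_v)[0])
    z0 = PhasePoint(x=x0, v=v0)
    z_mid, ledger1 = run_steps(system, config, z0, spec.n_steps_T, s_a)
    if spec.mode == "configuration":
        v_mid = np.atleast_1d(sample_velocities(system, 1, s_mid)[0])
        z_mid = PhasePoint(x=z_mid.x, v=v_mid)
    _, ledger2 = run_steps(system, config, z_mid, spec.n_steps_T, s_b)
    return ProtocolSample(w_first=ledger1.shadow_work,
                          w_second=ledger2.shadow_work)


def collect_protocol_samples(system: SystemSpec, config: IntegratorConfig,
                             spec: ProtocolSpec, rng_seed):
    """Draw ``spec.n_samples`` protocol realizations; returns (w_first, w_second).

    1D built-in systems run through the jit kernels; other systems fall back
    to the generic per-sample path.  Instability in any realization raises
    :class:`InstabilityError`.
    """
    if system.dimension == 1 and system.pot_id >= 0:
        return _collect_fast(system, config, spec, rng_seed)
    seeds = _child_seeds(rng_seed, spec.n_samples)
    pairs = [run_protocol_sample(system, config, spec, s) for s in seeds]
    return (np.array([p.w_first for p in pairs]),
            np.array([p.w_second for p in pairs]))


def _collect_fast(system, config, spec, rng_seed):
    from ._kernels import batch_work, compile_scheme

    pot_id, beta, m, codes, taus, a_coef, sigma = compile_scheme(system, config)
    s_x, s_v, s_a, s_mid, s_b = _child_seeds(rng_seed, 5)
    x0 = sample_equilibrium_positions(system, spec.n_samples, s_x)
    v0 = sample_velocities(system, spec.n_samples, s_v)
    xm, vm, w1, ok1 = batch_work(pot_id, beta, m, codes, taus, a_coef, sigma,
                                 x0, v0, spec.n_steps_T, s_a)
    if spec.mode == "configuration":
        vm = sample_velocities(system, spec.n_samples, s_mid)
    _, _, w2, ok2 = batch_work(pot_id, beta, m, codes, taus, a_coef, sigma,
                               xm, vm, spec.n_steps_T, s_b)
    bad = int(np.sum(~ok1) + np.sum(ok1 & ~ok2))
    if bad:
        raise InstabilityError(
            f"{bad}/{spec.n_samples} protocol realizations diverged "
            f"(splitting={config.name}, dt={config.dt})")
    return w1, w2


def estimate_kl_near_eq(samples) -> KLEstimate:
    """Halved difference of work averages with a paired-difference 95% CI.

    ``samples`` is either an iterable of :class:`ProtocolSample` or a
    ``(w_first, w_second)`` array pair.  Each realization contributes both
    halves, which are correlated, so the CI comes from the per-realization
    differences d_i = (w_first_i - w_second_i)/2.  Negative point estimates
    are reported as-is (small-divergence noise), never clamped.
    """
    if isinstance(samples, tuple) and len(samples) == 2:
        w1, w2 = (np.asarray(samples[0], float), np.asarray(samples[1], float))
    else:
        samples = list(samples)
        w1 = np.array([s.w_first for s in samples])
        w2 = np.array([s.w_second for s in samples])
    n = w1.size
    if n < 2:
        raise ValueError("need at least 2 protocol samples for a CI")
    d = (w1 - w2) / 2.0
    value = float(d.mean())
    half = 1.96 * float(d.std(ddof=1)) / np.sqrt(n)
    return KLEstimate(value=value, ci_low=value - half, ci_high=value + half,
                      estimator="near_equilibrium", n=n)


def estimate_kl(system: SystemSpec, config: IntegratorConfig, mode: str = "phase",
                n_steps_T: int | None = None, n_samples: int = 10_000,
                rng_seed=0) -> KLEstimate:
    """End-to-end near-equilibrium estimate for one condition."""
    if n_steps_T is None:
        n_steps_T = default_protocol_length(config)
    spec = ProtocolSpec(n_steps_T=n_steps_T, mode=mode, n_samples=n_samples)
    works = collect_protocol_samples(system, config, spec, rng_seed)
    est = estimate_kl_near_eq(works)
    est.meta.update(system=system.name, splitting=config.name, dt=config.dt,
                    gamma=config.gamma, mode=mode, n_steps_T=n_steps_T,
                    seed=rng_seed)
    return est


@dataclass(frozen=True)
class ConcordanceReport:
    """Estimates at protocol lengths T and 2T and their agreement."""

    estimate_T: KLEstimate
    estimate_2T: KLEstimate
    difference: float
    combined_se: float
    concordant: bool


def check_protocol_length(system: SystemSpec, config: IntegratorConfig,
                          spec: ProtocolSpec, rng_seed) -> ConcordanceReport:
    """Compare estimates at T and 2T; flags |difference| > 2 combined SE."""
    s1, s2 = _child_seeds(rng_seed, 2)
    est_T = estimate_kl(system, config, spec.mode, spec.n_steps_T,
                        spec.n_samples, s1)
    est_2T = estimate_kl(system, config, spec.mode, 2 * spec.n_steps_T,
                         spec.n_samples, s2)
    diff = est_2T.value - est_T.value
    combined = float(np.hypot(est_T.se, est_2T.se))
    return ConcordanceReport(estimate_T=est_T, estimate_2T=est_2T,
                             difference=diff, combined_se=combined,
                             concordant=abs(diff) <= 2.0 * combined)


def auto_protocol_length(system: SystemSpec, config: IntegratorConfig,
                         mode: str = "phase", n_samples: int = 100_000,
                         rng_seed=0, max_doublings: int = 6,
                         se_factor: float = 1.0) -> int:
    """Smallest protocol length (by doubling) whose T vs 2T check passes.

    Relaxation toward the integrator's steady state is gradual, so the
    doubling stop uses a stricter criterion (|difference| below ``se_factor``
    combined SEs, default 1) than the 2-SE concordance report, and needs
    enough samples that the per-doubling drift is resolvable — hence the
    large default ``n_samples``.
    """
    T = default_protocol_length(config)
    for _ in range(max_doublings):
        spec = ProtocolSpec(n_steps_T=T, mode=mode, n_samples=n_samples)
        report = check_protocol_length(system, config, spec, rng_seed)
        if abs(report.difference) <= se_factor * report.combined_se:
            return T
        T *= 2
    return T
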