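"""Jit-compiled 1D trajectory kernels.

These kernels exist so that million-step double-well runs and large protocol
ensembles finish in seconds; the generic numpy path in
:mod:`splitkl.integrators` is the reference implementation and the two are
cross-checked in the test suite.

Substep sequences arrive pre-compiled: ``codes`` holds 0/1/2 for R/V/O,
``taus`` the substep durations, and for O substeps ``a_coef``/``sigma`` the
mixing coefficient ``e^(-gamma tau)`` and noise amplitude
``sqrt((1-a^2)/(beta m))``.  All energies are reduced (units of kT).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .integrators import IntegratorConfig
from .systems import SystemSpec

R_CODE, V_CODE, O_CODE = 0, 1, 2
POSITION_BOUND = 1e6


def compile_scheme(system: SystemSpec, config: IntegratorConfig):
    """Flatten a (system, integrator) pair into kernel arguments."""
    if system.dimension != 1 or system.pot_id < 0:
        raise ValueError("jit kernels require a built-in 1D potential")
    letters = config.scheme.letters
    codes = np.array([{"R": R_CODE, "V": V_CODE, "O": O_CODE}[c] for c in letters],
                     dtype=np.int64)
    taus = np.array(config.scheme.fractions, dtype=np.float64) * config.dt
    a_coef = np.ones_like(taus)
    sigma = np.zeros_like(taus)
    beta, m = system.beta, float(system.masses[0])
    for k, c in enumerate(letters):
        if c == "O":
            a = np.exp(-config.gamma * taus[k])
            a_coef[k] = a
            sigma[k] = np.sqrt(max(0.0, 1.0 - a * a) / (beta * m))
    return int(system.pot_id), beta, m, codes, taus, a_coef, sigma


@njit(cache=True)
def _u_red(pot_id, beta, x):
    if pot_id == 0:
        return beta * x**4
    return beta * (x**6 + 2.0 * np.cos(5.0 * (x + 1.0)))


@njit(cache=True)
def _neg_grad(pot_id, x):
    if pot_id == 0:
        return -4.0 * x**3
    return -(6.0 * x**5 - 10.0 * np.sin(5.0 * (x + 1.0)))


@njit(cache=True)
def _t_red(beta, m, v):
    return 0.5 * beta * m * v * v


@njit(cache=True)
def batch_work(pot_id, beta, m, codes, taus, a_coef, sigma,
               x0s, v0s, n_steps, seed):
    """Run each (x0, v0) pair for ``n_steps`` cycles with fresh noise.

    Returns final positions, final velocities, shadow works (w = dh - dq),
    and per-trajectory stability flags.  Unstable rows carry NaN work.
    """
    np.random.seed(seed)
    n = x0s.shape[0]
    xf = np.empty(n)
    vf = np.empty(n)
    works = np.empty(n)
    ok = np.ones(n, dtype=np.bool_)
    for i in range(n):
        x = x0s[i]
        v = v0s[i]
        dq = 0.0
        h0 = _u_red(pot_id, beta, x) + _t_red(beta, m, v)
        stable = True
        for _ in range(n_steps):
            for k in range(codes.shape[0]):
                c = codes[k]
                if c == R_CODE:
                    x = x + v * taus[k]
                elif c == V_CODE:
                    v = v + _neg_grad(pot_id, x) / m * taus[k]
                else:
                    t_before = _t_red(beta, m, v)
                    v = a_coef[k] * v + sigma[k] * np.random.normal()
                    dq += _t_red(beta, m, v) - t_before
            if not (np.isfinite(x) and np.isfinite(v)) or abs(x) > POSITION_BOUND:
                stable = False
                break
        if stable:
            works[i] = (_u_red(pot_id, beta, x) + _t_red(beta, m, v) - h0) - dq
        else:
            works[i] = np.nan
        xf[i] = x
        vf[i] = v
        ok[i] = stable
    return xf, vf, works, ok


@njit(cache=True)
def run_record(pot_id, beta, m, codes, taus, a_coef, sigma,
               x0, v0, n_steps, stride, seed):
    """Single long trajectory recording (x, v) every ``stride`` cycles.

    Returns recorded positions/velocities, the number of completed cycles
    (== n_steps when stable), and a stability flag.
    """
    np.random.seed(seed)
    n_rec = n_steps // stride
    xs = np.empty(n_rec)
    vs = np.empty(n_rec)
    x = x0
    v = v0
    filled = 0
    for s in range(n_steps):
        for k in range(codes.shape[0]):
            c = codes[k]
            if c == R_CODE:
                x = x + v * taus[k]
            elif c == V_CODE:
                v = v + _neg_grad(pot_id, x) / m * taus[k]
            else:
                v = a_coef[k] * v + sigma[k] * np.random.normal()
        if not (np.isfinite(x) and np.isfinite(v)) or abs(x) > POSITION_BOUND:
            return xs[:filled], vs[:filled], s, False
        if (s + 1) % stride == 0:
            xs[filled] = x
            vs[filled] = v
            filled += 1
    return xs[:filled], vs[:filled], n_steps, True


@njit(cache=True)
def ghmc_chain(pot_id, beta, m, codes, taus, a_coef, sigma,
               x0, v0, n_iterations, steps_per_proposal, seed):
    """Metropolized splitting integrator: exact canonical sampling.

    Each proposal runs ``steps_per_proposal`` cycles and is accepted with
    probability min(1, e^-w) on the accumulated shadow work; on rejection
    the state is restored with negated velocity (detailed balance).
    Returns per-iteration positions and the acceptance count.
    """
    np.random.seed(seed)
    xs = np.empty(n_iterations)
    n_accept = 0
    x = x0
    v = v0
    for it in range(n_iterations):
        xp = x
        vp = v
        dq = 0.0
        h0 = _u_red(pot_id, beta, xp) + _t_red(beta, m, vp)
        stable = True
        for _ in range(steps_per_proposal):
            for k in range(codes.shape[0]):
                c = codes[k]
                if c == R_CODE:
                    xp = xp + vp * taus[k]
                elif c == V_CODE:
                    vp = vp + _neg_grad(pot_id, xp) / m * taus[k]
                else:
                    t_before = _t_red(beta, m, vp)
                    vp = a_coef[k] * vp + sigma[k] * np.random.normal()
                    dq += _t_red(beta, m, vp) - t_before
            if not (np.isfinite(xp) and np.isfinite(vp)) or abs(xp) > POSITION_BOUND:
                stable = False
                break
        if stable:
            w = (_u_red(pot_id, beta, xp) + _t_red(beta, m, vp) - h0) - dq
            accept = np.random.random() < np.exp(-w) if w > 0.0 else True
        else:
            accept = False
        if accept:
            x = xp
            v = vp
            n_accept += 1
        else:
            v = -v
        xs[it] = x
    return xs, n_accept
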