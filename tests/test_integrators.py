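import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import splitkl as sk
from splitkl.integrators import parse_splitting, substep_O, substep_R, substep_V
from splitkl.systems import kinetic_energy, potential_energy


class TestParser:
    def test_ovrvo_sequence(self):
        s = parse_splitting("OVRVO")
        assert s.letters == "OVRVO"
        assert s.fractions == (0.5, 0.5, 1.0, 0.5, 0.5)

    def test_vrorv_sequence(self):
        s = parse_splitting("VRORV")
        assert s.letters == "VRORV"
        assert s.fractions == (0.5, 0.5, 1.0, 0.5, 0.5)

    def test_single_letter(self):
        assert parse_splitting("r").letters == "R"
        assert parse_splitting("R").fractions == (1.0,)

    def test_illegal_character(self):
        with pytest.raises(ValueError, match="illegal"):
            parse_splitting("OVXVO")

    def test_non_palindrome_rejected(self):
        with pytest.raises(ValueError, match="palindrom"):
            parse_splitting("OVRV")
        with pytest.raises(ValueError):
            parse_splitting("")

    @given(half=st.text(alphabet="RVO", min_size=0, max_size=5),
           mid=st.sampled_from(["", "R", "V", "O"]))
    @settings(derandomize=True, max_examples=50)
    def test_fractions_sum_to_one_per_letter(self, half, mid):
        word = half + mid + half[::-1]
        if not word:
            return
        scheme = parse_splitting(word)
        for letter in set(scheme.letters):
            total = sum(f for c, f in scheme if c == letter)
            assert total == pytest.approx(1.0)


class TestSubsteps:
    def test_R_drift(self, quartic):
        z = sk.PhasePoint(x=[0.0], v=[1.0])
        assert substep_R(quartic, z, 0.5).x[0] == pytest.approx(0.5)
        assert substep_R(quartic, z, 0.0).x[0] == 0.0

    def test_V_kick_quartic(self, quartic):
        # grad U = 4 x^3 -> dv = -0.4 at x=1, m=1, tau=0.1
        z = sk.PhasePoint(x=[1.0], v=[0.3])
        z2 = substep_V(quartic, z, 0.1)
        assert z2.v[0] == pytest.approx(0.3 - 0.4)
        assert z2.x[0] == 1.0

    def test_V_no_force_at_minimum(self, quartic):
        z = sk.PhasePoint(x=[0.0], v=[0.7])
        assert substep_V(quartic, z, 0.3).v[0] == 0.7

    def test_O_no_coupling_at_zero_gamma(self, quartic):
        z = sk.PhasePoint(x=[0.2], v=[1.0])
        z2 = substep_O(quartic, z, 0.5, 0.0, np.array([2.0]))
        assert z2.v[0] == 1.0

    def test_O_full_randomization_limit(self, quartic):
        z = sk.PhasePoint(x=[0.2], v=[1.0])
        xi = np.array([1.7])
        z2 = substep_O(quartic, z, 1e8, 1.0, xi)
        # a -> 0: v' = xi / sqrt(beta m)
        assert z2.v[0] == pytest.approx(1.7)

    def test_O_half_mixing_heat(self, quartic):
        # a = 1/2, beta m = 1, v=1, xi=0: v'=0.5, heat = t(0.5)-t(1) = -0.375
        gamma, tau = 1.0, np.log(2.0)
        z = sk.PhasePoint(x=[0.0], v=[1.0])
        z2 = substep_O(quartic, z, tau, gamma, np.array([0.0]))
        assert z2.v[0] == pytest.approx(0.5)
        dq = kinetic_energy(quartic, z2.v) - kinetic_energy(quartic, z.v)
        assert dq == pytest.approx(-0.375)


def _manual_work_oracle(system, config, z0, seed):
    """Independent energy bookkeeping for a single symmetric-splitting cycle.

    Replays the substeps with the same noise stream and computes the work as
    [potential + kinetic change over the cycle] minus [kinetic change across
    each O substep], never touching WorkLedger.
    """
    rng = np.random.default_rng(seed)
    z = z0
    u0 = potential_energy(system, z.x)
    t0 = kinetic_energy(system, z.v)
    dq = 0.0
    for letter, fraction in config.scheme:
        tau = fraction * config.dt
        if letter == "R":
            z = substep_R(system, z, tau)
        elif letter == "V":
            z = substep_V(system, z, tau)
        else:
            t_in = kinetic_energy(system, z.v)
            z = substep_O(system, z, tau, config.gamma,
                          rng.standard_normal(system.dimension))
            dq += kinetic_energy(system, z.v) - t_in
    u1 = potential_energy(system, z.x)
    t1 = kinetic_energy(system, z.v)
    return (u1 - u0) + (t1 - t0) - dq


class TestWorkAccounting:
    def test_ledger_matches_energy_oracle_ovrvo(self, quartic):
        """1000 random single OVRVO cycles: ledger work == four-term expansion."""
        config = sk.IntegratorConfig(splitting="OVRVO", dt=0.4, gamma=2.0)
        rng = np.random.default_rng(123)
        for i in range(1000):
            z0 = sk.PhasePoint(x=rng.normal(size=1), v=rng.normal(size=1))
            _, ledger = sk.run_steps(quartic, config, z0, 1, rng_seed=i)
            expected = _manual_work_oracle(quartic, config, z0, seed=i)
            assert ledger.shadow_work == pytest.approx(expected, rel=1e-12,
                                                       abs=1e-14)

    @pytest.mark.parametrize("splitting", ["VRORV", "RVOVR", "ORVRO"])
    def test_ledger_matches_energy_oracle_other_splittings(self, double_well,
                                                           splitting):
        config = sk.IntegratorConfig(splitting=splitting, dt=0.3, gamma=10.0)
        rng = np.random.default_rng(7)
        for i in range(100):
            z0 = sk.PhasePoint(x=rng.normal(scale=0.8, size=1),
                               v=rng.normal(scale=0.3, size=1))
            _, ledger = sk.run_steps(double_well, config, z0, 3, rng_seed=i)
            expected = _multi_step_oracle(double_well, config, z0, 3, i)
            assert ledger.shadow_work == pytest.approx(expected, rel=1e-12,
                                                       abs=1e-14)

    def test_zero_gamma_work_equals_hamiltonian_change(self, double_well):
        config = sk.IntegratorConfig(splitting="VRORV", dt=0.1, gamma=0.0)
        z0 = sk.PhasePoint(x=[0.5], v=[0.1])
        _, ledger = sk.run_steps(double_well, config, z0, 50, rng_seed=0)
        assert ledger.delta_q == 0.0
        assert ledger.shadow_work == ledger.delta_h

    def test_zero_steps_ledger(self, quartic):
        config = sk.IntegratorConfig(splitting="OVRVO", dt=0.1, gamma=1.0)
        z0 = sk.PhasePoint(x=[0.3], v=[0.4])
        z1, ledger = sk.run_steps(quartic, config, z0, 0, rng_seed=0)
        assert ledger.delta_h == 0.0 and ledger.delta_q == 0.0
        np.testing.assert_array_equal(z1.x, z0.x)

    def test_shadow_work_helper(self):
        ledger = sk.WorkLedger(delta_h=1.0, delta_q=0.3)
        assert sk.shadow_work(ledger) == pytest.approx(0.7)
        ledger2 = sk.WorkLedger(delta_h=0.4, delta_q=0.4)
        assert sk.shadow_work(ledger2) == 0.0


def _multi_step_oracle(system, config, z0, n_steps, seed):
    rng = np.random.default_rng(seed)
    z = z0
    u0 = potential_energy(system, z.x)
    t0 = kinetic_energy(system, z.v)
    dq = 0.0
    for _ in range(n_steps):
        for letter, fraction in config.scheme:
            tau = fraction * config.dt
            if letter == "R":
                z = substep_R(system, z, tau)
            elif letter == "V":
                z = substep_V(system, z, tau)
            else:
                t_in = kinetic_energy(system, z.v)
                z = substep_O(system, z, tau, config.gamma,
                              rng.standard_normal(system.dimension))
                dq += kinetic_energy(system, z.v) - t_in
    return (potential_energy(system, z.x) + kinetic_energy(system, z.v)
            - u0 - t0) - dq


class TestTrajectories:
    def test_velocity_verlet_reversibility(self, double_well):
        """VRV at gamma=0 is velocity Verlet: time-reversible to 1e-10."""
        config = sk.IntegratorConfig(splitting="VRV", dt=0.05, gamma=0.0)
        z0 = sk.PhasePoint(x=[0.8], v=[0.2])
        z_fwd, _ = sk.run_steps(double_well, config, z0, 200, rng_seed=0)
        z_back, _ = sk.run_steps(double_well, config,
                                 sk.PhasePoint(x=z_fwd.x, v=-z_fwd.v),
                                 200, rng_seed=0)
        assert abs(z_back.x[0] - z0.x[0]) < 1e-10
        assert abs(-z_back.v[0] - z0.v[0]) < 1e-10

    def test_deterministic_given_seed(self, double_well):
        config = sk.IntegratorConfig(splitting="OVRVO", dt=0.3, gamma=10.0)
        z0 = sk.PhasePoint(x=[0.1], v=[-0.2])
        za, la = sk.run_steps(double_well, config, z0, 100, rng_seed=42)
        zb, lb = sk.run_steps(double_well, config, z0, 100, rng_seed=42)
        assert za.x[0] == zb.x[0] and za.v[0] == zb.v[0]
        assert la.shadow_work == lb.shadow_work

    def test_instability_reported_with_step(self, double_well):
        config = sk.IntegratorConfig(splitting="OVRVO", dt=5.0, gamma=10.0)
        z0 = sk.PhasePoint(x=[1.0], v=[0.0])
        with pytest.raises(sk.InstabilityError) as err:
            sk.run_steps(double_well, config, z0, 1000, rng_seed=0)
        assert err.value.step is not None

    def test_long_run_stays_finite_at_small_dt(self, double_well):
        """Double well at dt=0.1 remains finite over 1e6 steps (jit path)."""
        from splitkl._kernels import compile_scheme, run_record
        config = sk.IntegratorConfig(splitting="OVRVO", dt=0.1, gamma=10.0)
        args = compile_scheme(double_well, config)
        xs, vs, n_done, ok = run_record(*args, 0.0, 0.0, 1_000_000,
                                        1_000_000, 17)
        assert ok and n_done == 1_000_000

    def test_kernel_agrees_with_generic_path(self, double_well):
        """Jit batch kernel vs numpy reference: matching work statistics."""
        from splitkl._kernels import batch_work, compile_scheme
        config = sk.IntegratorConfig(splitting="OVRVO", dt=0.5, gamma=10.0)
        n, T = 4000, 5
        x0 = sk.sample_equilibrium_positions(double_well, n, seed=1)
        v0 = sk.sample_velocities(double_well, n, seed=2)
        _, _, w_fast, ok = batch_work(*compile_scheme(double_well, config),
                                      x0, v0, T, 3)
        assert ok.all()
        w_ref = np.empty(n // 10)
        for i in range(n // 10):
            z0 = sk.PhasePoint(x=[x0[i]], v=[v0[i]])
            _, ledger = sk.run_steps(double_well, config, z0, T, rng_seed=i)
            w_ref[i] = ledger.shadow_work
        se = np.hypot(w_fast.std() / np.sqrt(w_fast.size),
                      w_ref.std() / np.sqrt(w_ref.size))
        assert abs(w_fast.mean() - w_ref.mean()) < 4 * se
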