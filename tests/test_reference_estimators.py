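import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import splitkl as sk
from splitkl.reference_estimators import (_STATISTICS, _inner_sigma,
                                          InnerLoopController,
                                          JaggedWorkSamples,
                                          InfiniteDivergenceError,
                                          collect_inner_work,
                                          sample_steady_state_start)

LN2 = np.log(2.0)


class TestNestedArithmetic:
    def test_zero_works_give_zero(self):
        j = JaggedWorkSamples(rows=[np.zeros(5), np.zeros(3)])
        assert sk.nested_mc_kl(j, n_boot=10).value == 0.0

    def test_log_mean_exponential(self):
        # each row holds works {-ln 2}: ln<e^-w> = ln 2
        j = JaggedWorkSamples(rows=[np.array([-LN2]), np.array([-LN2])])
        assert sk.nested_mc_kl(j, n_boot=10).value == pytest.approx(LN2)

    def test_requires_two_rows(self):
        with pytest.raises(ValueError):
            sk.nested_mc_kl(JaggedWorkSamples(rows=[np.array([0.1])]))

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            JaggedWorkSamples(rows=[np.array([0.1]), np.array([])])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            JaggedWorkSamples(rows=[np.array([np.inf])])


class TestJensenBound:
    def test_pooled_constant(self):
        j = JaggedWorkSamples(rows=[np.array([-LN2]), np.array([-LN2])])
        assert sk.jensen_upper_bound(j, n_boot=10).value == pytest.approx(LN2)

    def test_zeros(self):
        j = JaggedWorkSamples(rows=[np.zeros(4)])
        assert sk.jensen_upper_bound(j).value == 0.0

    @given(st.lists(st.lists(st.floats(-3, 3), min_size=1, max_size=8),
                    min_size=2, max_size=6))
    @settings(derandomize=True, max_examples=100)
    def test_jensen_dominates_nested_algebraically(self, rows):
        """ln of mean >= mean of ln, row-balanced, for any jagged dataset."""
        j = JaggedWorkSamples(rows=[np.array(r) for r in rows])
        assert _STATISTICS["jensen"](j) >= _STATISTICS["nested"](j) - 1e-12


class TestHistogramKL:
    def test_identical_distributions(self):
        edges = np.linspace(0, 1, 5)
        p = sk.Histogram(edges=(edges,), masses=np.full(4, 0.25))
        assert sk.histogram_kl(p, p) == 0.0

    def test_closed_form_two_bins(self):
        edges = np.array([0.0, 0.5, 1.0])
        p = sk.Histogram(edges=(edges,), masses=np.array([0.5, 0.5]))
        q = sk.Histogram(edges=(edges,), masses=np.array([0.25, 0.75]))
        expected = 0.5 * np.log(2.0) + 0.5 * np.log(2.0 / 3.0)
        assert sk.histogram_kl(p, q) == pytest.approx(expected)

    def test_zero_reference_bin_raises(self):
        edges = np.array([0.0, 0.5, 1.0])
        p = sk.Histogram(edges=(edges,), masses=np.array([0.5, 0.5]))
        q = sk.Histogram(edges=(edges,), masses=np.array([1.0, 0.0]))
        with pytest.raises(InfiniteDivergenceError) as err:
            sk.histogram_kl(p, q)
        assert (1,) in err.value.bins

    def test_mismatched_edges_rejected(self):
        p = sk.Histogram(edges=(np.array([0.0, 0.5, 1.0]),),
                         masses=np.array([0.5, 0.5]))
        q = sk.Histogram(edges=(np.array([0.0, 0.4, 1.0]),),
                         masses=np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            sk.histogram_kl(p, q)

    @given(st.lists(st.floats(0.01, 1.0), min_size=3, max_size=8),
           st.lists(st.floats(0.01, 1.0), min_size=3, max_size=8))
    @settings(derandomize=True, max_examples=50)
    def test_non_negative_on_shared_support(self, a, b):
        n = min(len(a), len(b))
        p = np.array(a[:n]) / np.sum(a[:n])
        q = np.array(b[:n]) / np.sum(b[:n])
        p /= p.sum()
        q /= q.sum()
        edges = np.arange(n + 1, dtype=float)
        kl = sk.histogram_kl(
            sk.Histogram(edges=(edges,), masses=p, normalized=False),
            sk.Histogram(edges=(edges,), masses=q, normalized=False))
        assert kl >= -1e-12


class TestBootstrap:
    def test_degenerate_single_value(self):
        j = JaggedWorkSamples(rows=[np.array([0.3])])
        lo, hi = sk.bootstrap_jagged(j, "jensen", n_boot=20, rng_seed=0)
        assert lo == pytest.approx(hi) == pytest.approx(-0.3)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        j = JaggedWorkSamples(rows=[rng.normal(size=6) for _ in range(5)])
        a = sk.bootstrap_jagged(j, "nested", n_boot=50, rng_seed=7)
        b = sk.bootstrap_jagged(j, "nested", n_boot=50, rng_seed=7)
        assert a == b

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(2)
        j = JaggedWorkSamples(rows=[0.2 + 0.1 * rng.normal(size=40)
                                    for _ in range(30)])
        lo, hi = sk.bootstrap_jagged(j, "nested", n_boot=200, rng_seed=8)
        assert lo <= _STATISTICS["nested"](j) <= hi


class TestInnerLoop:
    def test_sigma_of_constant_sample_is_zero(self):
        assert _inner_sigma(np.full(100, 0.3)) == 0.0

    def test_sigma_matches_hand_formula(self):
        w = np.array([0.1, 0.2, 0.3, 0.4])
        y = np.exp(-w)
        expected = y.std(ddof=1) / (y.mean() * 2.0)
        assert _inner_sigma(w) == pytest.approx(expected)

    def test_tiny_timestep_converges_immediately(self, double_well):
        cfg = sk.IntegratorConfig(splitting="OVRVO", dt=0.01, gamma=10.0)
        start = sk.PhasePoint(x=[0.5], v=[0.1])
        w, sig, converged = collect_inner_work(double_well, cfg, start, 5,
                                               InnerLoopController(), 1)
        assert converged
        assert w.size == 100  # first batch suffices
        assert sig < 0.01

    def test_budget_exhaustion_flagged(self, double_well):
        cfg = sk.IntegratorConfig(splitting="OVRVO", dt=0.5, gamma=10.0)
        start = sk.PhasePoint(x=[1.0], v=[0.3])
        ctrl = InnerLoopController(sigma_threshold=1e-7, budget=300, batch=100)
        w, sig, converged = collect_inner_work(double_well, cfg, start, 4,
                                               ctrl, 2)
        assert not converged
        assert w.size == 300
        assert sig > 1e-7

    def test_controller_validation(self):
        with pytest.raises(ValueError):
            InnerLoopController(sigma_threshold=0.0)
        with pytest.raises(ValueError):
            InnerLoopController(budget=10, batch=100)


class TestSteadyStateStarts:
    def test_zero_decorrelation_returns_equilibrium_draw(self, double_well):
        z = sample_steady_state_start(double_well,
                                      sk.IntegratorConfig("OVRVO", 0.3, 10.0),
                                      "phase", decorrelation_steps=0,
                                      rng_seed=3)
        from splitkl.near_equilibrium import _child_seeds
        s_x, s_v = _child_seeds(3, 4)[:2]
        x = sk.sample_equilibrium_positions(double_well, 1, s_x)[0]
        v = sk.sample_velocities(double_well, 1, s_v)[0]
        assert z.x[0] == x and z.v[0] == v

    def test_reproducible(self, double_well):
        cfg = sk.IntegratorConfig("VRORV", 0.4, 10.0)
        a = sample_steady_state_start(double_well, cfg, "configuration",
                                      10, rng_seed=4)
        b = sample_steady_state_start(double_well, cfg, "configuration",
                                      10, rng_seed=4)
        assert a.x[0] == b.x[0] and a.v[0] == b.v[0]


class TestNestedOnDoubleWell:
    def test_divergence_grows_with_timestep(self, double_well):
        """Nested-MC estimates rise from dt=0.3 to dt=0.5 (OVRVO, phase)."""
        ctrl = InnerLoopController(sigma_threshold=0.02)
        vals = {}
        for dt, T in [(0.3, 7), (0.5, 4)]:
            cfg = sk.IntegratorConfig("OVRVO", dt, 10.0)
            res = sk.run_nested_estimate(double_well, cfg, "phase",
                                         n_steps_T=T, n_outer=200,
                                         decorrelation_steps=4 * T,
                                         controller=ctrl, rng_seed=9)
            vals[dt] = res.nested
        assert vals[0.5].value > vals[0.3].value

    def test_jensen_dominates_nested_on_simulation_data(self, double_well):
        cfg = sk.IntegratorConfig("VRORV", 0.5, 10.0)
        ctrl = InnerLoopController(sigma_threshold=0.02)
        res = sk.run_nested_estimate(double_well, cfg, "configuration",
                                     n_steps_T=4, n_outer=80,
                                     controller=ctrl, rng_seed=10)
        assert res.jensen.value >= res.nested.value
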