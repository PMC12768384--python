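"""Integration, ablation, stimulation, propagation and perturbation."""
import numpy as np
import pytest

import premotornet as pn
from premotornet import dynamics
from premotornet.simulate import (SimulationConfig, ablate,
                                  baseline_fixed_point, integrate,
                                  interpolate_signals, perturb_signals,
                                  propagation_map, stimulate)
from premotornet.traces import ActivityTraces

from _oracles import rk4_integrate


def _small_system(seed=0, n_core=3, n_signal=2, trace_length=120):
    spec = pn.SyntheticSpec(n_core=n_core, n_signal=n_signal,
                            trace_length=trace_length, noise_sd=0.0,
                            seed=seed)
    reg = pn.synthetic_registry(spec)
    w = pn.generate_connectome(spec, reg)
    p = pn.generate_ground_truth_params(spec, w, reg)
    sig = pn.generate_signal_traces(spec, reg)
    return reg, w, p, sig


class TestInterpolation:
    def test_exact_at_samples_and_linear_midpoints(self):
        t = 0.5 * np.arange(6)
        vals = np.array([[0.0, 1.0, 4.0, 9.0, 16.0, 25.0]])
        f = interpolate_signals(ActivityTraces(("a",), t, vals))
        assert f(1.0)[0] == 4.0
        assert f(0.25)[0] == pytest.approx(0.5)  # midpoint mean

    def test_out_of_coverage_rejected(self):
        t = np.arange(4.0)
        f = interpolate_signals(ActivityTraces(("a",), t, np.zeros((1, 4))))
        with pytest.raises(ValueError):
            f(5.0)

    def test_refinement_halves_error_order(self):
        def smooth(t):
            return np.sin(2 * np.pi * t)

        errs = []
        for dt in (0.02, 0.01):
            t = np.arange(0, 1 + dt / 2, dt)
            f = interpolate_signals(
                ActivityTraces(("a",), t, smooth(t)[None, :]))
            q = np.linspace(0.0, 1.0, 1001)
            errs.append(np.max(np.abs(np.array([f(x)[0] for x in q])
                                      - smooth(q))))
        # piecewise-linear error is O(dt^2): ratio about 4
        assert errs[0] / errs[1] > 3.0


class TestIntegrate:
    def test_constant_at_stable_root_without_coupling(self):
        reg = pn.NeuronRegistry(forward=("FD01L", "FD01R"), reversal=(),
                                avd=(), signal=("SIG001",))
        w = pn.NetworkWeights(np.zeros((3, 3)), np.zeros((2, 3), bool))
        p = pn.ModelParameters(syn=np.zeros((2, 3)), bias=np.zeros(2),
                               beta=1.0, tau=0.2, magnification=1.0)
        t = 0.01 * np.arange(101)
        sig = ActivityTraces(("SIG001",), t, np.sin(t)[None, :])
        out = integrate(p, w, sig, SimulationConfig(x0=np.array([1.0, -0.8])),
                        reg)
        assert np.allclose(out.values[0], 1.0, atol=1e-7)
        assert np.allclose(out.values[1], -0.8, atol=1e-7)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_fixed_step_oracle(self, seed):
        reg, w, p, sig = _small_system(seed=seed)
        cfg = SimulationConfig(tspan=(0.0, 1.0), output_dt=0.05)
        out = integrate(p, w, sig, cfg, reg)
        f = interpolate_signals(sig)

        def fun(t, x):
            return dynamics.rhs(t, x, f(t), p, w)

        ts, xs = rk4_integrate(fun, (0.0, 1.0), np.full(reg.n_core, -0.8),
                               1e-4)
        idx = [int(round(t / 1e-4)) for t in out.times]
        assert np.max(np.abs(out.values - xs[:, idx])) < 1e-5

    def test_tolerance_convergence(self):
        reg, w, p, sig = _small_system(seed=3)
        cfg1 = SimulationConfig(tspan=(0.0, 1.0), output_dt=0.1,
                                rel_tol=1e-9, abs_tol=1e-11)
        cfg2 = SimulationConfig(tspan=(0.0, 1.0), output_dt=0.1,
                                rel_tol=1e-10, abs_tol=1e-12)
        a = integrate(p, w, sig, cfg1, reg)
        b = integrate(p, w, sig, cfg2, reg)
        assert np.max(np.abs(a.values - b.values)) < 1e-6

    def test_determinism(self):
        reg, w, p, sig = _small_system(seed=4)
        cfg = SimulationConfig(tspan=(0.0, 1.0), output_dt=0.05)
        a = integrate(p, w, sig, cfg, reg)
        b = integrate(p, w, sig, cfg, reg)
        assert np.array_equal(a.values, b.values)

    def test_missing_signals_zero_filled_with_warning(self):
        reg, w, p, sig = _small_system(seed=5)
        partial = sig.subset(sig.labels[:1])
        with pytest.warns(UserWarning, match="zero-filled"):
            integrate(p, w, partial, SimulationConfig(tspan=(0.0, 0.5)), reg)

    def test_bounded_under_bounded_signals(self):
        reg, w, p, sig = _small_system(seed=6, trace_length=1500)
        out = integrate(p, w, sig, SimulationConfig(), reg)
        assert np.max(np.abs(out.values)) < 10.0


class TestGapPairSynchronization:
    def test_identical_coupled_neurons_converge(self):
        reg = pn.NeuronRegistry(forward=("FD01L", "FD01R"), reversal=(),
                                avd=(), signal=())
        gap = np.array([[0.0, 2.0], [2.0, 0.0]])
        w = pn.NetworkWeights(gap, np.zeros((2, 2), bool))
        p = pn.ModelParameters(syn=np.zeros((2, 2)), bias=np.zeros(2),
                               beta=2.0, tau=0.2, magnification=1.0)
        t = 0.01 * np.arange(1001)
        empty = ActivityTraces((), t, np.zeros((0, t.size)))
        for x0 in ([1.2, -1.0], [-0.3, 0.4], [2.0, -2.0]):
            out = integrate(p, w, empty, SimulationConfig(
                x0=np.array(x0)), reg)
            assert abs(out.values[0, -1] - out.values[1, -1]) < 1e-6


class TestAblate:
    def _default_net(self):
        spec = pn.SyntheticSpec(n_core=15, n_signal=8, seed=10)
        reg = pn.synthetic_registry(spec)
        w = pn.generate_connectome(spec, reg)
        p = pn.generate_ground_truth_params(spec, w, reg)
        return reg, w, p

    def test_ablating_class_zeroes_exactly_its_rows_and_columns(self):
        reg, w, p = self._default_net()
        p2, w2 = ablate(p, w, reg, ["RIB"])
        idx = [reg.index(n) for n in ("RIBL", "RIBR")]
        for k in idx:
            assert not w2.gap[k].any() and not w2.gap[:, k].any()
            assert not p2.syn[k].any() and not p2.syn[:, k].any()
        others = [i for i in range(reg.n_core) if i not in idx]
        sub = np.ix_(others, [j for j in range(reg.n_total) if j not in idx])
        assert np.array_equal(p2.syn[sub], p.syn[sub])

    def test_ablation_idempotent_and_full_disconnect(self):
        reg, w, p = self._default_net()
        p2, w2 = ablate(p, w, reg, ["RIB"])
        p3, w3 = ablate(p2, w2, reg, ["RIB"])
        assert np.array_equal(p2.syn, p3.syn)
        assert np.array_equal(w2.gap, w3.gap)
        all_classes = reg.core_classes()
        p4, w4 = ablate(p, w, reg, list(all_classes))
        assert not p4.syn[:, :reg.n_core].any()
        assert not w4.gap[:reg.n_core, :reg.n_core].any()

    def test_unknown_class_rejected(self):
        reg, w, p = self._default_net()
        with pytest.raises(KeyError):
            ablate(p, w, reg, ["PVC"])


class TestStimulateAndPropagation:
    def _bistable_single(self):
        reg = pn.NeuronRegistry(forward=("FD01L", "FD01R"), reversal=(),
                                avd=(), signal=())
        w = pn.NetworkWeights(np.zeros((2, 2)), np.zeros((2, 2), bool))
        p = pn.ModelParameters(syn=np.zeros((2, 2)), bias=np.zeros(2),
                               beta=1.0, tau=0.2, magnification=1.0)
        return reg, w, p

    def test_zero_amplitude_is_baseline_relaxation(self):
        reg, w, p = self._bistable_single()
        out = stimulate(p, w, reg, "FD01L", 0.0, (0.0, 2.0),
                        SimulationConfig(x0=np.array([-0.8, -0.8])))
        assert np.allclose(out.values, -0.8, atol=1e-7)

    def test_response_continuous_in_amplitude(self):
        reg, w, p = self._bistable_single()
        cfg = SimulationConfig(x0=np.array([-0.8, -0.8]), output_dt=0.5)
        small = stimulate(p, w, reg, "FD01L", 1e-3, (0.0, 1.0), cfg)
        assert np.max(np.abs(small.values + 0.8)) < 0.05

    def test_injection_outside_window_has_no_effect(self):
        reg, w, p = self._bistable_single()
        cfg = SimulationConfig(tspan=(0.0, 3.0), output_dt=0.5,
                               x0=np.array([-0.8, -0.8]))
        out = stimulate(p, w, reg, "FD01R", 2.0, (10.0, 11.0), cfg)
        assert np.allclose(out.values, -0.8, atol=1e-7)

    def test_baseline_fixed_point_residual(self):
        spec = pn.SyntheticSpec(n_core=5, n_signal=4, seed=12)
        reg = pn.synthetic_registry(spec)
        w = pn.generate_connectome(spec, reg)
        p = pn.generate_ground_truth_params(spec, w, reg)
        x = baseline_fixed_point(p, w, SimulationConfig())
        zeros = np.zeros(reg.n_signal)
        assert np.linalg.norm(dynamics.rhs(0.0, x, zeros, p, w)) < 1e-8

    def test_disconnected_neurons_settle_in_upper_basin(self):
        reg, w, p = self._bistable_single()
        x = baseline_fixed_point(p, w, SimulationConfig(
            x0=np.array([0.5, 0.5])))
        assert np.allclose(x, 1.0, atol=1e-6)

    def test_propagation_map_zero_amplitude_and_disconnected_diagonal(self):
        reg, w, p = self._bistable_single()
        m0 = propagation_map(p, w, reg, amplitude=0.0,
                             cfg=SimulationConfig(x0=np.array([-0.8, -0.8])))
        assert np.allclose(m0, 0.0, atol=1e-6)
        m = propagation_map(p, w, reg, amplitude=2.0,
                            cfg=SimulationConfig(x0=np.array([-0.8, -0.8])))
        off_diag = m[~np.eye(2, dtype=bool)]
        assert np.allclose(off_diag, 0.0, atol=1e-6)
        # a strong push moves the stimulated bistable neuron to a new
        # steady state above its unstimulated plateau
        assert m[0, 0] > 1.7

    def test_stimulating_unknown_target_rejected(self):
        reg, w, p = self._bistable_single()
        with pytest.raises(KeyError):
            stimulate(p, w, reg, "AVAL", 1.0, (0.0, 1.0))


class TestPerturbSignals:
    def _sig(self):
        t = 0.1 * np.arange(20)
        vals = np.vstack([np.linspace(0, 1, 20), np.ones(20)])
        return ActivityTraces(("A", "B"), t, vals)

    def test_empty_spec_is_identity(self):
        sig = self._sig()
        out = perturb_signals(sig, [])
        assert np.array_equal(out.values, sig.values)

    def test_zeroing(self):
        out = perturb_signals(self._sig(), [("B", "zero")])
        assert not out.row("B").any()

    def test_additive_bump_window(self):
        sig = self._sig()
        out = perturb_signals(sig, [("A", 1.0, (0.5, 1.0))])
        mask = (sig.times >= 0.5) & (sig.times <= 1.0)
        assert np.allclose(out.row("A")[mask], sig.row("A")[mask] + 1.0)
        assert np.allclose(out.row("A")[~mask], sig.row("A")[~mask])

    def test_unknown_neuron_rejected(self):
        with pytest.raises(KeyError):
            perturb_signals(self._sig(), [("Z", "zero")])
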