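"""Numerical integration of the driven core network, with ablation,
stimulation and signal-perturbation hooks.

The core ODE system is integrated with an adaptive embedded Runge-Kutta 4(5)
scheme (scipy's ``RK45``); signal-neuron traces are interpolated piecewise
linearly to supply drive at arbitrary integrator times.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d

from . import dynamics
from .network import ModelParameters, NetworkWeights
from .registry import NeuronRegistry
from .traces import ActivityTraces

__all__ = [
    "SimulationConfig", "interpolate_signals", "integrate", "ablate",
    "stimulate", "baseline_fixed_point", "propagation_map", "perturb_signals",
]

#: Common resting mode of the intrinsic dynamics; default initial condition.
REST_STATE = -0.8


@dataclass
class SimulationConfig:
    """Integration settings.

    tspan : (start, end) in minutes, or None for the full signal coverage.
    x0 : initial core state; None puts every neuron at the resting mode -0.8.
    rel_tol, abs_tol : integrator tolerances.
    output_dt : output sampling interval in minutes; None reuses the signal dt.
    seed : seed for any stochastic drive (the deterministic model ignores it).
    """

    tspan: tuple[float, float] | None = None
    x0: np.ndarray | None = None
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    output_dt: float | None = None
    seed: int | None = None
    max_settle_minutes: float = 200.0
    settle_tol: float = 1e-8
    #: integrator step cap; None means the signal sampling interval (the
    #: drive is only piecewise smooth, so steps must resolve its kinks)
    max_step: float | None = None

    def __post_init__(self) -> None:
        if not (self.rel_tol > 0 and self.abs_tol > 0):
            raise ValueError("integrator tolerances must be positive")


def interpolate_signals(traces: ActivityTraces) -> Callable[[float], np.ndarray]:
    """Piecewise-linear interpolant over all rows of ``traces``.

    The returned callable maps a time (minutes) to the vector of values in
    trace row order; it is exact at sample points and raises outside the
    sampled coverage.
    """
    f = interp1d(traces.times, traces.values, axis=1, kind="linear",
                 bounds_error=True, assume_sorted=True)

    def signal_fn(t: float) -> np.ndarray:
        return np.atleast_1d(f(t))

    return signal_fn


def _signal_matrix(signals: ActivityTraces, registry: NeuronRegistry) -> ActivityTraces:
    """Signal traces reordered to the registry's signal order; missing neurons
    are zero-filled with a warning (their synaptic drive is absent from the
    dataset and partially compensated by the magnification factor)."""
    rows = []
    missing = []
    for name in registry.signal:
        if name in signals:
            rows.append(signals.row(name))
        else:
            missing.append(name)
            rows.append(np.zeros(signals.n_samples))
    if missing:
        warnings.warn(
            f"signal neurons missing from dataset, zero-filled: {missing}",
            stacklevel=2)
    values = (np.stack(rows) if rows
              else np.zeros((0, signals.n_samples)))
    return ActivityTraces(registry.signal, signals.times, values)


def _integrate_segments(fun, tspan, x0, t_eval, cfg, breakpoints=(),
                        max_step=np.inf):
    """Integrate over tspan, restarting at breakpoints (drive discontinuities)."""
    edges = [tspan[0]] + sorted(t for t in breakpoints
                                if tspan[0] < t < tspan[1]) + [tspan[1]]
    x = np.asarray(x0, dtype=float)
    t_blocks, x_blocks = [], []
    for k, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        lo = (t_eval >= a - 1e-12) if k == 0 else (t_eval > a + 1e-12)
        seg_eval = t_eval[lo & (t_eval <= b + 1e-12)]
        sol = solve_ivp(fun, (a, b), x, method="RK45",
                        rtol=cfg.rel_tol, atol=cfg.abs_tol,
                        max_step=max_step,
                        t_eval=seg_eval if seg_eval.size else None,
                        dense_output=True)
        if not sol.success:
            raise RuntimeError(
                f"integration failed near t={sol.t[-1] if sol.t.size else a:.4f}"
                f" min: {sol.message}")
        if seg_eval.size:
            t_blocks.append(seg_eval)
            x_blocks.append(sol.y)
        x = sol.sol(b)
    return np.concatenate(t_blocks), np.concatenate(x_blocks, axis=1)


def integrate(params: ModelParameters, weights: NetworkWeights,
              signals: ActivityTraces, cfg: SimulationConfig | None = None,
              registry: NeuronRegistry | None = None) -> ActivityTraces:
    """Integrate the driven core system over the signal coverage.

    ``signals`` supplies the recorded (or synthetic) signal-neuron traces;
    every registry signal neuron absent from it is zero-filled with a warning.
    Returns core traces sampled at ``cfg.output_dt``.
    """
    cfg = cfg or SimulationConfig()
    if registry is None:
        registry = NeuronRegistry(signal=tuple(signals.labels))  # type: ignore[arg-type]
    sig = _signal_matrix(signals, registry)
    signal_fn = interpolate_signals(sig)
    tspan = cfg.tspan or (float(sig.times[0]), float(sig.times[-1]))
    if tspan[0] < sig.times[0] - 1e-12 or tspan[1] > sig.times[-1] + 1e-12:
        raise ValueError("tspan extends beyond signal coverage")
    out_dt = cfg.output_dt or sig.dt
    n_out = int(round((tspan[1] - tspan[0]) / out_dt)) + 1
    t_eval = tspan[0] + out_dt * np.arange(n_out)
    t_eval = t_eval[t_eval <= tspan[1] + 1e-12]
    x0 = (np.full(params.n_core, REST_STATE) if cfg.x0 is None
          else np.asarray(cfg.x0, dtype=float))

    def fun(t, x):
        return dynamics.rhs(t, x, signal_fn(min(t, tspan[1])), params, weights)

    t_out, x_out = _integrate_segments(fun, tspan, x0, t_eval, cfg,
                                       max_step=cfg.max_step or sig.dt)
    return ActivityTraces(registry.core, t_out, x_out)


def ablate(params: ModelParameters, weights: NetworkWeights,
           registry: NeuronRegistry, classes: Sequence[str]
           ) -> tuple[ModelParameters, NetworkWeights]:
    """Sever all synaptic and gap-junction links between the named core
    classes and the rest of the network; intrinsic dynamics are retained.
    """
    core_classes = registry.core_classes()
    members: list[str] = []
    for label in classes:
        if label not in core_classes:
            raise KeyError(f"{label!r} is not a core neuron class")
        members.extend(n for n in registry.core if registry.class_of(n) == label)
    p, w = params.copy(), weights.copy()
    for name in members:
        k = registry.index(name)  # global index; core block comes first
        p.syn[k, :] = 0.0
        p.syn[:, k] = 0.0
        w.syn_mask[k, :] = False
        w.syn_mask[:, k] = False
        w.gap[k, :] = 0.0
        w.gap[:, k] = 0.0
    return p, w


def _undriven_fun(params: ModelParameters, weights: NetworkWeights):
    n_signal = params.n_total - params.n_core
    zeros = np.zeros(n_signal)

    def fun(t, x):
        return dynamics.rhs(t, x, zeros, params, weights)

    return fun


def stimulate(params: ModelParameters, weights: NetworkWeights,
              registry: NeuronRegistry, target: str, amplitude: float,
              window: tuple[float, float],
              cfg: SimulationConfig | None = None) -> ActivityTraces:
    """Integrate with all signal input zeroed and a constant current injected
    into ``target`` during ``window``.

    The injected current enters the dynamics like the bias term (inside the
    bracket divided by tau).
    """
    cfg = cfg or SimulationConfig()
    if target not in registry.core:
        raise KeyError(f"{target!r} is not a core neuron")
    idx = registry.core.index(target)
    tspan = cfg.tspan or (0.0, float(window[1]))
    out_dt = cfg.output_dt or 0.01
    n_out = int(round((tspan[1] - tspan[0]) / out_dt)) + 1
    t_eval = tspan[0] + out_dt * np.arange(n_out)
    t_eval = t_eval[t_eval <= tspan[1] + 1e-12]
    x0 = (np.full(params.n_core, REST_STATE) if cfg.x0 is None
          else np.asarray(cfg.x0, dtype=float))
    base = _undriven_fun(params, weights)
    bump = np.zeros(params.n_core)
    bump[idx] = amplitude / params.tau

    def fun(t, x):
        dx = base(t, x)
        if window[0] <= t <= window[1]:
            return dx + bump
        return dx

    t_out, x_out = _integrate_segments(fun, tspan, x0, t_eval, cfg,
                                       breakpoints=window,
                                       max_step=cfg.max_step or np.inf)
    return ActivityTraces(registry.core, t_out, x_out)


def baseline_fixed_point(params: ModelParameters, weights: NetworkWeights,
                         cfg: SimulationConfig | None = None) -> np.ndarray:
    """Steady state of the undriven core dynamics (no signal input).

    Integrates from ``cfg.x0`` until the vector-field norm drops below
    ``cfg.settle_tol``; raises if the state has not settled within
    ``cfg.max_settle_minutes`` (e.g. a limit cycle).
    """
    cfg = cfg or SimulationConfig()
    fun = _undriven_fun(params, weights)
    x = (np.full(params.n_core, REST_STATE) if cfg.x0 is None
         else np.asarray(cfg.x0, dtype=float))
    t, chunk = 0.0, 5.0
    while t < cfg.max_settle_minutes:
        sol = solve_ivp(fun, (t, t + chunk), x, method="RK45",
                        rtol=cfg.rel_tol, atol=cfg.abs_tol)
        if not sol.success:
            raise RuntimeError(f"integration failed while settling: {sol.message}")
        x = sol.y[:, -1]
        t += chunk
        if np.linalg.norm(fun(t, x)) < 1e-4:
            # near a fixed point (up to integrator tolerance): Newton polish
            from scipy.optimize import root
            res = root(lambda y: fun(0.0, y), x, tol=1e-13)
            polished = res.x
            # accept on the residual itself: `root` may flag "no progress"
            # when the start is already at the solution
            if (np.linalg.norm(polished - x) < 1e-3
                    and np.linalg.norm(fun(0.0, polished)) < cfg.settle_tol):
                return polished
    raise RuntimeError(
        "undriven dynamics did not settle to a fixed point within "
        f"{cfg.max_settle_minutes} minutes (possible limit cycle)")


def propagation_map(params: ModelParameters, weights: NetworkWeights,
                    registry: NeuronRegistry, amplitude: float = 2.0,
                    cfg: SimulationConfig | None = None,
                    window_minutes: float = 5.0) -> np.ndarray:
    """Signal propagation map: steady-state displacement of every core neuron
    under stimulation of each core neuron in turn.

    Entry ``[target, stimulated]`` is the target's steady activity at the end
    of the stimulation window minus its unstimulated baseline.  Stimulation is
    applied one neuron at a time with no other signal input, starting from the
    baseline fixed point.
    """
    cfg = cfg or SimulationConfig()
    baseline = baseline_fixed_point(params, weights, cfg)
    n = params.n_core
    out = np.zeros((n, n))
    from dataclasses import replace
    stim_cfg = replace(cfg, x0=baseline, tspan=(0.0, window_minutes),
                       output_dt=window_minutes)
    for j, name in enumerate(registry.core):
        tr = stimulate(params, weights, registry, name, amplitude,
                       (0.0, window_minutes), stim_cfg)
        out[:, j] = tr.values[:, -1] - baseline
    return out


def perturb_signals(signals: ActivityTraces, spec: Sequence[tuple]) -> ActivityTraces:
    """Apply perturbations to named signal traces; returns a modified copy.

    Each spec entry is either ``(neuron, "zero")`` — replace the whole trace
    with zeros — or ``(neuron, shape, (t_start, t_end))`` where ``shape`` is a
    scalar or a callable of time, added to the trace within the window.
    """
    out = signals.copy()
    for entry in spec:
        name = entry[0]
        if name not in out:
            raise KeyError(f"no trace for neuron {name!r}")
        i = out.labels.index(name)
        if len(entry) == 2 and entry[1] == "zero":
            out.values[i, :] = 0.0
            continue
        _, shape, window = entry
        mask = (out.times >= window[0]) & (out.times <= window[1])
        if callable(shape):
            out.values[i, mask] += np.asarray([shape(t) for t in out.times[mask]])
        else:
            out.values[i, mask] += float(shape)
    return out
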