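"""Vector field of the driven core network and its equilibrium analysis.

Each core neuron's GCaMP z-score ``x_i`` evolves as

    tau * dx_i/dt = f(x_i) + bias_i
                    + beta * sum_j W_ij (x_j - x_i)
                    + magnification * sum_j A_ij relu(x_j)

where the sums run over core and signal neurons, ``W`` holds symmetric
gap-junction weights (diffusive coupling) and ``A`` signed synaptic weights
applied to the rectified presynaptic activity (neurons influence their
postsynaptic partners only when depolarized).  The intrinsic cubic

    f(x) = -2 (x + 0.8)(x - 0.1)(x - 1)

has stable states at -0.8 (rest) and 1 (plateau) separated by an unstable
state at 0.1, giving every neuron Schmitt-trigger-like bistability with
saturation at large |x|.
"""
from __future__ import annotations

import numpy as np

from .network import ModelParameters, NetworkWeights, VoltageCubicCalibration

__all__ = [
    "CUBIC_ROOTS", "intrinsic_dynamics", "gap_current", "synaptic_current",
    "rhs", "equilibria", "voltage_form_equilibria",
]

#: Fixed points of the zero-bias intrinsic cubic (rest, threshold, plateau).
CUBIC_ROOTS = (-0.8, 0.1, 1.0)

_MERGE_TOL = 1e-8  # roots closer than this collapse to a double (semi-stable) root


def _check_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def intrinsic_dynamics(x, d=0.0):
    """Intrinsic rate ``-2 (x + 0.8)(x - 0.1)(x - 1) + d``.  Vectorized."""
    x = _check_finite("x", x)
    d = _check_finite("d", d)
    return -2.0 * (x + 0.8) * (x - 0.1) * (x - 1.0) + d


def gap_current(x_self, x_all, w_row, beta: float):
    """Diffusive gap-junction input ``beta * sum_j w_j (x_j - x_self)``."""
    x_all = _check_finite("x_all", x_all)
    w_row = _check_finite("w_row", w_row)
    if w_row.shape != x_all.shape:
        raise ValueError("w_row and x_all must have matching shapes")
    if np.any(w_row < 0):
        raise ValueError("gap-junction weights must be nonnegative")
    return float(beta) * float(np.dot(w_row, x_all - x_self))


def synaptic_current(x_all, a_row, magnification: float = 1.0):
    """Rectified synaptic input ``magnification * sum_j a_j relu(x_j)``."""
    x_all = _check_finite("x_all", x_all)
    a_row = np.asarray(a_row, dtype=float)
    if a_row.shape != x_all.shape:
        raise ValueError("a_row and x_all must have matching shapes")
    return float(magnification) * float(np.dot(a_row, np.maximum(x_all, 0.0)))


def rhs(t: float, x_core: np.ndarray, signal_values: np.ndarray,
        params: ModelParameters, weights: NetworkWeights) -> np.ndarray:
    """Time derivative of the core state under the driven dynamics.

    Parameters
    ----------
    t : float
        Time (unused by the autonomous part; kept for integrator interfaces).
    x_core : ndarray, shape (n_core,)
        Current core activities.
    signal_values : ndarray, shape (n_signal,)
        Signal-neuron activities at time ``t``; must cover every signal
        neuron (n_total - n_core entries).
    """
    x_core = _check_finite("x_core", x_core)
    signal_values = np.atleast_1d(_check_finite("signal_values", signal_values))
    n_core, n_total = params.syn.shape
    if x_core.shape != (n_core,):
        raise ValueError(f"x_core must have shape ({n_core},)")
    if signal_values.shape != (n_total - n_core,):
        raise ValueError(
            f"expected {n_total - n_core} signal values, got {signal_values.size}")
    x_all = np.concatenate([x_core, signal_values])
    w = weights.gap[:n_core]
    gap = params.beta * (w @ x_all - w.sum(axis=1) * x_core)
    syn = params.magnification * (params.syn @ np.maximum(x_all, 0.0))
    return (intrinsic_dynamics(x_core, params.bias) + gap + syn) / params.tau


def _classify_cubic_roots(poly: np.polynomial.Polynomial):
    """Real roots of a cubic with stability from the local derivative sign."""
    roots = poly.roots()
    real = sorted(float(r.real) for r in roots if abs(r.imag) < 1e-7)
    # merge near-coincident roots into double roots
    merged: list[list[float]] = []
    for r in real:
        if merged and abs(r - merged[-1][-1]) < _MERGE_TOL:
            merged[-1].append(r)
        else:
            merged.append([r])
    deriv = poly.deriv()
    out = []
    for group in merged:
        r = float(np.mean(group))
        if len(group) > 1:
            out.append((r, "semi-stable"))
        else:
            slope = deriv(r)
            if abs(slope) < _MERGE_TOL:
                out.append((r, "semi-stable"))
            else:
                out.append((r, "stable" if slope < 0 else "unstable"))
    return out


def equilibria(d: float = 0.0):
    """Equilibria of the isolated-neuron dynamics ``f(x) + d = 0``.

    Returns a list of ``(root, stability)`` pairs sorted by root, with
    stability in {"stable", "unstable", "semi-stable"} from the sign of the
    vector-field derivative at the root (semi-stable at double roots).

    With ``d = 0`` the neuron is bistable: stable states at -0.8 and 1 and an
    unstable threshold at 0.1.  A large enough |d| removes one stable state.
    """
    d = float(_check_finite("d", d))
    base = -2.0 * np.polynomial.Polynomial.fromroots(CUBIC_ROOTS)
    return _classify_cubic_roots(base + d)


def voltage_form_equilibria(calibration: VoltageCubicCalibration | None = None):
    """Equilibria (mV, stability) of the RMD voltage-form intrinsic cubic.

    The cubic ``dV/dt = -(1/8000)(V + 70)(V + 60)(V + 50)`` approximates the
    RMD steady-state I-V relation: stable resting potential near -70 mV, a
    stable plateau near -50 mV, and an unstable threshold at -60 mV.
    """
    cal = calibration or VoltageCubicCalibration()
    poly = -cal.coefficient * np.polynomial.Polynomial.fromroots(cal.roots)
    return _classify_cubic_roots(poly)
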