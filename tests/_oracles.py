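"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own code paths: a fixed-step RK4
integrator (vs the adaptive solver), a sample-by-sample interval enumerator
(vs the run-length bookkeeping), and list-based smoothing rules (vs the
array implementation).
"""
from __future__ import annotations

import numpy as np


def rk4_integrate(fun, tspan, x0, dt):
    """Classical fixed-step 4th-order Runge-Kutta."""
    t0, t1 = tspan
    n = int(round((t1 - t0) / dt))
    x = np.asarray(x0, dtype=float).copy()
    ts = [t0]
    xs = [x.copy()]
    for k in range(n):
        t = t0 + k * dt
        k1 = fun(t, x)
        k2 = fun(t + dt / 2, x + dt / 2 * k1)
        k3 = fun(t + dt / 2, x + dt / 2 * k2)
        k4 = fun(t + dt, x + dt * k3)
        x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        ts.append(t0 + (k + 1) * dt)
        xs.append(x.copy())
    return np.array(ts), np.array(xs).T


def enumerate_intervals(states, dt, t0=0.0):
    """Sample-by-sample interval enumeration: (state, t_start, t_end)."""
    out = []
    start = 0
    for k in range(1, len(states) + 1):
        if k == len(states) or states[k] != states[start]:
            out.append((states[start], t0 + start * dt, t0 + k * dt))
            start = k
    return out


def smooth_by_rules(states, dt, short_locomotion, short_pause):
    """List-based reference of the two interval-smoothing rules.

    Rule 1: interior F/R intervals shorter than ``short_locomotion`` with
    pause on both sides become pause.  Rule 2 (applied after): interior pause
    intervals shorter than ``short_pause`` flanked by the same locomotion
    state take that state.  Boundary intervals never change.
    """
    states = list(states)

    def runs(s):
        out = []
        start = 0
        for k in range(1, len(s) + 1):
            if k == len(s) or s[k] != s[start]:
                out.append((s[start], start, k - start))
                start = k
        return out

    r = runs(states)
    for k, (lab, start, count) in enumerate(r):
        if 0 < k < len(r) - 1 and lab in "FR" and count * dt < short_locomotion:
            if r[k - 1][0] == "P" and r[k + 1][0] == "P":
                for i in range(start, start + count):
                    states[i] = "P"
    r = runs(states)
    for k, (lab, start, count) in enumerate(r):
        if 0 < k < len(r) - 1 and lab == "P" and count * dt < short_pause:
            left, right = r[k - 1][0], r[k + 1][0]
            if left == right and left in "FR":
                for i in range(start, start + count):
                    states[i] = left
    return states
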