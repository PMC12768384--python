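"""Behavioral state classification from core neuron activity.

The dominant core cluster is a proxy for locomotion: with F(t) the mean
forward-cluster activity and R(t) the mean reversal-cluster activity, the
difference z(t) = F(t) - R(t) classifies each sample as forward (z > 0.5),
reversal (z < -0.5) or pause/ambiguous otherwise.  Interval smoothing removes
implausibly short bouts, and dwell-time/occupancy statistics summarize the
resulting behavior strip.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .registry import NeuronRegistry
from .traces import ActivityTraces

__all__ = [
    "BehaviorSignals", "BehaviorSequence", "cluster_averages", "classify",
    "smooth_states", "dwell_statistics", "state_fractions",
    "fraction_reversing_around_events", "DwellStatistics",
]

STATES = ("F", "R", "P")
DEFAULT_THRESHOLD = 0.5
#: smoothing rule thresholds, in minutes (2 s and 5 s)
SHORT_LOCOMOTION_MIN = 2.0 / 60.0
SHORT_PAUSE_MIN = 5.0 / 60.0


@dataclass
class BehaviorSignals:
    """Cluster-average traces F(t), R(t) and their difference z(t)."""

    times: np.ndarray
    forward_mean: np.ndarray
    reversal_mean: np.ndarray
    n_forward: int
    n_reversal: int

    @property
    def z(self) -> np.ndarray:
        return self.forward_mean - self.reversal_mean


@dataclass
class BehaviorSequence:
    """Per-sample behavioral states on a uniform time grid.

    Each sample represents ``dt`` minutes of behavior; an interval of ``k``
    consecutive equal states has duration ``k * dt``.
    """

    times: np.ndarray
    states: np.ndarray  # array of 'F' | 'R' | 'P'

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype="<U1")
        if self.times.shape != self.states.shape or self.times.size == 0:
            raise ValueError("times and states must be equal-length, nonempty")
        if not set(np.unique(self.states)) <= set(STATES):
            raise ValueError("states must be in {'F', 'R', 'P'}")

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def runs(self) -> list[tuple[str, int, int]]:
        """Run-length encoding: (state, start_index, count)."""
        s = self.states
        change = np.flatnonzero(s[1:] != s[:-1]) + 1
        starts = np.concatenate([[0], change])
        counts = np.diff(np.concatenate([starts, [s.size]]))
        return [(str(s[i]), int(i), int(c)) for i, c in zip(starts, counts)]

    def intervals(self) -> list[tuple[str, float, float]]:
        """(state, t_start, t_end) triples partitioning the time axis."""
        dt = self.dt
        t0 = float(self.times[0])
        out = []
        for state, start, count in self.runs():
            out.append((state, t0 + start * dt, t0 + (start + count) * dt))
        return out

    def dwell_times(self, state: str) -> np.ndarray:
        """Durations (minutes) of all intervals of the given state."""
        dt = self.dt
        return np.array([c * dt for s, _, c in self.runs() if s == state])


def cluster_averages(traces: ActivityTraces, registry: NeuronRegistry
                     ) -> BehaviorSignals:
    """Unweighted forward- and reversal-cluster mean activities.

    Every cluster member must be present in ``traces`` (proxies substituted
    upstream count as present).
    """
    for cluster in (registry.forward, registry.reversal):
        if not cluster:
            raise ValueError("registry has an empty core cluster")
    fwd = traces.matrix_for(registry.forward)
    rev = traces.matrix_for(registry.reversal)
    return BehaviorSignals(traces.times.copy(), fwd.mean(axis=0),
                           rev.mean(axis=0), len(registry.forward),
                           len(registry.reversal))


def classify(z, times=None, threshold: float = DEFAULT_THRESHOLD
             ) -> BehaviorSequence:
    """Threshold the cluster difference into a behavior strip.

    Accepts either a :class:`BehaviorSignals` or a raw z array plus times.
    F where z > threshold, R where z < -threshold, else P.
    """
    if isinstance(z, BehaviorSignals):
        times = z.times
        z = z.z
    z = np.asarray(z, dtype=float)
    if times is None:
        raise ValueError("times required when z is a raw array")
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    states = np.full(z.shape, "P", dtype="<U1")
    states[z > threshold] = "F"
    states[z < -threshold] = "R"
    return BehaviorSequence(np.asarray(times, dtype=float), states)


def smooth_states(seq: BehaviorSequence,
                  short_locomotion: float = SHORT_LOCOMOTION_MIN,
                  short_pause: float = SHORT_PAUSE_MIN) -> BehaviorSequence:
    """Remove implausibly short bouts from a behavior strip.

    Two rules, applied in order in a single left-to-right pass each:

    1. forward/reversal intervals shorter than ``short_locomotion`` (default
       2 s) dividing a pause state become pause;
    2. pause intervals shorter than ``short_pause`` (default 5 s) dividing a
       forward or reversal interval become the enclosing locomotive state.

    Rule 2 only fires when both neighbors share the same locomotion state; a
    short pause between F and R is left unchanged.  Intervals at the
    recording boundary are never relabeled (no enclosing context).
    """
    dt = seq.dt
    states = seq.states.copy()

    def pass_rule(states, target_states, max_dur, neighbor_test, relabel):
        runs = BehaviorSequence(seq.times, states).runs()
        out = states.copy()
        for k, (s, start, count) in enumerate(runs):
            if k == 0 or k == len(runs) - 1:
                continue  # boundary intervals keep their label
            if s not in target_states or count * dt >= max_dur:
                continue
            left, right = runs[k - 1][0], runs[k + 1][0]
            new = relabel(left, right)
            if new is not None and neighbor_test(left, right):
                out[start:start + count] = new
        return out

    # rule 1: short locomotion bouts inside a pause -> pause
    states = pass_rule(
        states, ("F", "R"), short_locomotion,
        neighbor_test=lambda l, r: l == "P" and r == "P",
        relabel=lambda l, r: "P")
    # rule 2: short pauses between same-state locomotion -> that state
    states = pass_rule(
        states, ("P",), short_pause,
        neighbor_test=lambda l, r: l == r and l in ("F", "R"),
        relabel=lambda l, r: l)
    return BehaviorSequence(seq.times.copy(), states)


@dataclass
class DwellStatistics:
    """Histogram of dwell times for one state, after a minimum-dwell filter."""

    state: str
    dwell_times: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float | None

    @property
    def n_intervals(self) -> int:
        return self.dwell_times.size


def dwell_statistics(seq: BehaviorSequence, state: str,
                     bin_width: float = 0.1, min_dwell: float = 0.05
                     ) -> DwellStatistics:
    """Dwell-time histogram for one state (bin width 0.1 min by default),
    excluding intervals shorter than ``min_dwell`` (default 0.05 min)."""
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    dwells = seq.dwell_times(state)
    dwells = dwells[dwells >= min_dwell]
    if dwells.size == 0:
        return DwellStatistics(state, dwells, np.array([0.0]),
                               np.array([], dtype=int), None)
    n_bins = int(np.ceil(dwells.max() / bin_width)) or 1
    edges = bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(dwells, bins=edges)
    return DwellStatistics(state, dwells, edges, counts, float(dwells.mean()))


def state_fractions(seq: BehaviorSequence) -> tuple[float, float, float]:
    """Time-weighted occupancy of (F, R, P); sums to 1."""
    n = seq.states.size
    if n == 0:
        raise ValueError("empty behavior sequence")
    return tuple(float(np.mean(seq.states == s)) for s in STATES)  # type: ignore


def fraction_reversing_around_events(seq: BehaviorSequence,
                                     event_times, pre_window: float,
                                     post_window: float
                                     ) -> tuple[float, float]:
    """Mean reversal occupancy in windows before and after perturbation
    events, averaged over events; events whose windows fall outside the
    sequence coverage are skipped."""
    event_times = np.atleast_1d(np.asarray(event_times, dtype=float))
    if event_times.size == 0:
        raise ValueError("no perturbation events supplied")
    t = seq.times
    pre_vals, post_vals = [], []
    for e in event_times:
        pre = (t >= e - pre_window) & (t < e)
        post = (t > e) & (t <= e + post_window)
        if e - pre_window < t[0] - 1e-12 or e + post_window > t[-1] + 1e-12 \
                or not pre.any() or not post.any():
            continue  # window outside coverage
        pre_vals.append(float(np.mean(seq.states[pre] == "R")))
        post_vals.append(float(np.mean(seq.states[post] == "R")))
    if not pre_vals:
        raise ValueError("all event windows fall outside the sequence coverage")
    return float(np.mean(pre_vals)), float(np.mean(post_vals))
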