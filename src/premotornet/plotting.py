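"""Plot helpers: activity rasters, behavior strips, propagation maps,
locomotion paths.  All functions accept and return matplotlib Axes so they
compose into multi-panel figures."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .behavior import BehaviorSequence
from .locomotion import PathRealization
from .registry import NeuronRegistry
from .traces import ActivityTraces

__all__ = ["plot_traces", "plot_behavior_strip", "plot_propagation_map",
           "plot_path"]

STATE_COLORS = {"F": "#2d6a2d", "R": "#c8a165", "P": "#b0b0b0"}
ROLE_COLORS = {"forward": "#2d6a2d", "reversal": "#c8a165",
               "avd": "#5555aa", "signal": "#888888"}


def _ax(ax):
    if ax is None:
        _, ax = plt.subplots()
    return ax


def plot_traces(traces: ActivityTraces, registry: NeuronRegistry | None = None,
                offset: float = 2.5, ax=None):
    """Stacked activity traces, colored by cluster role when a registry is
    given."""
    ax = _ax(ax)
    for k, name in enumerate(traces.labels):
        color = (ROLE_COLORS.get(registry.role(name)) if registry is not None
                 and name in registry.names else None)
        ax.plot(traces.times, traces.values[k] + offset * k, lw=0.8,
                color=color)
        ax.text(traces.times[0], offset * k, name, fontsize=6, ha="right")
    ax.set_xlabel("time (min)")
    ax.set_yticks([])
    return ax


def plot_behavior_strip(seq: BehaviorSequence, ax=None, y: float = 0.0,
                        height: float = 1.0):
    """Colored forward/reversal/pause strip along the time axis."""
    ax = _ax(ax)
    for state, t0, t1 in seq.intervals():
        ax.axvspan(t0, t1, ymin=y, ymax=y + height,
                   color=STATE_COLORS[state], lw=0)
    ax.set_xlim(seq.times[0], seq.times[-1] + seq.dt)
    ax.set_xlabel("time (min)")
    ax.set_yticks([])
    return ax


def plot_propagation_map(displacements: np.ndarray,
                         registry: NeuronRegistry, ax=None):
    """Heatmap of steady-state displacements (rows: responding neuron,
    columns: stimulated neuron)."""
    ax = _ax(ax)
    v = np.max(np.abs(displacements)) or 1.0
    im = ax.imshow(displacements, cmap="RdBu_r", vmin=-v, vmax=v)
    names = list(registry.core)
    ax.set_xticks(range(len(names)), names, rotation=90, fontsize=6)
    ax.set_yticks(range(len(names)), names, fontsize=6)
    ax.set_xlabel("stimulated")
    ax.set_ylabel("response")
    ax.figure.colorbar(im, ax=ax, label="displacement (z-score)")
    return ax


def plot_path(path: PathRealization, ax=None):
    """One locomotion path, colored by interval state, start marked red."""
    ax = _ax(ax)
    for k, state in enumerate(path.states):
        seg = path.vertices[k:k + 2]
        ax.plot(seg[:, 0], seg[:, 1], color=STATE_COLORS[state], lw=1.0)
    ax.plot(*path.vertices[0], "r.", markersize=8)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    return ax
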