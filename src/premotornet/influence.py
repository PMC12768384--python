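"""Promoter/suppressor ranking of signal neurons and knockout experiments.

A signal neuron promotes (suppresses) a core cluster to the extent that its
rectified activity, weighted by its synaptic connections onto the cluster,
accumulates positive (negative) drive in the windows preceding behavioral
switches into the relevant state.  Gap-junction input is excluded: the
ranking concerns synaptic influence.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavior as behavior_mod
from .network import ModelParameters, NetworkWeights
from .registry import NeuronRegistry
from .simulate import SimulationConfig, integrate, perturb_signals
from .traces import ActivityTraces

__all__ = ["InfluenceRanking", "rank_influencers", "knockout_experiment",
           "DEFAULT_WINDOW_SECONDS"]

DEFAULT_WINDOW_SECONDS = 10.0

#: which switch destination is relevant for each (target, direction)
_SWITCH_STATE = {
    ("forward", "promote"): "F",
    ("reversal", "suppress"): "F",
    ("reversal", "promote"): "R",
    ("forward", "suppress"): "R",
}


@dataclass
class InfluenceRanking:
    """Ranked signal neurons with their cumulative pre-switch drive.

    ``table`` has columns (neuron, score, rank); scores are the summed
    synaptic drive onto the target cluster over all pre-switch windows
    (promoters: positive totals; suppressors: negative totals), ranked by
    magnitude.  ``raw_scores`` keeps the unfiltered per-neuron totals.
    """

    target: str
    direction: str
    window_seconds: float
    n_switches: int
    table: pd.DataFrame
    raw_scores: pd.Series

    def top(self, k: int = 3) -> list[str]:
        return list(self.table["neuron"].head(k))


def rank_influencers(params: ModelParameters, weights: NetworkWeights,
                     registry: NeuronRegistry, signals: ActivityTraces,
                     behavior: behavior_mod.BehaviorSequence,
                     target: str = "forward", direction: str = "promote",
                     window_seconds: float = DEFAULT_WINDOW_SECONDS,
                     per_switch_average: bool = False) -> InfluenceRanking:
    """Rank signal neurons by cumulative synaptic drive before switches.

    For every switch into the relevant state (to-forward for forward
    promoters and reversal suppressors; to-reversal otherwise), the drive of
    signal neuron j is ``sum_{t in window} sum_{i in cluster}
    A[i, j] * relu(x_j(t)) * dt`` over the ``window_seconds`` preceding the
    switch; totals are summed over switches (or averaged with
    ``per_switch_average``).
    """
    if target not in ("forward", "reversal"):
        raise ValueError("target must be 'forward' or 'reversal'")
    if direction not in ("promote", "suppress"):
        raise ValueError("direction must be 'promote' or 'suppress'")
    switch_state = _SWITCH_STATE[(target, direction)]
    cluster = registry.forward if target == "forward" else registry.reversal
    cluster_rows = registry.core_indices(cluster)
    window = window_seconds / 60.0  # minutes
    dt = signals.dt

    # switch times: first sample of every new F/R interval after the start
    runs = behavior.runs()
    t0 = float(behavior.times[0])
    bdt = behavior.dt
    switch_times = [t0 + start * bdt for k, (s, start, _) in enumerate(runs)
                    if k > 0 and s == switch_state]

    present = [n for n in registry.signal if n in signals]
    cols = [registry.index(n) for n in present]
    scores = pd.Series(0.0, index=present)
    cluster_weight = params.syn[np.ix_(cluster_rows, cols)].sum(axis=0)
    sig_matrix = signals.matrix_for(present)
    eps = 1e-9  # tolerate float rounding at window boundaries
    for ts in switch_times:
        mask = (signals.times >= ts - window - eps) & (signals.times < ts - eps)
        if not mask.any():
            continue
        relu = np.maximum(sig_matrix[:, mask], 0.0)
        scores += pd.Series(cluster_weight * relu.sum(axis=1) * dt,
                            index=present)
    if per_switch_average and switch_times:
        scores = scores / len(switch_times)

    if direction == "promote":
        kept = scores[scores > 0].sort_values(ascending=False)
    else:
        kept = scores[scores < 0].sort_values(ascending=True)
    table = pd.DataFrame({"neuron": kept.index, "score": kept.values,
                          "rank": np.arange(1, len(kept) + 1)})
    return InfluenceRanking(target=target, direction=direction,
                            window_seconds=window_seconds,
                            n_switches=len(switch_times), table=table,
                            raw_scores=scores)


def knockout_experiment(params: ModelParameters, weights: NetworkWeights,
                        registry: NeuronRegistry, signals: ActivityTraces,
                        neurons, cfg: SimulationConfig | None = None,
                        threshold: float = behavior_mod.DEFAULT_THRESHOLD,
                        smooth: bool = False):
    """Re-simulate with the named signal traces set to zero.

    Returns ``(baseline_seq, knockout_seq, occupancy_deltas)`` where the
    deltas map each state to (knockout fraction - baseline fraction).
    """
    neurons = list(neurons)
    for n in neurons:
        if n not in registry.signal:
            raise KeyError(f"{n!r} is not a signal neuron")
    cfg = cfg or SimulationConfig()

    def run(sig: ActivityTraces) -> behavior_mod.BehaviorSequence:
        core = integrate(params, weights, sig, cfg, registry)
        seq = behavior_mod.classify(
            behavior_mod.cluster_averages(core, registry), threshold=threshold)
        return behavior_mod.smooth_states(seq) if smooth else seq

    baseline_seq = run(signals)
    ko_signals = perturb_signals(signals, [(n, "zero") for n in neurons]) \
        if neurons else signals
    knockout_seq = run(ko_signals) if neurons else baseline_seq
    base_frac = behavior_mod.state_fractions(baseline_seq)
    ko_frac = behavior_mod.state_fractions(knockout_seq)
    deltas = {s: ko_frac[k] - base_frac[k]
              for k, s in enumerate(behavior_mod.STATES)}
    return baseline_seq, knockout_seq, deltas
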