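"""High-level facade: a fitted premotor network and its analyses.

:class:`PremotorNetwork` bundles the parameterization, connectome weights and
neuron registry of one fitted model and exposes the downstream analyses
(simulation, ablation, propagation maps, behavior classification, influence
ranking, knockouts) as methods.  Construct it from fitted results, a saved
parameter bundle, or the synthetic generator's ground truth.
"""
from __future__ import annotations

import numpy as np

from . import behavior as behavior_mod
from . import influence as influence_mod
from . import simulate as simulate_mod
from .network import ModelParameters, NetworkWeights
from .registry import NeuronRegistry
from .simulate import SimulationConfig
from .traces import ActivityTraces

__all__ = ["PremotorNetwork"]


class PremotorNetwork:
    """A driven premotor-network model with a fixed parameterization."""

    def __init__(self, params: ModelParameters, weights: NetworkWeights,
                 registry: NeuronRegistry) -> None:
        if params.syn.shape != weights.syn_mask.shape:
            raise ValueError("parameter and weight shapes disagree")
        if registry.n_total != weights.n_total:
            raise ValueError("registry size does not match the weight matrices")
        params.validate_support(weights)
        self.params = params
        self.weights = weights
        self.registry = registry

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_bundle(cls, path) -> "PremotorNetwork":
        from .io import read_parameter_bundle
        params, weights, registry, _ = read_parameter_bundle(path)
        return cls(params, weights, registry)

    @classmethod
    def from_synthetic(cls, dataset) -> "PremotorNetwork":
        return cls(dataset.params, dataset.weights, dataset.registry)

    # -- simulation -------------------------------------------------------
    def simulate(self, signals: ActivityTraces,
                 cfg: SimulationConfig | None = None) -> ActivityTraces:
        return simulate_mod.integrate(self.params, self.weights, signals,
                                      cfg, self.registry)

    def ablated(self, classes) -> "PremotorNetwork":
        p, w = simulate_mod.ablate(self.params, self.weights, self.registry,
                                   classes)
        return PremotorNetwork(p, w, self.registry)

    def stimulate(self, target: str, amplitude: float,
                  window: tuple[float, float],
                  cfg: SimulationConfig | None = None) -> ActivityTraces:
        return simulate_mod.stimulate(self.params, self.weights,
                                      self.registry, target, amplitude,
                                      window, cfg)

    def baseline_fixed_point(self, cfg: SimulationConfig | None = None
                             ) -> np.ndarray:
        return simulate_mod.baseline_fixed_point(self.params, self.weights,
                                                 cfg)

    def propagation_map(self, amplitude: float = 2.0,
                        cfg: SimulationConfig | None = None,
                        window_minutes: float = 5.0) -> np.ndarray:
        return simulate_mod.propagation_map(self.params, self.weights,
                                            self.registry, amplitude, cfg,
                                            window_minutes)

    # -- behavior ---------------------------------------------------------
    def behavior(self, core_traces: ActivityTraces,
                 threshold: float = behavior_mod.DEFAULT_THRESHOLD,
                 smooth: bool = False) -> behavior_mod.BehaviorSequence:
        seq = behavior_mod.classify(
            behavior_mod.cluster_averages(core_traces, self.registry),
            threshold=threshold)
        return behavior_mod.smooth_states(seq) if smooth else seq

    # -- influence --------------------------------------------------------
    def rank_influencers(self, signals: ActivityTraces,
                         behavior_seq: behavior_mod.BehaviorSequence,
                         **kwargs) -> influence_mod.InfluenceRanking:
        return influence_mod.rank_influencers(self.params, self.weights,
                                              self.registry, signals,
                                              behavior_seq, **kwargs)

    def knockout(self, signals: ActivityTraces, neurons,
                 cfg: SimulationConfig | None = None, **kwargs):
        return influence_mod.knockout_experiment(self.params, self.weights,
                                                 self.registry, signals,
                                                 neurons, cfg, **kwargs)
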