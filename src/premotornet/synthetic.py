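"""Synthetic connectomes, ground-truth parameters and signal traces.

The generator emulates the statistical structure of the real inputs so that
every downstream stage (regression, simulation, behavior, influence ranking)
is testable without any download:

* a surrogate connectome with a symmetric nonnegative gap-junction matrix and
  a sparse synapse-presence mask with forward/reversal block structure;
* ground-truth signed synaptic weights whose sign biases follow the principal
  circuit structure (within-cluster excitation, cross-cluster inhibition,
  signal groups that promote one cluster and suppress the other);
* signal-neuron traces generated as Ornstein-Uhlenbeck noise passed through a
  saturating bistable map, giving smooth series with bimodal marginals peaked
  near the intrinsic fixed points -0.8 and 1, organized into cross-correlated
  groups;
* full datasets in which the core traces are the integrated model response to
  the generated signals plus additive observation noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import dynamics
from .network import ModelParameters, NetworkWeights
from .registry import NeuronRegistry, default_registry
from .simulate import SimulationConfig, integrate
from .traces import ActivityTraces

__all__ = ["SyntheticSpec", "SyntheticDataset", "synthetic_registry",
           "generate_connectome", "generate_ground_truth_params",
           "generate_signal_traces", "generate_dataset"]

#: sign bias per (presynaptic role, postsynaptic role): probability of an
#: excitatory sign is (1 + bias) / 2.  "signal_fwd"/"signal_rev" are the two
#: functional signal groups (forward-promoting / reversal-promoting).
DEFAULT_BLOCK_STRUCTURE: dict[tuple[str, str], float] = {
    ("forward", "forward"): 0.9,
    ("reversal", "reversal"): 0.9,
    ("forward", "reversal"): -0.9,
    ("reversal", "forward"): -0.9,
    ("forward", "avd"): 0.0,
    ("reversal", "avd"): 0.0,
    ("avd", "forward"): 0.0,
    ("avd", "reversal"): 0.0,
    ("avd", "avd"): 0.0,
    ("signal_fwd", "forward"): 0.9,
    ("signal_fwd", "reversal"): -0.9,
    ("signal_fwd", "avd"): 0.0,
    ("signal_rev", "forward"): -0.9,
    ("signal_rev", "reversal"): 0.9,
    ("signal_rev", "avd"): 0.0,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic corpus.

    Defaults mirror the real modeling setup: a 15-neuron core driven by 112
    signal neurons sampled every 0.01 min, with 12-minute recordings.
    """

    n_core: int = 15
    n_signal: int = 112
    gap_density: float = 0.3
    syn_density: float = 0.3
    block_structure: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BLOCK_STRUCTURE))
    trace_length: int = 1200
    dt: float = 0.01  # minutes
    noise_sd: float = 0.05  # observation noise on core traces, z-score units
    seed: int = 0
    # generative-law details (the real data constrain only the marginals)
    beta: float = 1.0
    tau: float = 0.2
    magnification: float = 1.0
    syn_weight_scale: float = 0.4
    bias_sd: float = 0.1
    n_groups: int = 4
    group_corr: float = 0.8     # latent shared-driver fraction within a group
    signal_sd: float = 1.5      # stationary latent sd; 0 gives constant traces
    signal_timescale: float = 0.5  # latent OU correlation time, minutes
    latent_mean: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.gap_density <= 1 and 0 <= self.syn_density <= 1):
            raise ValueError("densities must lie in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.trace_length < 2:
            raise ValueError("trace_length must be at least 2")
        if not (0 <= self.group_corr <= 1):
            raise ValueError("group_corr must lie in [0, 1]")


def synthetic_registry(spec: SyntheticSpec) -> NeuronRegistry:
    """Registry for a synthetic network.

    With the default 15-neuron core the real core names are used; otherwise
    the core splits into paired forward/reversal halves with generated names.
    Signal neurons are named SIG001, SIG002, ...
    """
    signal = tuple(f"SIG{i + 1:03d}" for i in range(spec.n_signal))
    if spec.n_core == 15:
        return default_registry(signal=signal)
    n_fwd = max(spec.n_core // 2, 1)
    forward = tuple(f"FD{i + 1:02d}{'L' if i % 2 == 0 else 'R'}"
                    for i in range(n_fwd))
    reversal = tuple(f"RV{i + 1:02d}{'L' if i % 2 == 0 else 'R'}"
                     for i in range(spec.n_core - n_fwd))
    return NeuronRegistry(forward=forward, reversal=reversal, avd=(),
                          signal=signal)


def _signal_group(spec: SyntheticSpec, signal_index: int) -> int:
    return signal_index % max(spec.n_groups, 1)


def _signal_role(spec: SyntheticSpec, signal_index: int) -> str:
    """Functional role of a signal neuron: even groups promote forward."""
    return "signal_fwd" if _signal_group(spec, signal_index) % 2 == 0 else \
        "signal_rev"


def _rng(spec: SyntheticSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, salt]))


def generate_connectome(spec: SyntheticSpec,
                        registry: NeuronRegistry | None = None
                        ) -> NetworkWeights:
    """Surrogate connectome: symmetric nonnegative gap weights and a boolean
    synapse-presence mask at the requested densities."""
    registry = registry or synthetic_registry(spec)
    rng = _rng(spec, 1)
    n_core, n_total = registry.n_core, registry.n_total
    gap = np.zeros((n_total, n_total))
    # core-core block: symmetric, zero diagonal
    upper = np.triu(rng.random((n_core, n_core)) < spec.gap_density, k=1)
    w = rng.gamma(shape=2.0, scale=1.0, size=(n_core, n_core)) * upper
    gap[:n_core, :n_core] = w + w.T
    # signal-core gap junctions (sparser), mirrored for symmetry
    sel = rng.random((n_core, n_total - n_core)) < spec.gap_density / 2
    ws = rng.gamma(shape=2.0, scale=1.0, size=sel.shape) * sel
    gap[:n_core, n_core:] = ws
    gap[n_core:, :n_core] = ws.T
    mask = rng.random((n_core, n_total)) < spec.syn_density
    mask[:, :n_core] &= ~np.eye(n_core, dtype=bool)  # no self-synapses
    return NetworkWeights(gap, mask)


def generate_ground_truth_params(spec: SyntheticSpec, weights: NetworkWeights,
                                 registry: NeuronRegistry | None = None
                                 ) -> ModelParameters:
    """Ground-truth signed synaptic weights and biases on the mask support.

    Signs are drawn with the block-structure bias of the presynaptic and
    postsynaptic roles; magnitudes are gamma-distributed around
    ``syn_weight_scale``.
    """
    registry = registry or synthetic_registry(spec)
    rng = _rng(spec, 2)
    n_core, n_total = weights.n_core, weights.n_total
    roles = [registry.role(n) for n in registry.core]
    syn = np.zeros((n_core, n_total))
    for i in range(n_core):
        for j in range(n_total):
            if not weights.syn_mask[i, j]:
                continue
            role_pre = (roles[j] if j < n_core
                        else _signal_role(spec, j - n_core))
            bias = spec.block_structure.get((role_pre, roles[i]), 0.0)
            sign = 1.0 if rng.random() < (1.0 + bias) / 2.0 else -1.0
            syn[i, j] = sign * rng.gamma(2.0, spec.syn_weight_scale / 2.0)
    bias_vec = rng.normal(0.0, spec.bias_sd, size=n_core)
    return ModelParameters(syn=syn, bias=bias_vec, beta=spec.beta,
                           tau=spec.tau, magnification=max(spec.magnification, 1.0))


def generate_signal_traces(spec: SyntheticSpec,
                           registry: NeuronRegistry | None = None
                           ) -> ActivityTraces:
    """Signal traces: correlated OU latents through a soft bistable map.

    Each neuron's latent is ``sqrt(rho) * group_driver + sqrt(1-rho) * own``
    where both parts are stationary OU processes with sd ``signal_sd`` and
    correlation time ``signal_timescale``; the trace is
    ``0.1 + 0.9 * tanh(latent)``, whose marginal is bimodal with modes near
    -0.8 and 1 when the latent sd is large enough to saturate the tanh.
    """
    registry = registry or synthetic_registry(spec)
    rng = _rng(spec, 3)
    n_sig, n_t = spec.n_signal, spec.trace_length
    n_groups = max(spec.n_groups, 1)
    theta = spec.signal_timescale
    sd = spec.signal_sd
    a = np.exp(-spec.dt / theta)
    innov_sd = sd * np.sqrt(1.0 - a * a)

    def ou(n_series: int) -> np.ndarray:
        y = np.empty((n_series, n_t))
        y[:, 0] = spec.latent_mean + (rng.normal(0.0, sd, n_series)
                                      if sd > 0 else 0.0)
        eps = rng.normal(0.0, 1.0, (n_series, n_t - 1)) if sd > 0 else None
        for k in range(1, n_t):
            drift = spec.latent_mean + a * (y[:, k - 1] - spec.latent_mean)
            y[:, k] = drift + (innov_sd * eps[:, k - 1] if sd > 0 else 0.0)
        return y

    drivers = ou(n_groups)
    own = ou(n_sig)
    rho = spec.group_corr
    latent = np.empty((n_sig, n_t))
    for i in range(n_sig):
        g = _signal_group(spec, i)
        latent[i] = (spec.latent_mean
                     + np.sqrt(rho) * (drivers[g] - spec.latent_mean)
                     + np.sqrt(1.0 - rho) * (own[i] - spec.latent_mean))
    values = 0.1 + 0.9 * np.tanh(latent)
    times = spec.dt * np.arange(n_t)
    return ActivityTraces(registry.signal, times, values)


@dataclass
class SyntheticDataset:
    """A complete synthetic recording with its generating truth.

    ``traces`` holds core + signal rows (observation noise on the core);
    ``exact_derivatives`` are the model rates evaluated on the noiseless core
    solution at the sample times (rows follow ``registry.core``).
    """

    traces: ActivityTraces
    params: ModelParameters
    weights: NetworkWeights
    registry: NeuronRegistry
    noiseless_core: ActivityTraces
    exact_derivatives: np.ndarray


def generate_dataset(spec: SyntheticSpec,
                     drop_neurons: Sequence[str] = ()) -> SyntheticDataset:
    """Generate a full dataset: signals, integrated core response, noise.

    ``drop_neurons`` removes named neurons from the emitted traces to
    exercise missing-data handling downstream (the generating truth still
    contains them).
    """
    registry = synthetic_registry(spec)
    weights = generate_connectome(spec, registry)
    params = generate_ground_truth_params(spec, weights, registry)
    signals = generate_signal_traces(spec, registry)
    cfg = SimulationConfig(output_dt=spec.dt, rel_tol=1e-10, abs_tol=1e-12)
    try:
        core = integrate(params, weights, signals, cfg, registry)
    except RuntimeError as exc:
        raise RuntimeError(
            f"synthetic core integration failed for seed={spec.seed}") from exc
    sig_at_samples = signals.values  # exact sample values
    deriv = np.empty_like(core.values)
    for k in range(core.n_samples):
        deriv[:, k] = dynamics.rhs(core.times[k], core.values[:, k],
                                   sig_at_samples[:, k], params, weights)
    rng = _rng(spec, 4)
    noisy_core = core.values + (
        rng.normal(0.0, spec.noise_sd, core.values.shape)
        if spec.noise_sd > 0 else 0.0)
    labels = registry.core + registry.signal
    values = np.vstack([noisy_core, signals.values])
    if drop_neurons:
        keep = [i for i, n in enumerate(labels) if n not in set(drop_neurons)]
        labels = tuple(labels[i] for i in keep)
        values = values[keep]
    traces = ActivityTraces(labels, core.times, values)
    return SyntheticDataset(traces=traces, params=params, weights=weights,
                            registry=registry,
                            noiseless_core=core, exact_derivatives=deriv)
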