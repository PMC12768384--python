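"""Network weight containers: gap junctions, synapse support, fitted parameters.

Index convention follows :class:`~premotornet.registry.NeuronRegistry`: the
first ``n_core`` indices are core neurons, the remaining indices are signal
neurons.  The gap-junction matrix ``gap`` is stored over all neuron pairs but
only its core rows enter the dynamics; the synaptic containers store core rows
only (signal neurons are never postsynaptic in the model).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["NetworkWeights", "ModelParameters", "VoltageCubicCalibration"]

_SYM_TOL = 1e-12


@dataclass
class NetworkWeights:
    """Connectome-derived coupling structure.

    Attributes
    ----------
    gap : ndarray, shape (n_total, n_total)
        Nonnegative relative gap-junction weights; the core-core block must be
        symmetric (electrical synapses are undirected).
    syn_mask : ndarray of bool, shape (n_core, n_total)
        Synapse presence: ``syn_mask[i, j]`` is True when the connectome
        records a chemical synapse from neuron ``j`` onto core neuron ``i``.
        Fitted synaptic weights are constrained to this support.
    """

    gap: np.ndarray
    syn_mask: np.ndarray

    def __post_init__(self) -> None:
        self.gap = np.asarray(self.gap, dtype=float)
        self.syn_mask = np.asarray(self.syn_mask, dtype=bool)
        n_core, n_total = self.syn_mask.shape
        if self.gap.shape != (n_total, n_total):
            raise ValueError(
                f"gap shape {self.gap.shape} incompatible with syn_mask "
                f"shape {self.syn_mask.shape}")
        if n_core > n_total:
            raise ValueError("more core rows than total neurons")
        if np.any(self.gap < 0):
            raise ValueError("gap-junction weights must be nonnegative")
        core_block = self.gap[:n_core, :n_core]
        if np.max(np.abs(core_block - core_block.T), initial=0.0) > _SYM_TOL:
            raise ValueError("core-core gap-junction block must be symmetric")

    @property
    def n_core(self) -> int:
        return self.syn_mask.shape[0]

    @property
    def n_total(self) -> int:
        return self.syn_mask.shape[1]

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(self.gap.copy(), self.syn_mask.copy())


@dataclass
class ModelParameters:
    """Complete parameterization of the driven core dynamics.

    ``tau * dx_i/dt = f_i(x_i) + beta * sum_j gap[i,j] (x_j - x_i)
    + magnification * sum_j syn[i,j] relu(x_j)``
    with ``f_i(x) = -2 (x + 0.8)(x - 0.1)(x - 1) + bias[i]``.

    Attributes
    ----------
    syn : ndarray, shape (n_core, n_total)
        Signed synaptic weights (net excitatory/inhibitory), zero outside the
        connectome support.
    bias : ndarray, shape (n_core,)
        Per-neuron offset of the intrinsic cubic.
    beta : float
        Relative contribution of gap-junction input (> 0).
    tau : float
        Global timescale in minutes (> 0).
    magnification : float
        Simulation-time amplification of synaptic input (>= 1), compensating
        for signal neurons missing from a given dataset.  Never applied during
        fitting.
    """

    syn: np.ndarray
    bias: np.ndarray
    beta: float = 10.0
    tau: float = 0.2
    magnification: float = 1.4

    def __post_init__(self) -> None:
        self.syn = np.asarray(self.syn, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.syn.ndim != 2 or self.bias.shape != (self.syn.shape[0],):
            raise ValueError("bias length must equal the number of core rows of syn")
        if not (self.beta > 0):
            raise ValueError("beta must be positive")
        if not (self.tau > 0):
            raise ValueError("tau must be positive")
        if not (self.magnification >= 1):
            raise ValueError("magnification must be >= 1")

    @property
    def n_core(self) -> int:
        return self.syn.shape[0]

    @property
    def n_total(self) -> int:
        return self.syn.shape[1]

    def validate_support(self, weights: NetworkWeights, tol: float = 0.0) -> None:
        """Raise if any synaptic weight lies outside the connectome support."""
        off = np.abs(self.syn[~weights.syn_mask])
        if off.size and np.max(off) > tol:
            raise ValueError("synaptic weights present outside connectome support")

    def copy(self) -> "ModelParameters":
        return replace(self, syn=self.syn.copy(), bias=self.bias.copy())


@dataclass(frozen=True)
class VoltageCubicCalibration:
    """Voltage-form intrinsic dynamics calibrated to RMD voltage-clamp data.

    ``dV/dt = -coefficient * (V - roots[0]) (V - roots[1]) (V - roots[2])``
    with V in mV.  The default roots place stable resting and plateau
    potentials at -70 and -50 mV with an unstable threshold at -60 mV.
    """

    coefficient: float = 1.0 / 8000.0
    roots: tuple[float, float, float] = (-70.0, -60.0, -50.0)

    def __post_init__(self) -> None:
        r = sorted(self.roots)
        if len(set(r)) != 3:
            raise ValueError("calibration roots must be distinct")
        object.__setattr__(self, "roots", tuple(r))

    def vector_field(self, v: float) -> float:
        a, b, c = self.roots
        return -self.coefficient * (v - a) * (v - b) * (v - c)
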