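"""Activity trace container: named neurons x uniformly sampled GCaMP z-scores."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ActivityTraces"]

_UNIFORMITY_TOL = 1e-9


@dataclass
class ActivityTraces:
    """Named neuron activity time series on a uniform time grid.

    Attributes
    ----------
    labels : tuple of str
        Unique neuron names, one per row of ``values``.
    times : ndarray, shape (n_samples,)
        Sample times in minutes, strictly increasing and uniformly spaced.
    values : ndarray, shape (n_neurons, n_samples)
        GCaMP z-score activity, finite.
    """

    labels: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("trace labels must be unique")
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("times must be a 1-D array with at least 2 samples")
        if self.values.shape != (len(self.labels), self.times.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.labels)}, {self.times.size})")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if np.ptp(steps) > _UNIFORMITY_TOL:
            raise ValueError("times must be uniformly spaced")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        self._index = {name: i for i, name in enumerate(self.labels)}

    # -- basic accessors --------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return len(self.labels)

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        """Sampling interval in minutes."""
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def row(self, name: str) -> np.ndarray:
        try:
            return self.values[self._index[name]]
        except KeyError:
            raise KeyError(f"no trace for neuron {name!r}") from None

    def subset(self, names) -> "ActivityTraces":
        """Traces restricted to the given names, in the given order."""
        idx = [self._index[n] if n in self._index else self._missing(n) for n in names]
        return ActivityTraces(tuple(names), self.times.copy(), self.values[idx].copy())

    def _missing(self, name: str):
        raise KeyError(f"no trace for neuron {name!r}")

    def with_values(self, values: np.ndarray) -> "ActivityTraces":
        return ActivityTraces(self.labels, self.times.copy(), np.asarray(values, float))

    def copy(self) -> "ActivityTraces":
        return ActivityTraces(self.labels, self.times.copy(), self.values.copy())

    def matrix_for(self, names) -> np.ndarray:
        """Values stacked in the order of ``names`` (all must be present)."""
        return np.stack([self.row(n) for n in names])
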