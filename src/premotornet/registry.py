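"""Neuron registry: names, core/signal membership, cluster roles.

The modeled circuit is a recurrent "core" of premotor interneurons driven by a
larger set of "signal" neurons whose recorded traces enter the model as external
input.  The default core contains 15 neurons split into three clusters:

* forward cluster (5): AVBL, AVBR, RIBL, RIBR, RID
* reversal cluster (8): AVAL, AVAR, RIML, RIMR, AVEL, AVER, AIBL, AIBR
* AVD pair (2): AVDL, AVDR — highly interconnected with both clusters

Left/right homologs collapse onto a single class label (AVBL, AVBR -> AVB),
which is the unit used for ablations and dataset-selection rules.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = ["NeuronRegistry", "default_registry", "class_of_name",
           "FORWARD_NEURONS", "REVERSAL_NEURONS", "AVD_NEURONS"]

FORWARD_NEURONS = ("AVBL", "AVBR", "RIBL", "RIBR", "RID")
REVERSAL_NEURONS = ("AVAL", "AVAR", "RIML", "RIMR", "AVEL", "AVER", "AIBL", "AIBR")
AVD_NEURONS = ("AVDL", "AVDR")

ROLES = ("forward", "reversal", "avd", "signal")


def class_of_name(name: str) -> str:
    """Collapse a left/right neuron name onto its class label.

    ``AVBL``/``AVBR`` -> ``AVB``; names without a trailing L/R side suffix
    (e.g. ``RID``) are their own class.  Three-letter names are never stripped
    (all C. elegans class stems have >= 3 characters).
    """
    if len(name) >= 4 and name[-1] in "LR":
        return name[:-1]
    return name


@dataclass(frozen=True)
class NeuronRegistry:
    """Ordered neuron name lists with role and class lookup.

    Core neurons come first (forward, reversal, avd, in that order) followed by
    the signal neurons; every index-based container in the package uses this
    ordering.
    """

    forward: tuple[str, ...] = FORWARD_NEURONS
    reversal: tuple[str, ...] = REVERSAL_NEURONS
    avd: tuple[str, ...] = AVD_NEURONS
    signal: tuple[str, ...] = ()
    class_overrides: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        core = self.forward + self.reversal + self.avd
        if len(set(core)) != len(core):
            raise ValueError("core neuron names must be unique")
        if set(core) & set(self.signal):
            raise ValueError("signal names must be disjoint from core names")
        if len(set(self.signal)) != len(self.signal):
            raise ValueError("signal neuron names must be unique")

    # -- membership -------------------------------------------------------
    @property
    def core(self) -> tuple[str, ...]:
        return self.forward + self.reversal + self.avd

    @property
    def names(self) -> tuple[str, ...]:
        return self.core + self.signal

    @property
    def n_core(self) -> int:
        return len(self.core)

    @property
    def n_signal(self) -> int:
        return len(self.signal)

    @property
    def n_total(self) -> int:
        return self.n_core + self.n_signal

    def role(self, name: str) -> str:
        if name in self.forward:
            return "forward"
        if name in self.reversal:
            return "reversal"
        if name in self.avd:
            return "avd"
        if name in self.signal:
            return "signal"
        raise KeyError(f"unknown neuron {name!r}")

    def class_of(self, name: str) -> str:
        if name in self.class_overrides:
            return self.class_overrides[name]
        return class_of_name(name)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown neuron {name!r}") from None

    def core_classes(self) -> tuple[str, ...]:
        """Distinct core class labels in core order."""
        seen: list[str] = []
        for n in self.core:
            c = self.class_of(n)
            if c not in seen:
                seen.append(c)
        return tuple(seen)

    def members_of_class(self, label: str) -> tuple[str, ...]:
        members = tuple(n for n in self.names if self.class_of(n) == label)
        if not members:
            raise KeyError(f"unknown neuron class {label!r}")
        return members

    def core_indices(self, names: Iterable[str]) -> list[int]:
        """Indices (within the core block) of the given core neuron names."""
        core = self.core
        out = []
        for n in names:
            if n not in core:
                raise KeyError(f"{n!r} is not a core neuron")
            out.append(core.index(n))
        return out


def default_registry(signal: Iterable[str] = ()) -> NeuronRegistry:
    """The 15-neuron core registry, optionally with named signal neurons."""
    return NeuronRegistry(signal=tuple(signal))
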