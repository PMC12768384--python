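"""On-disk formats: activity datasets (JSON), connectome edge lists (CSV),
parameter bundles (JSON), behavior strips and path tables (TSV).

The local activity-dataset schema is JSON with explicit ``dt_minutes``,
``labels`` and ``traces`` fields; a configurable field-name adapter maps
whole-brain-imaging database exports with different key names onto it.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .network import ModelParameters, NetworkWeights
from .registry import NeuronRegistry
from .traces import ActivityTraces

__all__ = [
    "read_activity_dataset", "write_activity_dataset",
    "read_connectome_table", "write_connectome_table",
    "write_parameter_bundle", "read_parameter_bundle",
    "write_behavior_strip", "write_path_table", "write_provenance",
]

#: accepted aliases for each local schema field, tried in order
DEFAULT_SCHEMA: dict[str, tuple[str, ...]] = {
    "labels": ("labels", "labeled", "neuron_ids", "ids"),
    "traces": ("traces", "trace_array", "data", "values"),
    "dt_minutes": ("dt_minutes", "avg_timestep", "dt"),
    "t0_minutes": ("t0_minutes", "t0"),
    "times": ("times", "timestamps"),
}


def _lookup(raw: Mapping, field: str, schema: Mapping[str, tuple[str, ...]]):
    for key in schema.get(field, (field,)):
        if key in raw:
            return raw[key]
    return None


def read_activity_dataset(path, registry: NeuronRegistry | None = None,
                          schema: Mapping[str, tuple[str, ...]] | None = None
                          ) -> ActivityTraces:
    """Read a JSON activity dataset.

    Unknown labels (relative to ``registry``) are kept but flagged with a
    warning; non-uniform time axes are rejected.
    """
    raw = json.loads(Path(path).read_text())
    schema = schema or DEFAULT_SCHEMA
    labels = _lookup(raw, "labels", schema)
    traces = _lookup(raw, "traces", schema)
    if labels is None:
        raise ValueError(f"{path}: missing neuron label field "
                         f"(tried {schema['labels']})")
    if traces is None:
        raise ValueError(f"{path}: missing trace field "
                         f"(tried {schema['traces']})")
    values = np.asarray(traces, dtype=float)
    if values.ndim != 2 or values.shape[0] != len(labels):
        raise ValueError(f"{path}: trace matrix shape {values.shape} does not"
                         f" match {len(labels)} labels")
    times = _lookup(raw, "times", schema)
    if times is not None:
        times = np.asarray(times, dtype=float)
    else:
        dt = _lookup(raw, "dt_minutes", schema)
        if dt is None:
            raise ValueError(f"{path}: missing dt_minutes (or times) field")
        t0 = _lookup(raw, "t0_minutes", schema) or 0.0
        times = float(t0) + float(dt) * np.arange(values.shape[1])
    try:
        out = ActivityTraces(tuple(labels), times, values)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    if registry is not None:
        unknown = [n for n in out.labels if n not in registry.names]
        if unknown:
            warnings.warn(f"{path}: labels not in the registry (kept): "
                          f"{unknown}", stacklevel=2)
    return out


def write_activity_dataset(path, traces: ActivityTraces) -> None:
    doc = {
        "dt_minutes": traces.dt,
        "t0_minutes": float(traces.times[0]),
        "labels": list(traces.labels),
        "traces": traces.values.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def read_connectome_table(path, registry: NeuronRegistry) -> NetworkWeights:
    """Read a connectome edge list (CSV: pre, post, kind, weight).

    Gap edges accumulate symmetrically into the gap matrix; chemical edges
    set the synapse mask (weight ignored beyond presence).  Duplicate edges
    are summed with a warning; edges naming unregistered neurons, or chemical
    edges onto non-core neurons, are skipped with a warning.
    """
    df = pd.read_csv(path)
    required = {"pre", "post", "kind"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: connectome table needs columns {required}")
    if "weight" not in df.columns:
        df["weight"] = 1.0
    n_core, n_total = registry.n_core, registry.n_total
    gap = np.zeros((n_total, n_total))
    mask = np.zeros((n_core, n_total), dtype=bool)
    core = set(registry.core)
    seen: set[tuple] = set()
    for _, row in df.iterrows():
        pre, post, kind = str(row["pre"]), str(row["post"]), str(row["kind"])
        w = float(row["weight"])
        if pre not in registry.names or post not in registry.names:
            warnings.warn(f"{path}: edge {pre}->{post} names unregistered "
                          "neuron(s); skipped", stacklevel=2)
            continue
        i, j = registry.index(post), registry.index(pre)
        if kind == "gap":
            if w < 0:
                raise ValueError(f"{path}: negative gap weight {pre}-{post}")
            key = ("gap", *sorted((pre, post)))
            if key in seen:
                warnings.warn(f"{path}: duplicate gap edge {pre}-{post} "
                              "summed", stacklevel=2)
            seen.add(key)
            gap[i, j] += w
            if i != j:
                gap[j, i] += w
        elif kind == "chemical":
            if post not in core:
                warnings.warn(f"{path}: chemical edge onto non-core neuron "
                              f"{post}; skipped", stacklevel=2)
                continue
            key = ("chem", pre, post)
            if key in seen:
                warnings.warn(f"{path}: duplicate chemical edge "
                              f"{pre}->{post}", stacklevel=2)
            seen.add(key)
            mask[i, j] = True
        else:
            raise ValueError(f"{path}: unknown edge kind {kind!r}")
    return NetworkWeights(gap, mask)


def write_connectome_table(path, weights: NetworkWeights,
                           registry: NeuronRegistry) -> None:
    names = registry.names
    rows = []
    n_core = weights.n_core
    for i in range(n_core):
        for j in range(weights.n_total):
            if j < i or (j >= n_core):
                w = weights.gap[i, j]
                if w > 0:
                    rows.append({"pre": names[i], "post": names[j],
                                 "kind": "gap", "weight": w})
    for i in range(n_core):
        for j in range(weights.n_total):
            if weights.syn_mask[i, j]:
                rows.append({"pre": names[j], "post": names[i],
                             "kind": "chemical", "weight": 1.0})
    pd.DataFrame(rows, columns=["pre", "post", "kind", "weight"]).to_csv(
        path, index=False)


def write_parameter_bundle(path, params: ModelParameters,
                           weights: NetworkWeights, registry: NeuronRegistry,
                           provenance: dict | None = None) -> None:
    """Write a fitted parameter bundle (model + connectome + registry +
    provenance metadata) as JSON."""
    from . import __version__
    doc = {
        "registry": {
            "forward": list(registry.forward),
            "reversal": list(registry.reversal),
            "avd": list(registry.avd),
            "signal": list(registry.signal),
        },
        "weights": {
            "gap": weights.gap.tolist(),
            "syn_mask": weights.syn_mask.astype(int).tolist(),
        },
        "params": {
            "syn": params.syn.tolist(),
            "bias": params.bias.tolist(),
            "beta": params.beta,
            "tau": params.tau,
            "magnification": params.magnification,
        },
        "provenance": dict(provenance or {}, software_version=__version__),
    }
    Path(path).write_text(json.dumps(doc))


def read_parameter_bundle(path) -> tuple[ModelParameters, NetworkWeights,
                                         NeuronRegistry, dict]:
    raw = json.loads(Path(path).read_text())
    for key in ("registry", "weights", "params"):
        if key not in raw:
            raise ValueError(f"{path}: parameter bundle missing field {key!r}")
    r = raw["registry"]
    registry = NeuronRegistry(forward=tuple(r["forward"]),
                              reversal=tuple(r["reversal"]),
                              avd=tuple(r["avd"]), signal=tuple(r["signal"]))
    weights = NetworkWeights(np.asarray(raw["weights"]["gap"], dtype=float),
                             np.asarray(raw["weights"]["syn_mask"],
                                        dtype=bool))
    p = raw["params"]
    params = ModelParameters(syn=np.asarray(p["syn"], dtype=float),
                             bias=np.asarray(p["bias"], dtype=float),
                             beta=float(p["beta"]), tau=float(p["tau"]),
                             magnification=float(p["magnification"]))
    return params, weights, registry, raw.get("provenance", {})


def write_behavior_strip(path, seq) -> None:
    """Tab-separated behavior strip: t_start, t_end, state."""
    rows = [{"t_start": a, "t_end": b, "state": s}
            for s, a, b in seq.intervals()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_path_table(path, realization) -> None:
    """Tab-separated path vertices: t, x_mm, y_mm, state."""
    r = realization
    rows = [{"t": r.times[0], "x_mm": r.vertices[0, 0],
             "y_mm": r.vertices[0, 1], "state": "start"}]
    for k, s in enumerate(r.states):
        rows.append({"t": r.times[k + 1], "x_mm": r.vertices[k + 1, 0],
                     "y_mm": r.vertices[k + 1, 1], "state": s})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_provenance(path, command: str, arguments: dict) -> None:
    """Sidecar JSON recording how an output file was produced."""
    from . import __version__
    doc = {"command": command, "arguments": {k: str(v) for k, v in
                                             arguments.items()},
           "software_version": __version__}
    Path(path).write_text(json.dumps(doc, indent=2))
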