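"""Regression-based inference of synaptic weights and biases.

Rearranging the core ODE (with tau = 1 during fitting) so that everything
known sits on the left gives, per core neuron i and time sample t,

    dx_i/dt + 2 (x_i + 0.8)(x_i - 0.1)(x_i - 1)
        - beta * sum_j W_ij (x_j - x_i)
      = sum_j A_ij relu(x_j) + d_i

which is linear in the unknowns A_ij (restricted to the connectome support)
and d_i, and is solved by ordinary least squares per core neuron.  beta is
chosen by a grid sweep minimizing a hybrid of the regression error and the
reconstructed-derivative error; tau is calibrated afterwards by matching the
behavioral switching rate of simulations to that of the data.

The model-fitting surface follows the statsmodels idiom:
``ActivityRegression(traces, weights, registry, beta).fit()`` returns an
:class:`ActivityRegressionResults` with the estimates, per-neuron residual
diagnostics and a ``summary()`` table.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import behavior as behavior_mod
from . import dynamics
from .network import ModelParameters, NetworkWeights
from .registry import NeuronRegistry
from .simulate import SimulationConfig, integrate
from .traces import ActivityTraces

__all__ = [
    "DatasetCatalogEntry", "select_datasets", "pair_correlations",
    "data_replacement", "estimate_derivatives", "build_regression_system",
    "ActivityRegression", "ActivityRegressionResults", "FitResult",
    "fit_dataset", "sweep_beta", "average_parameters", "calibrate_tau",
]

logger = logging.getLogger(__name__)

HYBRID_WEIGHT = 0.05  # weight of the derivative error in the hybrid error


# ---------------------------------------------------------------------------
# dataset selection and data replacement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetCatalogEntry:
    """A dataset id together with the set of neuron names it labels."""

    dataset_id: str
    neurons: frozenset[str]

    def __init__(self, dataset_id: str, neurons) -> None:
        object.__setattr__(self, "dataset_id", dataset_id)
        object.__setattr__(self, "neurons", frozenset(neurons))


def _paired_forward_neurons(registry: NeuronRegistry) -> tuple[str, ...]:
    """Forward-cluster neurons belonging to left/right-paired classes
    (the selection rule keys on these; unpaired classes such as RID are
    too sparsely labeled to anchor a dataset)."""
    by_class: dict[str, list[str]] = {}
    for n in registry.forward:
        by_class.setdefault(registry.class_of(n), []).append(n)
    return tuple(n for members in by_class.values() if len(members) > 1
                 for n in members)


def select_datasets(catalog: list[DatasetCatalogEntry],
                    registry: NeuronRegistry) -> list[DatasetCatalogEntry]:
    """Keep datasets with enough labeled core neurons to anchor a fit.

    A dataset is kept when it labels (i) at least one paired forward-cluster
    neuron (AVBL/AVBR/RIBL/RIBR in the default registry), (ii) at least one
    member of every reversal class, and (iii) at least one AVD neuron when
    the registry has an AVD pair.
    """
    if not catalog:
        raise ValueError("empty dataset catalog")
    forward_any = set(_paired_forward_neurons(registry))
    reversal_classes = {registry.class_of(n) for n in registry.reversal}
    kept = []
    for entry in catalog:
        names = entry.neurons
        if forward_any and not (names & forward_any):
            continue
        if any(not (names & set(registry.members_of_class(c)) & set(registry.reversal))
               for c in reversal_classes):
            continue
        if registry.avd and not (names & set(registry.avd)):
            continue
        kept.append(entry)
    return kept


def pair_correlations(datasets: list[ActivityTraces],
                      registry: NeuronRegistry) -> pd.DataFrame:
    """Mean Pearson correlation of each left/right homolog pair across the
    datasets in which both members appear."""
    pairs: dict[str, list[str]] = {}
    for n in registry.names:
        pairs.setdefault(registry.class_of(n), []).append(n)
    rows = []
    for cls, members in pairs.items():
        if len(members) != 2:
            continue
        a, b = members
        corrs = []
        for ds in datasets:
            if a in ds and b in ds:
                ra, rb = ds.row(a), ds.row(b)
                if np.std(ra) > 0 and np.std(rb) > 0:
                    corrs.append(float(np.corrcoef(ra, rb)[0, 1]))
        if corrs:
            rows.append({"left": a, "right": b, "mean_corr": float(np.mean(corrs)),
                         "n_datasets": len(corrs)})
    return pd.DataFrame(rows, columns=["left", "right", "mean_corr", "n_datasets"])


def data_replacement(traces: ActivityTraces, pair_stats: pd.DataFrame,
                     registry: NeuronRegistry, threshold: float = 0.7
                     ) -> tuple[ActivityTraces, list[tuple[str, str]]]:
    """Substitute missing neurons with their highly correlated L/R partner.

    For each registry neuron absent from ``traces`` whose partner is present
    and whose pair mean correlation is at least ``threshold``, the partner's
    trace is copied in under the missing name.  Returns the augmented traces
    and the list of (missing, proxy) substitutions (also logged).
    """
    substitutions: list[tuple[str, str]] = []
    labels = list(traces.labels)
    values = [traces.values]
    for _, row in pair_stats.iterrows():
        if row["mean_corr"] < threshold:
            continue
        for missing, proxy in ((row["left"], row["right"]),
                               (row["right"], row["left"])):
            if missing in registry.names and missing not in traces \
                    and proxy in traces and missing not in labels:
                labels.append(missing)
                values.append(traces.row(proxy)[None, :])
                substitutions.append((missing, proxy))
                logger.info("data replacement: %s := %s", missing, proxy)
    if not substitutions:
        return traces, []
    out = ActivityTraces(tuple(labels), traces.times.copy(),
                         np.vstack(values))
    return out, substitutions


# ---------------------------------------------------------------------------
# derivatives and the regression system
# ---------------------------------------------------------------------------

def estimate_derivatives(traces: ActivityTraces, method: str = "central"
                         ) -> np.ndarray:
    """Per-sample time derivatives of every trace row.

    ``central``: second-order central differences in the interior, one-sided
    at the ends (exact for quadratics in the interior).  ``smoothed``: a
    Savitzky-Golay derivative filter (window 7, order 3) for noisy data.
    """
    if traces.n_samples < 3:
        raise ValueError("at least 3 samples are required for differentiation")
    if method == "central":
        return np.gradient(traces.values, traces.dt, axis=1, edge_order=2)
    if method == "smoothed":
        from scipy.signal import savgol_filter
        window = min(7, traces.n_samples if traces.n_samples % 2 else
                     traces.n_samples - 1)
        return savgol_filter(traces.values, window, polyorder=3, deriv=1,
                             delta=traces.dt, axis=1)
    raise ValueError(f"unknown derivative method {method!r}")


def build_regression_system(traces: ActivityTraces, dxdt: np.ndarray,
                            weights: NetworkWeights, beta: float,
                            registry: NeuronRegistry):
    """Per-core-neuron least-squares systems for the rearranged ODE.

    For each core neuron i present in ``traces`` this returns a dict entry
    ``name -> (design, response, predictor_names)`` where the response is the
    known left-hand side (derivative plus default intrinsic cubic minus the
    gap-junction input over *present* neurons, tau = 1) and the design holds
    one rectified-activity column per present presynaptic neuron on the
    support, plus a trailing intercept column for the bias.

    Core neurons without a trace are excluded (and logged); presynaptic
    neurons without a trace contribute no column and are inestimable here.
    """
    names = registry.names
    present = [n for n in names if n in traces]
    present_idx = {n: k for k, n in enumerate(present)}
    x = traces.matrix_for(present) if present else np.empty((0, traces.n_samples))
    relu = np.maximum(x, 0.0)
    systems = {}
    for i, name in enumerate(registry.core):
        if name not in traces:
            logger.info("core neuron %s missing from dataset; excluded", name)
            continue
        xi = traces.row(name)
        di = dxdt[traces.labels.index(name)]
        # gap input over present neurons
        w_row = weights.gap[i]
        gap = np.zeros_like(xi)
        for j, nj in enumerate(names):
            if w_row[j] != 0.0 and nj in present_idx:
                gap += w_row[j] * (x[present_idx[nj]] - xi)
        response = di - dynamics.intrinsic_dynamics(xi, 0.0) - beta * gap
        cols, col_names = [], []
        for j, nj in enumerate(names):
            if weights.syn_mask[i, j] and nj in present_idx:
                cols.append(relu[present_idx[nj]])
                col_names.append(nj)
        design = np.column_stack(cols + [np.ones_like(xi)]) if cols else \
            np.ones((xi.size, 1))
        systems[name] = (design, response, col_names)
    return systems


# ---------------------------------------------------------------------------
# per-dataset fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates and error components for one dataset fit.

    ``syn_hat`` is NaN where an entry was inestimable in this dataset (the
    presynaptic neuron was missing, or its rectified trace was identically
    zero); ``bias_hat`` is NaN for core neurons missing from the dataset.
    ``error_hybrid = error_regress + hybrid_weight * error_deriv`` exactly.
    """

    syn_hat: np.ndarray
    bias_hat: np.ndarray
    beta: float
    error_regress: float
    error_deriv: float
    error_hybrid: float
    hybrid_weight: float
    residual_table: pd.DataFrame


class ActivityRegression:
    """Least-squares model for the synaptic weights and biases of one dataset.

    Parameters
    ----------
    traces : ActivityTraces
        Core + signal activity (missing neurons are tolerated; see
        :func:`build_regression_system`).
    weights : NetworkWeights
        Connectome support (gap weights and synapse mask).
    registry : NeuronRegistry
        Neuron ordering, roles and classes.
    beta : float
        Gap-junction scale held fixed during the regression.
    derivatives : ndarray, optional
        Precomputed derivatives (same row order as ``traces``); by default
        central differences are used.  Supplying exact derivatives makes the
        noiseless recovery an algebraic identity.
    """

    def __init__(self, traces: ActivityTraces, weights: NetworkWeights,
                 registry: NeuronRegistry, beta: float = 10.0,
                 hybrid_weight: float = HYBRID_WEIGHT,
                 derivatives: np.ndarray | None = None,
                 derivative_method: str = "central") -> None:
        self.traces = traces
        self.weights = weights
        self.registry = registry
        self.beta = float(beta)
        self.hybrid_weight = float(hybrid_weight)
        if derivatives is None:
            derivatives = estimate_derivatives(traces, derivative_method)
        self.derivatives = np.asarray(derivatives, dtype=float)
        if self.derivatives.shape != traces.values.shape:
            raise ValueError("derivatives must match the trace matrix shape")

    def fit(self) -> "ActivityRegressionResults":
        reg, weights, traces = self.registry, self.weights, self.traces
        n_core, n_total = weights.n_core, weights.n_total
        syn_hat = np.full((n_core, n_total), np.nan)
        syn_hat[weights.syn_mask] = np.nan
        syn_hat[~weights.syn_mask] = 0.0
        bias_hat = np.full(n_core, np.nan)
        systems = build_regression_system(traces, self.derivatives, weights,
                                          self.beta, reg)
        rows = []
        sq_regress = 0.0
        name_to_col = {n: j for j, n in enumerate(reg.names)}
        for i, name in enumerate(reg.core):
            if name not in systems:
                rows.append({"neuron": name, "n_samples": 0, "n_predictors": 0,
                             "resid_norm": np.nan, "rank_deficient": False,
                             "fitted": False})
                continue
            design, response, col_names = systems[name]
            # drop identically-zero predictor columns (never-depolarized
            # presynaptic neurons): their coefficients are indeterminate
            keep = [k for k in range(len(col_names))
                    if np.any(design[:, k] != 0.0)]
            kept_names = [col_names[k] for k in keep]
            slim = np.column_stack([design[:, keep],
                                    design[:, -1]]) if keep else design[:, -1:]
            coef, _, rank, _ = np.linalg.lstsq(slim, response, rcond=None)
            rank_deficient = rank < slim.shape[1]
            if rank_deficient:
                logger.info("rank-deficient regression for %s "
                            "(minimum-norm solution)", name)
            resid = response - slim @ coef
            sq_regress += float(np.dot(resid, resid))
            for k, nj in enumerate(kept_names):
                syn_hat[i, name_to_col[nj]] = coef[k]
            bias_hat[i] = coef[-1]
            rows.append({"neuron": name, "n_samples": response.size,
                         "n_predictors": len(kept_names),
                         "resid_norm": float(np.linalg.norm(resid)),
                         "rank_deficient": bool(rank_deficient),
                         "fitted": True})
        error_regress = float(np.sqrt(sq_regress))
        error_deriv = self._derivative_error(syn_hat, bias_hat)
        fit = FitResult(
            syn_hat=syn_hat, bias_hat=bias_hat, beta=self.beta,
            error_regress=error_regress, error_deriv=error_deriv,
            error_hybrid=error_regress + self.hybrid_weight * error_deriv,
            hybrid_weight=self.hybrid_weight,
            residual_table=pd.DataFrame(rows))
        return ActivityRegressionResults(self, fit)

    def _derivative_error(self, syn_hat: np.ndarray,
                          bias_hat: np.ndarray) -> float:
        """Pooled L2 norm of (data derivative - reconstructed rate).

        The reconstruction evaluates the full core rate (tau = 1) on the
        observed traces with the fitted parameters; inestimable entries
        contribute zero drive.
        """
        reg, weights, traces = self.registry, self.weights, self.traces
        names = reg.names
        present = [n for n in names if n in traces]
        present_idx = {n: k for k, n in enumerate(present)}
        x = traces.matrix_for(present)
        relu = np.maximum(x, 0.0)
        sq = 0.0
        for i, name in enumerate(reg.core):
            if name not in traces or not np.isfinite(bias_hat[i]):
                continue
            xi = traces.row(name)
            di = self.derivatives[traces.labels.index(name)]
            rate = dynamics.intrinsic_dynamics(xi, bias_hat[i])
            w_row = weights.gap[i]
            for j, nj in enumerate(names):
                if w_row[j] != 0.0 and nj in present_idx:
                    rate = rate + self.beta * w_row[j] * (x[present_idx[nj]] - xi)
                a = syn_hat[i, j]
                if np.isfinite(a) and a != 0.0 and nj in present_idx:
                    rate = rate + a * relu[present_idx[nj]]
            sq += float(np.sum((di - rate) ** 2))
        return float(np.sqrt(sq))


class ActivityRegressionResults:
    """Results wrapper with estimates, diagnostics and a summary table."""

    def __init__(self, model: ActivityRegression, fit: FitResult) -> None:
        self.model = model
        self._fit = fit

    # statsmodels-style accessors
    @property
    def syn_hat(self) -> np.ndarray:
        return self._fit.syn_hat

    @property
    def bias_hat(self) -> np.ndarray:
        return self._fit.bias_hat

    @property
    def error_regress(self) -> float:
        return self._fit.error_regress

    @property
    def error_deriv(self) -> float:
        return self._fit.error_deriv

    @property
    def error_hybrid(self) -> float:
        return self._fit.error_hybrid

    @property
    def residual_table(self) -> pd.DataFrame:
        return self._fit.residual_table

    def as_fit_result(self) -> FitResult:
        return self._fit

    def summary(self) -> str:
        t = self._fit.residual_table
        lines = [
            "Activity regression results",
            "===========================",
            f"beta: {self._fit.beta:g}    hybrid weight: "
            f"{self._fit.hybrid_weight:g}",
            f"error_regress: {self._fit.error_regress:.6g}",
            f"error_deriv:   {self._fit.error_deriv:.6g}",
            f"error_hybrid:  {self._fit.error_hybrid:.6g}",
            "",
            t.to_string(index=False),
        ]
        return "\n".join(lines)


def fit_dataset(traces: ActivityTraces, weights: NetworkWeights,
                beta: float, registry: NeuronRegistry,
                derivatives: np.ndarray | None = None,
                hybrid_weight: float = HYBRID_WEIGHT) -> FitResult:
    """Ordinary least-squares fit of one dataset (functional form of
    :class:`ActivityRegression`)."""
    model = ActivityRegression(traces, weights, registry, beta=beta,
                               hybrid_weight=hybrid_weight,
                               derivatives=derivatives)
    return model.fit().as_fit_result()


# ---------------------------------------------------------------------------
# beta sweep, averaging, tau calibration
# ---------------------------------------------------------------------------

def sweep_beta(datasets: list[ActivityTraces], weights: NetworkWeights,
               registry: NeuronRegistry, beta_grid,
               derivatives: list[np.ndarray] | None = None,
               hybrid_weight: float = HYBRID_WEIGHT
               ) -> tuple[pd.DataFrame, float]:
    """Fit every dataset at every grid value of beta; return the error table
    and the grid value minimizing the mean hybrid error (ties toward the
    smaller beta)."""
    beta_grid = sorted(float(b) for b in beta_grid)
    if not beta_grid:
        raise ValueError("empty beta grid")
    rows = []
    for beta in beta_grid:
        er, ed, eh = [], [], []
        for k, ds in enumerate(datasets):
            d = derivatives[k] if derivatives is not None else None
            fit = fit_dataset(ds, weights, beta, registry, derivatives=d,
                              hybrid_weight=hybrid_weight)
            er.append(fit.error_regress)
            ed.append(fit.error_deriv)
            eh.append(fit.error_hybrid)
        rows.append({"beta": beta, "mean_error_regress": float(np.mean(er)),
                     "mean_error_deriv": float(np.mean(ed)),
                     "mean_error_hybrid": float(np.mean(eh))})
    table = pd.DataFrame(rows)
    best = float(table.loc[table["mean_error_hybrid"].idxmin(), "beta"])
    if (table["mean_error_hybrid"] == table["mean_error_hybrid"].min()).sum() > 1:
        logger.info("beta sweep tie broken toward smaller beta: %g", best)
    return table, best


def average_parameters(fits: list[FitResult], beta: float | None = None,
                       tau: float = 0.2, magnification: float = 1.4
                       ) -> ModelParameters:
    """Entrywise mean of the estimates over the fits in which each entry was
    estimable; entries estimable in no fit are zero (logged)."""
    if not fits:
        raise ValueError("at least one fit is required")
    import warnings as _warnings
    syn_stack = np.stack([f.syn_hat for f in fits])
    bias_stack = np.stack([f.bias_hat for f in fits])
    with _warnings.catch_warnings():
        # entries estimable in no fit are all-NaN slices, handled below
        _warnings.simplefilter("ignore", RuntimeWarning)
        syn = np.nanmean(syn_stack, axis=0)
        bias = np.nanmean(bias_stack, axis=0)
    never = ~np.isfinite(syn)
    if never.any():
        logger.info("%d synaptic entries estimable in no fit; set to 0",
                    int(never.sum()))
    syn[never] = 0.0
    nb = ~np.isfinite(bias)
    if nb.any():
        logger.info("%d bias entries estimable in no fit; set to 0",
                    int(nb.sum()))
    bias[nb] = 0.0
    return ModelParameters(syn=syn, bias=bias,
                           beta=beta if beta is not None else fits[0].beta,
                           tau=tau, magnification=magnification)


def switch_rate(seq: behavior_mod.BehaviorSequence) -> float:
    """Behavioral state transitions per minute of a classified strip."""
    n_switches = max(len(seq.runs()) - 1, 0)
    duration = seq.dt * seq.states.size
    if duration <= 0:
        raise ValueError("zero-duration behavior sequence")
    return n_switches / duration


def calibrate_tau(params: ModelParameters, weights: NetworkWeights,
                  registry: NeuronRegistry, datasets: list[ActivityTraces],
                  tau_grid, cfg: SimulationConfig | None = None,
                  threshold: float = behavior_mod.DEFAULT_THRESHOLD) -> float:
    """Choose tau so simulated core dynamics switch at the data's speed.

    For each candidate tau, each dataset's core response is simulated from
    its signal traces and classified; the candidate minimizing the mean
    absolute difference between simulated and observed switching rates
    (transitions per minute) is returned.
    """
    tau_grid = sorted(float(t) for t in tau_grid)
    if not tau_grid:
        raise ValueError("empty tau grid")
    cfg = cfg or SimulationConfig()

    def classify_rate(core_traces: ActivityTraces) -> float:
        sig = behavior_mod.cluster_averages(core_traces, registry)
        return switch_rate(behavior_mod.classify(sig, threshold=threshold))

    data_rates = []
    signal_sets = []
    for ds in datasets:
        core = ds.subset([n for n in registry.core if n in ds])
        data_rates.append(classify_rate(core))
        sig_names = [n for n in registry.signal if n in ds]
        signal_sets.append(ds.subset(sig_names))
    scores = []
    for tau in tau_grid:
        p = replace(params, syn=params.syn.copy(), bias=params.bias.copy(),
                    tau=tau)
        diffs = []
        for sig, rate in zip(signal_sets, data_rates):
            core = integrate(p, weights, sig, cfg, registry)
            diffs.append(abs(classify_rate(core) - rate))
        scores.append(float(np.mean(diffs)))
    return tau_grid[int(np.argmin(scores))]
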