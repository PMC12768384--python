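"""Dataset selection, data replacement, and the regression machinery."""
import numpy as np
import pandas as pd
import pytest

import premotornet as pn
from premotornet import fitting
from premotornet.fitting import DatasetCatalogEntry
from premotornet.traces import ActivityTraces

from conftest import full_exact_derivatives


# ---------------------------------------------------------------------------
# dataset selection
# ---------------------------------------------------------------------------

REG = pn.default_registry()


@pytest.mark.parametrize("names, kept", [
    ({"AVBL", "AVAL", "RIML", "AVEL", "AIBL", "AVDL"}, True),
    ({"RIBR", "AVAR", "RIMR", "AVER", "AIBR", "AVDR"}, True),
    # missing all of AVB/RIB
    ({"RID", "AVAL", "RIML", "AVEL", "AIBL", "AVDL"}, False),
    # missing the AIB reversal class
    ({"AVBL", "AVAL", "RIML", "AVEL", "AVDL"}, False),
    # missing AVD
    ({"AVBL", "AVAL", "RIML", "AVEL", "AIBL"}, False),
])
def test_dataset_selection_rule(names, kept):
    catalog = [DatasetCatalogEntry("d", names)]
    out = fitting.select_datasets(catalog, REG)
    assert bool(out) == kept


def test_selection_keeps_order_and_allows_empty_result():
    catalog = [DatasetCatalogEntry("a", {"AVBL"}),
               DatasetCatalogEntry("b", {"RID"})]
    assert fitting.select_datasets(catalog, REG) == []


# ---------------------------------------------------------------------------
# data replacement
# ---------------------------------------------------------------------------

def _traces(labels, n=40, seed=0):
    rng = np.random.default_rng(seed)
    return ActivityTraces(tuple(labels), 0.01 * np.arange(n),
                          rng.normal(size=(len(labels), n)))


def test_data_replacement_copies_partner_trace():
    reg = pn.default_registry()
    tr = _traces(["AVBR", "AVAL"])
    stats = pd.DataFrame([{"left": "AVBL", "right": "AVBR",
                           "mean_corr": 0.9}])
    out, subs = fitting.data_replacement(tr, stats, reg)
    assert subs == [("AVBL", "AVBR")]
    assert np.array_equal(out.row("AVBL"), tr.row("AVBR"))


def test_data_replacement_below_threshold_or_both_missing():
    reg = pn.default_registry()
    tr = _traces(["AVBR"])
    low = pd.DataFrame([{"left": "AVBL", "right": "AVBR", "mean_corr": 0.6}])
    out, subs = fitting.data_replacement(tr, low, reg)
    assert subs == [] and out.labels == tr.labels
    both_missing = pd.DataFrame([{"left": "AVAL", "right": "AVAR",
                                  "mean_corr": 0.95}])
    out, subs = fitting.data_replacement(tr, both_missing, reg)
    assert subs == []


def test_data_replacement_identity_when_complete():
    reg = pn.default_registry()
    tr = _traces(["AVBL", "AVBR"])
    stats = pd.DataFrame([{"left": "AVBL", "right": "AVBR",
                           "mean_corr": 0.99}])
    out, subs = fitting.data_replacement(tr, stats, reg)
    assert subs == [] and out is tr


def test_pair_correlations_averages_over_datasets():
    reg = pn.NeuronRegistry(signal=())
    t = 0.01 * np.arange(100)
    base = np.sin(2 * np.pi * t)
    d1 = ActivityTraces(("AVBL", "AVBR"), t, np.vstack([base, base]))
    d2 = ActivityTraces(("AVBL", "AVBR"), t, np.vstack([base, -base]))
    stats = fitting.pair_correlations([d1, d2], reg)
    row = stats[stats["left"] == "AVBL"].iloc[0]
    assert row["mean_corr"] == pytest.approx(0.0, abs=1e-12)
    assert row["n_datasets"] == 2


# ---------------------------------------------------------------------------
# derivative estimation
# ---------------------------------------------------------------------------

def test_derivatives_exact_for_polynomials():
    t = 0.05 * np.arange(30)
    linear = 2.0 * t
    quad = 3.0 * t ** 2
    tr = ActivityTraces(("lin", "quad"), t, np.vstack([linear, quad]))
    d = fitting.estimate_derivatives(tr)
    assert np.allclose(d[0], 2.0, atol=1e-10)
    assert np.allclose(d[1, 1:-1], 6.0 * t[1:-1], atol=1e-9)


def test_derivatives_of_constant_are_zero_and_short_input_rejected():
    t = 0.05 * np.arange(10)
    tr = ActivityTraces(("c",), t, np.full((1, 10), 3.3))
    assert np.allclose(fitting.estimate_derivatives(tr), 0.0)
    short = ActivityTraces(("c",), t[:2], np.zeros((1, 2)))
    with pytest.raises(ValueError, match="3 samples"):
        fitting.estimate_derivatives(short)


# ---------------------------------------------------------------------------
# regression system
# ---------------------------------------------------------------------------

def test_intercept_only_regression_recovers_mean_bias():
    # a core neuron with no synapses: least squares on the intercept column
    spec = pn.SyntheticSpec(n_core=2, n_signal=2, gap_density=0.0,
                            syn_density=0.0, trace_length=100, noise_sd=0.0,
                            tau=1.0, seed=4)
    ds = pn.generate_dataset(spec)
    fit = fitting.fit_dataset(ds.traces, ds.weights, beta=1.0,
                              registry=ds.registry,
                              derivatives=full_exact_derivatives(ds))
    assert np.allclose(fit.bias_hat, ds.params.bias, atol=1e-8)


def test_never_depolarized_presynaptic_column_is_indeterminate():
    reg = pn.NeuronRegistry(forward=("FD01L", "FD01R"), reversal=("RV01L",),
                            avd=(), signal=("SIG001",))
    gap = np.zeros((4, 4))
    mask = np.zeros((3, 4), dtype=bool)
    mask[0, 3] = True  # SIG001 -> FD01L
    w = pn.NetworkWeights(gap, mask)
    t = 0.01 * np.arange(50)
    vals = np.vstack([np.sin(t * 6) * 0.1, np.zeros_like(t),
                      np.zeros_like(t), -np.ones_like(t)])  # signal clamped < 0
    tr = ActivityTraces(tuple(reg.names), t, vals)
    fit = fitting.fit_dataset(tr, w, beta=1.0, registry=reg)
    assert np.isnan(fit.syn_hat[0, 3])
    assert np.isfinite(fit.bias_hat[0])


def test_row_permutation_invariance_of_least_squares(recovery_dataset):
    spec, ds = recovery_dataset
    d = full_exact_derivatives(ds)
    sub = ds.traces
    fit1 = fitting.fit_dataset(sub, ds.weights, spec.beta, ds.registry,
                               derivatives=d)
    # permuting time samples permutes regression rows only
    rng = np.random.default_rng(0)
    perm = rng.permutation(sub.n_samples)
    # rebuild a trace container with permuted samples on a uniform grid
    tr2 = ActivityTraces(sub.labels, sub.times, sub.values[:, perm])
    fit2 = fitting.fit_dataset(tr2, ds.weights, spec.beta, ds.registry,
                               derivatives=d[:, perm])
    m = ds.weights.syn_mask
    assert np.allclose(fit1.syn_hat[m], fit2.syn_hat[m], atol=1e-8,
                       equal_nan=True)


def test_hybrid_error_composition(recovery_dataset):
    spec, ds = recovery_dataset
    fit = fitting.fit_dataset(ds.traces, ds.weights, spec.beta, ds.registry)
    assert fit.error_hybrid == pytest.approx(
        fit.error_regress + 0.05 * fit.error_deriv, rel=1e-15)
    assert fit.error_regress >= 0 and fit.error_deriv >= 0


def test_error_components_example_weighting():
    # hybrid error combines the two components with weight 0.05
    from premotornet.fitting import HYBRID_WEIGHT
    assert 1.0 + HYBRID_WEIGHT * 2.0 == pytest.approx(1.1)


def test_estimation_error_decreases_with_trace_length():
    errs = []
    for n in (300, 1000, 3000):
        spec = pn.SyntheticSpec(n_core=3, n_signal=8, trace_length=n,
                                noise_sd=0.05, tau=1.0, seed=29)
        ds = pn.generate_dataset(spec)
        fit = fitting.fit_dataset(ds.traces, ds.weights, spec.beta,
                                  ds.registry)
        m = ds.weights.syn_mask & np.isfinite(fit.syn_hat)
        errs.append(float(np.mean(np.abs(fit.syn_hat[m] - ds.params.syn[m]))))
    assert errs[2] < errs[0]


def test_summary_reports_errors(recovery_dataset):
    spec, ds = recovery_dataset
    res = fitting.ActivityRegression(ds.traces, ds.weights, ds.registry,
                                     beta=spec.beta).fit()
    text = res.summary()
    assert "error_hybrid" in text
    assert all(name in text for name in ds.registry.core)


# ---------------------------------------------------------------------------
# averaging
# ---------------------------------------------------------------------------

def _fake_fit(syn, bias, beta=10.0):
    return fitting.FitResult(syn_hat=np.asarray(syn, float),
                             bias_hat=np.asarray(bias, float), beta=beta,
                             error_regress=0.0, error_deriv=0.0,
                             error_hybrid=0.0, hybrid_weight=0.05,
                             residual_table=pd.DataFrame())


def test_average_parameters_rules():
    a = _fake_fit([[1.0, np.nan]], [0.5])
    b = _fake_fit([[3.0, 4.0]], [1.5])
    params = fitting.average_parameters([a, b], tau=1.0, magnification=1.0)
    assert params.syn[0, 0] == 2.0          # plain mean
    assert params.syn[0, 1] == 4.0          # present in one fit only
    assert params.bias[0] == 1.0
    # identical fits -> identity
    params2 = fitting.average_parameters([a, a], tau=1.0, magnification=1.0)
    assert params2.syn[0, 0] == 1.0 and params2.syn[0, 1] == 0.0

    # order invariance up to floating point
    p_ab = fitting.average_parameters([a, b], tau=1.0, magnification=1.0)
    p_ba = fitting.average_parameters([b, a], tau=1.0, magnification=1.0)
    assert np.allclose(p_ab.syn, p_ba.syn, atol=1e-12)


def test_sweep_beta_table_shape_and_single_point(beta_dataset):
    spec, ds = beta_dataset
    d = [full_exact_derivatives(ds)]
    table, best = fitting.sweep_beta([ds.traces], ds.weights, ds.registry,
                                     [spec.beta], derivatives=d)
    assert len(table) == 1
    assert best == spec.beta
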