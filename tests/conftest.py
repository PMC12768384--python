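"""Shared fixtures: synthetic study-condition datasets, generated once per
session (they drive both the module tests and the acceptance suite)."""
from __future__ import annotations

import numpy as np
import pytest

import premotornet as pn


def full_exact_derivatives(ds: pn.SyntheticDataset) -> np.ndarray:
    """Exact derivatives for the full trace matrix (core rows exact from the
    model rate; signal rows are never used by the regression)."""
    n_sig = ds.registry.n_signal
    return np.vstack([ds.exact_derivatives,
                      np.zeros((n_sig, ds.traces.n_samples))])


@pytest.fixture(scope="session")
def recovery_dataset():
    """Noiseless identifiability conditions: 4 core, 12 signal neurons,
    2000 samples, generated at the regression's tau = 1 convention."""
    spec = pn.SyntheticSpec(n_core=4, n_signal=12, trace_length=2000,
                            noise_sd=0.0, tau=1.0, seed=3)
    return spec, pn.generate_dataset(spec)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Same network with 0.1 z-score observation noise and 5000 samples."""
    spec = pn.SyntheticSpec(n_core=4, n_signal=12, trace_length=5000,
                            noise_sd=0.1, tau=1.0, seed=11)
    return spec, pn.generate_dataset(spec)


@pytest.fixture(scope="session")
def beta_dataset():
    """Dataset generated with a non-default gap scale (beta = 5) for the
    sweep-recovery check."""
    spec = pn.SyntheticSpec(n_core=4, n_signal=12, trace_length=1200,
                            noise_sd=0.0, tau=1.0, beta=5.0, seed=21)
    return spec, pn.generate_dataset(spec)


@pytest.fixture(scope="session")
def switching_dataset():
    """A strongly driven network whose behavioral switching rate is
    sensitive to the timescale parameter (for tau calibration)."""
    spec = pn.SyntheticSpec(n_core=4, n_signal=12, trace_length=1500,
                            noise_sd=0.0, tau=0.2, seed=5,
                            syn_weight_scale=0.9, syn_density=0.5,
                            signal_timescale=0.25)
    return spec, pn.generate_dataset(spec)


@pytest.fixture(scope="session")
def small_default_dataset():
    """A short default-structure dataset (15 core, fewer signals) used by
    behavior/influence/CLI tests."""
    spec = pn.SyntheticSpec(n_core=15, n_signal=24, trace_length=600,
                            noise_sd=0.02, seed=2)
    return spec, pn.generate_dataset(spec)
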