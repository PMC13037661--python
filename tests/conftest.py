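"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from megdigits.preprocess import bandpass
from megdigits.source import (
    a_window_maps,
    activation_index,
    data_covariance,
    fit_lcmv,
    reconstruct,
)
from megdigits.synth import SimulationConfig, make_source_model, simulate_meg


@pytest.fixture(scope="session")
def small_model():
    """Sphere-forward model at desk scale (60 vertices, 32 channels)."""
    return make_source_model(n_vertices=60, n_channels=32, seed=1)


@pytest.fixture(scope="session")
def delta_dataset(small_model):
    """Simulated epochs, delta-band filtered, beamformed, with A maps.

    25 trials per task at the default SNR; reused by decoding and
    activation-map tests to keep the suite fast.
    """
    cfg = SimulationConfig(n_trials_per_task=25)
    epochs, truth = simulate_meg(small_model, cfg, seed=2)
    band = bandpass(epochs, 0.5, 4.0, name="delta")
    fit = fit_lcmv(small_model, data_covariance(band), reg=0.05)
    src = reconstruct(band, fit)
    amap = activation_index(fit, band)
    awin = a_window_maps(fit, band)
    return {
        "model": small_model,
        "config": cfg,
        "epochs": epochs,
        "truth": truth,
        "band": band,
        "fit": fit,
        "src": src,
        "amap": amap,
        "awin": awin,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
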