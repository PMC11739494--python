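import numpy as np
import pytest

from domtrace.pipeline import RunConfig, preprocess_spectra
from domtrace.simulate import SimulationConfig, generate_campaign, make_formula_library


@pytest.fixture(scope="session")
def library200():
    return make_formula_library(7, 200)


@pytest.fixture(scope="session")
def small_config():
    """A reduced campaign (one well, four years) for fast integration tests."""
    return SimulationConfig(
        n_formulas=300, wells=("well-1",), n_quarters=24,
        n_seepage_per_location=4, n_reference=6, n_noise_peaks=150)


@pytest.fixture(scope="session")
def small_campaign(small_config):
    samples, manifest, truth = generate_campaign(small_config, 3)
    return samples, manifest, truth


@pytest.fixture(scope="session")
def small_processed(small_config, small_campaign):
    samples, _, truth = small_campaign
    cfg = RunConfig(simulation=small_config, seed=3)
    processed, qc = preprocess_spectra([sp for _, sp, _ in samples], cfg)
    return processed, qc, truth


def noiseless_config(**overrides):
    """Campaign config with every stochastic perturbation switched off."""
    base = dict(
        n_formulas=120, wells=("well-1",), n_quarters=8,
        n_seepage_per_location=2, n_reference=3, n_blanks=1,
        intensity_cv=0.0, dropout=0.0, n_noise_peaks=0,
        cal_intercept_mean=0.0, cal_intercept_sd=0.0, cal_slope_sd=0.0,
        mz_jitter_ppm=0.0)
    base.update(overrides)
    return SimulationConfig(**base)
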