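"""Shared fixtures: one small synthetic universe, session-scoped."""

import pytest

from concare import SimulationConfig, generate_dataset, run_pipeline


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(n_patients=800, seed=20240123)


@pytest.fixture(scope="session")
def tables(config):
    return generate_dataset(config)


@pytest.fixture(scope="session")
def pipeline(tables):
    return run_pipeline(tables, fit_models=False)


@pytest.fixture(scope="session")
def cohort(pipeline):
    return pipeline.cohort


@pytest.fixture(scope="session")
def profiles(pipeline):
    return pipeline.profiles


@pytest.fixture(scope="session")
def outcomes_df(pipeline):
    return pipeline.outcomes


@pytest.fixture(scope="session")
def covariates(pipeline):
    return pipeline.covariates


@pytest.fixture(scope="session")
def medium_pipeline():
    """Larger universe for model-suite statistics (single generation)."""
    cfg = SimulationConfig(n_patients=6000, seed=4242)
    return run_pipeline(generate_dataset(cfg), fit_models=True)
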