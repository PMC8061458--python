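import warnings

import pytest

from methcompass.synthdata import (
    SimScenario,
    generate_metadata_records,
    generate_models,
    generate_raw_signals,
    generate_tissue_beta_panel,
)

# a desk-scale cohort: same structure as the shipped scenario, fewer probes
SMALL = dict(
    n_probes=2000,
    n_low_var_probes=25,
    n_tissue_specific_per_tissue=30,
    n_shared_high_probes=190,
    n_age_probes=120,
    n_sex_probes=60,
    n_cell_probes=120,
    n_x_probes=120,
    n_y_probes=100,
    samples_per_study=(8, 12),
)


@pytest.fixture(scope="session")
def small_scenario() -> SimScenario:
    return SimScenario(seed=11, **SMALL)


@pytest.fixture(scope="session")
def small_panel(small_scenario):
    return generate_tissue_beta_panel(small_scenario)


@pytest.fixture(scope="session")
def small_signals(small_scenario):
    return generate_raw_signals(small_scenario)


@pytest.fixture(scope="session")
def small_models(small_scenario):
    return generate_models(small_scenario)


@pytest.fixture(scope="session")
def small_corpus(small_scenario):
    return generate_metadata_records(small_scenario)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield
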