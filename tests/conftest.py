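import pytest

from featherid import SimulationConfig, generate_reference_db, simulate_survey


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_species=12, sister_pair_fraction=0.2, n_samples=60, seed=7)


@pytest.fixture(scope="session")
def small_db(small_config):
    return generate_reference_db(small_config)


@pytest.fixture(scope="session")
def small_survey(small_config, small_db):
    _, truth = small_db
    return simulate_survey(truth, small_config)
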