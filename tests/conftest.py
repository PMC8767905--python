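import pytest

from phenodrought import cohort as cm
from phenodrought.datasets import field_yield_table, pot_yield_table


@pytest.fixture(scope="session")
def field_table():
    return field_yield_table()


@pytest.fixture(scope="session")
def pot_table():
    return pot_yield_table()


@pytest.fixture(scope="session")
def default_config():
    return cm.CohortConfig(seed=11)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return cm.make_cohort(default_config)


@pytest.fixture(scope="session")
def default_trajectories(default_cohort, default_config):
    return cm.simulate_trajectories(default_cohort, default_config)


@pytest.fixture(scope="session")
def noiseless_config():
    return cm.CohortConfig(
        seed=5, noise_sd={"PSA": 0.0, "WU": 0.0, "TR": 0.0, "NIR": 0.0, "yield": 0.0}
    )


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config):
    return cm.make_cohort(noiseless_config)
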