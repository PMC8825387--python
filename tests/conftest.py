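import pytest

from rgms.chem import default_database
from rgms.simulate import SimulationConfig, build_filter_fixture, simulate_dataset


@pytest.fixture(scope="session")
def db():
    return default_database()


@pytest.fixture(scope="session")
def clean_dataset(db):
    """Seeded clean synthetic dataset: 20 planted RGs plus decoys."""
    return simulate_dataset(SimulationConfig(seed=11, n_rgs=20), db)


@pytest.fixture(scope="session")
def filter_fixture(db):
    return build_filter_fixture(db)
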