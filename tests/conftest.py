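import pytest

from flavorgrade import datasets, oav_table, simulate_grade_dataset
from flavorgrade.simulate import SimulationSpec


@pytest.fixture(scope="session")
def volatiles():
    return datasets.load_volatiles()


@pytest.fixture(scope="session")
def thresholds():
    return datasets.load_thresholds()


@pytest.fixture(scope="session")
def nonvolatiles():
    return datasets.load_nonvolatiles()


@pytest.fixture(scope="session")
def oavs(volatiles, thresholds):
    return oav_table(volatiles, thresholds)


@pytest.fixture(scope="session")
def sim_triplicates(volatiles):
    """Seeded synthetic triplicates drawn from the fixture means/SDs."""
    return simulate_grade_dataset(
        SimulationSpec(template=volatiles, n_reps=3, seed=1))
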