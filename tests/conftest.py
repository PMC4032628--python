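import pytest

from rarevar import CohortConfig, Thresholds, load_table1
from rarevar.conservation import build_functional_matrix
from rarevar.filters import burden_inclusion


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def cohort():
    return CohortConfig()


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def fixture_matrix(table1, cohort, thresholds):
    """Full-cohort functional matrix from the bundled variant table."""
    _, conservation_set = burden_inclusion(table1)
    return build_functional_matrix(conservation_set, cohort, thresholds)
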