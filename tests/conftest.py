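import pytest

from springlipids import SimulationConfig, simulate, add_index_columns
from springlipids.io import GEOCHEM_PREDICTORS

PREDICTORS = list(GEOCHEM_PREDICTORS)


@pytest.fixture(scope="session")
def survey300():
    """Default synthetic survey (n=300) with index columns appended."""
    return add_index_columns(simulate(SimulationConfig(n_samples=300, seed=0)))


@pytest.fixture(scope="session")
def ynp41():
    """Small YNP-like synthetic survey (n=41, seven geochemical predictors)."""
    return add_index_columns(simulate(SimulationConfig(n_samples=41, seed=7)))
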