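import numpy as np
import pytest

from crowdnn import fixtures
from crowdnn.thermo import GAS_CONSTANT


@pytest.fixture(scope="session")
def bundle():
    return fixtures.load_fixtures()


@pytest.fixture(scope="session")
def dataset(bundle):
    return fixtures.study_dataset(bundle)


@pytest.fixture(scope="session")
def crowding_params(bundle):
    return fixtures.crowding_parameter_set(bundle)


def ds_for_tm(dH: float, tm_celsius: float, ct: float) -> float:
    """Entropy that places the van't Hoff melting temperature at tm_celsius."""
    return dH / (tm_celsius + 273.15) - GAS_CONSTANT * np.log(ct)
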