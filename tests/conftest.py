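import numpy as np
import pytest

from phycoflux.experiments import default_grids
from phycoflux.synthetic_data import GroundTruth


@pytest.fixture(scope="session")
def truth() -> GroundTruth:
    return GroundTruth(seed=7)


@pytest.fixture(scope="session")
def grids() -> tuple[np.ndarray, np.ndarray]:
    return default_grids()


@pytest.fixture(scope="session")
def coarse_grids() -> tuple[np.ndarray, np.ndarray]:
    """Small instance grids for expensive cross-checks."""
    return np.arange(-30.0, 401.0, 10.0), np.arange(555.0, 761.0, 20.0)
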