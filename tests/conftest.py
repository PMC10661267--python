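import numpy as np
import pytest

from qmrifit import population_aif


@pytest.fixture(scope="session")
def frame_times():
    """Standard DCE frame grid: 661 frames at 0.5 s spacing."""
    return np.arange(661) * 0.5


@pytest.fixture(scope="session")
def pop_aif(frame_times):
    return population_aif(frame_times)


@pytest.fixture(scope="session")
def short_times():
    """Coarse grid for cheap forward-model tests."""
    return np.arange(0, 330, 2.0)


@pytest.fixture(scope="session")
def short_aif(short_times):
    return population_aif(short_times)
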