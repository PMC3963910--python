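import numpy as np
import pytest

from thermotactics import TimeGrid, build_basis, filter_by_moran


@pytest.fixture(scope="session")
def full_basis():
    """The study-scale basis: 450 hourly samples, 205 harmonics, Moran-filtered."""
    return filter_by_moran(build_basis(450, 205))


@pytest.fixture(scope="session")
def grid450():
    return TimeGrid(450)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
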