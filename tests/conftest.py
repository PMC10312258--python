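import numpy as np
import pytest

import tmapper as tm


@pytest.fixture(scope="session")
def toy_fixture():
    """Default toy hysteresis data set: (time series, truth network, symbols)."""
    return tm.generate_toy_hysteresis(seed=1)


@pytest.fixture(scope="session")
def toy_reconstruction(toy_fixture):
    """Temporal Mapper reconstruction of the toy fixture (k=16, delta=2)."""
    ts, truth, sym = toy_fixture
    return tm.run_temporal_mapper(ts, k=16, delta=2)


@pytest.fixture(scope="session")
def two_region_connectome():
    C = np.array([[0.0, 1.0], [1.0, 0.0]])
    return tm.normalize_connectome(C)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
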