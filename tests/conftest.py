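import numpy as np
import pytest

from genomecontext import synthetic


@pytest.fixture(scope="session")
def small_world():
    return synthetic.simulate_world(seed=1)


@pytest.fixture(scope="session")
def null_world():
    return synthetic.simulate_world(synthetic.PRESETS["null"], seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
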