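import numpy as np
import pytest

import spiralscan as ss


@pytest.fixture(scope="session")
def default_as():
    return ss.make_trajectory(ss.SpiralParams(pattern="AS"))


@pytest.fixture(scope="session")
def default_fs():
    return ss.make_trajectory(ss.SpiralParams(pattern="FS"))


@pytest.fixture(scope="session")
def default_afs():
    return ss.make_trajectory(ss.SpiralParams(pattern="AFS"))


@pytest.fixture(scope="session")
def tree_phantom():
    return ss.make_phantom(style="random_tree", size=512, seed=7)


@pytest.fixture(scope="session")
def parallel_phantom():
    return ss.make_phantom(style="parallel", size=256, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
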