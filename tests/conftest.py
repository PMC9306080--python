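import warnings

import numpy as np
import pytest

from ahiot.fingerprints import load_library

warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")


@pytest.fixture(scope="session")
def library():
    """The packaged substructure library, compiled once per session."""
    return load_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
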