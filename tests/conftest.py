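import numpy as np
import pytest

from stmalign import control as ct


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def smoke_runs():
    """Three seeded scaled-down training runs (6x6 grid, 40 epochs).

    Shared across the end-to-end tests; building them is the dominant cost
    of the suite, so they are computed once per session.
    """
    return [ct.train(ct.smoke_config(seed)) for seed in (1, 2, 3)]
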