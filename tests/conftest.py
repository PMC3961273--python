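import numpy as np
import pytest

from polynuc.params import default_params
from polynuc.saw import grow_nucleus


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def small_params():
    """Reduced arm counts for fast growth-path tests.

    The nucleus radius is re-derived from the volume-ratio pin, so the
    reduced model has the same packing density as the default one.
    """
    return default_params(
        arm_bead_counts={"X": 8, "2L": 9, "2R": 9, "3L": 9, "3R": 10}
    )


@pytest.fixture(scope="session")
def nucleus(params):
    """One deterministic default nucleus shared across tests."""
    return grow_nucleus(params, np.random.default_rng(12345))


@pytest.fixture(scope="session")
def small_nucleus(small_params):
    return grow_nucleus(small_params, np.random.default_rng(54321))
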