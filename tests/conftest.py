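import numpy as np
import pytest

from cloudshape import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def chair_cloud():
    """A representative labeled cloud (6 parts, 256 points)."""
    return synthetic.generate_object(synthetic.get_template("chair"), 5, 256)


@pytest.fixture(scope="session")
def small_cloud_set():
    """A few labeled clouds per scramble-pool category, 128 points each."""
    return synthetic.generate_clouds(synthetic.SCRAMBLE_CATEGORIES, 2,
                                     seed=3, n_points=128)
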