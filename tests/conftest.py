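import numpy as np
import pytest

from glianet import make_preset, generate_cohort


@pytest.fixture(scope="session")
def dense_core_cohort():
    """Small seeded human dense-core cohort shared across tests."""
    return generate_cohort(make_preset("human-dense-core"), 30, seed=101)


@pytest.fixture(scope="session")
def mouse_mid_cohort():
    return generate_cohort(make_preset("mouse-mid"), 50, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
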