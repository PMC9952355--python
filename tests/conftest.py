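import numpy as np
import pytest

from r2cascade import (
    NoiseSpec,
    ParameterMaps,
    PhantomSpec,
    default_te_schedule,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def te12():
    """The 12-echo clinical schedule (0.93 + 1.34 k ms)."""
    return default_te_schedule()


@pytest.fixture(scope="session")
def small_dataset():
    """One 64x128 simulated subject at sigma_g = 9."""
    return simulate_dataset(PhantomSpec(seed=7), noise=NoiseSpec(9.0, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
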