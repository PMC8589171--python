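import numpy as np
import pytest

from protopolicy import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (N=1000) for estimator tests."""
    return generate_cohort(SyntheticConfig(patients_per_prototype=200, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
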