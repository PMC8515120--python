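import numpy as np
import pytest

from gutmet.synth import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-subject default-condition cohort shared by read-only tests."""
    return generate_cohort(SynthConfig(n_subjects=60, seed=7))


@pytest.fixture(scope="session")
def medium_cohort():
    """A 200-subject default-condition cohort shared by read-only tests."""
    return generate_cohort(SynthConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
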