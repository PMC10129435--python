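import numpy as np
import pytest

from gaitsynergy import CohortSpec, default_walking_model

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def walking_model():
    """Noiseless four-synergy, five-muscle ground truth."""
    return default_walking_model(seed=11, noise_sigma=0.0)


@pytest.fixture(scope="session")
def noisy_model():
    return default_walking_model(seed=11, noise_sigma=0.1)


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_subjects=2, n_cycles_per_subject=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
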