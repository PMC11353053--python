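import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crtnn.preprocessing import LabelScheme, preprocess_subject
from crtnn.synthetic import deap_spec, seed_spec, simulate_deap_like, simulate_seed_like

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def deap_study():
    """Small DEAP-like study: 2 subjects x 8 trials, default spectral model."""
    return simulate_deap_like(deap_spec(n_subjects=2, n_trials=8, seed=11))


@pytest.fixture(scope="session")
def seed_study():
    """SEED-like study: 1 subject x 15 clips, 20 s stimulus for speed."""
    return simulate_seed_like(seed_spec(n_subjects=1, stimulus_seconds=21.0, seed=11))


@pytest.fixture(scope="session")
def deap_segments(deap_study):
    """Preprocessed samples of the first DEAP-like subject (binary arousal)."""
    return preprocess_subject(deap_study[0], LabelScheme(2, "arousal"))
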