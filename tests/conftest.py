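import numpy as np
import pytest

from tnjmodel import SynthSpec, fixture_small, generate_dataset, generate_model_targets


@pytest.fixture(scope="session")
def small_trials():
    """Deterministic 4-participant table exercising every exclusion path."""
    return fixture_small()


@pytest.fixture(scope="session")
def clean_study_trials():
    """Small all-attentive synthetic study: 5 bands x 6 participants."""
    spec = SynthSpec(
        participants_per_band=6,
        inattentive_fraction=0.0,
        catch_correct_prob=1.0,
        seed=42,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def oracle_targets():
    """Noise-free design-grid targets from known parameters (0.6, 300 ms)."""
    return generate_model_targets(0.6, 300.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
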