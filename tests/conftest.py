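import numpy as np
import pytest

from earkit import synthetic_data as sd


@pytest.fixture(scope="session")
def model_zero_noise():
    """Planted model with no assay noise (deterministic fluorescence)."""
    return sd.generate_ground_truth(
        3, 3, effect_size=0.3, tech_noise_sd=0.0, bio_noise_sd=0.0, seed=11
    )


@pytest.fixture(scope="session")
def model_low_noise():
    return sd.generate_ground_truth(
        5, 5, effect_size=0.3, tech_noise_sd=0.05, bio_noise_sd=0.05, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
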