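import numpy as np
import pytest
from hypothesis import settings

from diadino.dynamics import CommunityParams, simulate_batch
from diadino.synthetic import (
    NoiseConfig,
    default_ground_truth,
    observe,
    simulate_latent,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def latent(truth):
    """Noise-free latent dynamics for the full factorial design."""
    return simulate_latent(truth)


@pytest.fixture(scope="session")
def noiseless_experiment(truth, latent):
    """One-replicate noiseless observation of the latent experiment."""
    return observe(latent, truth, NoiseConfig(), seed=0, replicates=1, noiseless=True)


@pytest.fixture(scope="session")
def noisy_experiment(truth, latent):
    """Default-noise triplicate observation of the latent experiment."""
    return observe(latent, truth, NoiseConfig(), seed=11)


@pytest.fixture()
def logistic_params():
    return CommunityParams(
        r_diatom=0.6, r_dino=0.4, K_diatom=100.0, K_dino=40.0, alpha=0.0, beta=0.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def mono_batch(logistic_params):
    return simulate_batch(logistic_params, 1.0, 0.0, 25)
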