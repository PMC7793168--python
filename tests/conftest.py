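import numpy as np
import pytest

from emres import geometry, forward, noise


@pytest.fixture(scope="session")
def small_space():
    return geometry.build_sphere_source_space(300, radius=0.08, bumpiness=0.1, seed=2)


@pytest.fixture(scope="session")
def small_parcellation(small_space):
    return geometry.parcellate(small_space, 30, seed=2)


@pytest.fixture(scope="session")
def small_sensors():
    return forward.build_helmet_array(48, radius=0.12, modality="mag", seed=2)


@pytest.fixture(scope="session")
def small_gain(small_space, small_sensors):
    return forward.build_gain(small_space, small_sensors)


@pytest.fixture(scope="session")
def noise_pools(small_gain):
    model = noise.default_noise_model(small_gain.n_sensors, scale=1e-13, seed=4)
    epochs = noise.simulate_epochs(model, n_epochs=60, duration=0.5, seed=4)
    evoked_pool, cov_pool = noise.split_epochs(epochs, n_evoked=20, seed=4)
    return evoked_pool, cov_pool


@pytest.fixture(scope="session")
def small_cov(noise_pools):
    return noise.estimate_covariance(noise_pools[1])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
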