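import numpy as np
import pytest

from vampens.synthetic_data import default_fixture, generate_hmm_dataset
from vampens.vampnet import TrainConfig, train_ensemble

# Small networks and datasets keep the suite fast; the synthetic fixture is
# separable enough that these sizes recover the ground truth comfortably.
SMALL_TRAIN_CONFIG = TrainConfig(
    hidden=(32,), batch_size=4096, max_epochs=40, patience=5, learning_rate=5e-3
)

FIXTURE_LAG = 5  # saved-frame steps


@pytest.fixture(scope="session")
def fixture_spec():
    return default_fixture(n_trajectories=4, frames_per_trajectory=5000, seed=123)


@pytest.fixture(scope="session")
def fixture_data(fixture_spec):
    return generate_hmm_dataset(fixture_spec)


@pytest.fixture(scope="session")
def fixture_dataset(fixture_data):
    return fixture_data[0]


@pytest.fixture(scope="session")
def fixture_truth(fixture_data):
    return fixture_data[1]


@pytest.fixture(scope="session")
def trained_ensemble(fixture_dataset):
    """A 3-model ensemble trained on the canonical synthetic fixture."""
    return train_ensemble(
        fixture_dataset, 3, FIXTURE_LAG, n_models=3, inits_per_split=1,
        config=SMALL_TRAIN_CONFIG, seed=2024,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
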