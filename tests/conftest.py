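import numpy as np
import pytest

from premacc.config import GenerativeParams, TaskConfig
from premacc.synthetic import generate_dataset


@pytest.fixture(scope="session")
def config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """60-trial gratings dataset with EEG, shared across analysis tests."""
    return generate_dataset(
        TaskConfig(), GenerativeParams(), n_trials=60, seed=123, task="gratings"
    )


@pytest.fixture(scope="session")
def small_preprocessed(small_dataset):
    from premacc.pipeline import preprocess_dataset

    stim, resp, report = preprocess_dataset(small_dataset)
    return stim, resp, report


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
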