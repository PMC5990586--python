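import numpy as np
import pandas as pd
import pytest

from cogreg.simulate import ScenarioConfig, generate_dataset
from cogreg.task import IGTDataset, build_traditional_schedule


@pytest.fixture(scope="session")
def schedule():
    return build_traditional_schedule(200)


@pytest.fixture(scope="session")
def tiny_dataset():
    """6 participants x 30 trials of synthetic IGT play, with covariates."""
    cfg = ScenarioConfig(n_participants=6, n_trials=30, rho=0.5, base_seed=4)
    dataset, covariates, truth = generate_dataset(cfg, 0)
    return dataset, covariates, truth


@pytest.fixture(scope="session")
def small_dataset():
    """30 participants x 60 trials under the default generating values."""
    cfg = ScenarioConfig(n_participants=30, n_trials=60, rho=0.0, base_seed=9)
    dataset, covariates, truth = generate_dataset(cfg, 0)
    return dataset, covariates, truth


@pytest.fixture()
def two_participant_trials():
    """Hand-written 2-participant, 3-trial fixture."""
    return IGTDataset(pd.DataFrame({
        "participant": [1, 1, 1, 2, 2, 2],
        "trial": [1, 2, 3, 1, 2, 3],
        "choice": [1, 3, 2, 4, 4, 1],
        "win": [100, 50, 100, 50, 50, 100],
        "loss": [0, -50, 0, 0, -250, -150],
    }))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
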