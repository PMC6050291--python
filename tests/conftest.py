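import numpy as np
import pytest

from switchkin.config import GeneratorConfig
from switchkin.model import HMMModel, table_model
from switchkin.synthetic import simulate_dataset


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def four_state_model(default_config):
    return table_model(default_config)


@pytest.fixture(scope="session")
def default_dataset(default_config, four_state_model):
    """94 lineages x 69 frames from the calibrated four-state model."""
    return simulate_dataset(default_config, four_state_model, seed=101)


@pytest.fixture()
def single_state_model():
    return HMMModel(
        means=np.array([[5.2, 0.0]]),
        transmat=np.array([[1.0]]),
        startprob=np.array([1.0]),
    )


def match_states(fitted_means, true_means):
    """Greedy-free optimal assignment of fitted states to true states by
    emission-mean distance (Hungarian)."""
    from scipy.optimize import linear_sum_assignment

    fitted_means = np.asarray(fitted_means)
    true_means = np.asarray(true_means)
    cost = np.linalg.norm(
        fitted_means[:, None, :] - true_means[None, :, :], axis=2
    )
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(cols), dtype=int)
    perm[cols] = rows
    return perm  # perm[true_index] = fitted_index
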