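import numpy as np
import pytest

import poismrf as pm


@pytest.fixture(scope="session")
def sharp_truth():
    return pm.generate_disk_phantom()


@pytest.fixture(scope="session")
def system_matrix(sharp_truth):
    return pm.build_system_matrix(sharp_truth.n_rows, sharp_truth.n_cols, 1.2)


@pytest.fixture(scope="session")
def graph(sharp_truth):
    return pm.build_neighborhood(sharp_truth.n_rows, sharp_truth.n_cols)


@pytest.fixture(scope="session")
def low_count_obs(sharp_truth, system_matrix):
    """Reduced scanning-time observation of the sharp phantom."""
    return pm.simulate_observation(
        sharp_truth, system_matrix, pm.NoiseConfig(exposure=0.25, seed=12)
    )


@pytest.fixture(scope="session")
def small_problem():
    """A 6x9 toy restoration problem for exactness checks."""
    rng = np.random.default_rng(7)
    truth = pm.ImageGrid(rng.uniform(0, 50, size=(6, 9)), kind="truth")
    A = pm.build_system_matrix(6, 9, 0.8)
    G = pm.build_neighborhood(6, 9)
    obs = pm.simulate_observation(truth, A, pm.NoiseConfig(seed=3))
    return truth, obs, A, G
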