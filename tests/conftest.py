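import numpy as np
import pytest

import envgblup as eg


@pytest.fixture(scope="session")
def small_dataset():
    """30 lines x 100 markers x 5 environments sparse bundle with truth."""
    cfg = eg.SimulationConfig(n_lines=30, n_markers=100, n_envs=5, seed=1)
    return eg.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_grm(small_dataset):
    X = eg.impute_and_standardize(small_dataset.genotypes)
    return eg.compute_grm(X, small_dataset.genotypes.line_ids)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
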