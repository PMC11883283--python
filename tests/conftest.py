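import numpy as np
import pytest

import heartregen as hr


@pytest.fixture(scope="session")
def small_experiment():
    """A 300-gene simulated count experiment with planted truth."""
    cfg = hr.SimulationConfig(seed=101, n_genes=300)
    exp, truth = hr.simulate_count_experiment(cfg)
    return exp, truth


@pytest.fixture(scope="session")
def null_experiment():
    """2,000 genes, no planted effects: every sample i.i.d. NB."""
    cfg = hr.SimulationConfig(seed=11, n_genes=2000, frac_responsive=0.0, dispersion=0.1)
    exp, _ = hr.simulate_count_experiment(cfg)
    return exp


@pytest.fixture(scope="session")
def image_set():
    return hr.simulate_image_pair(hr.SimulationConfig(seed=2))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
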