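import numpy as np
import pytest

from pupilnum.stimgen import GeometryConfig, generate_condition_set


@pytest.fixture(scope="session")
def exp1_config():
    return GeometryConfig.for_experiment(1)


@pytest.fixture(scope="session")
def exp2_config():
    return GeometryConfig.for_experiment(2)


@pytest.fixture(scope="session")
def exp1_set(exp1_config):
    """One matched four-cell stimulus set for experiment 1 (shared, seeded)."""
    return generate_condition_set(exp1_config, rng_seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
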