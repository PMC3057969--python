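import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pointkin as pk

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_config():
    """Reduced experiment: 5 participants, 10 reps per target and condition."""
    return pk.GeneratorConfig(
        n_participants=5,
        reps_per_target_per_condition=10,
        blocks_per_condition=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_trials(small_config):
    return [trial for trial, _ in pk.generate_trials(small_config)]


@pytest.fixture(scope="session")
def small_analysis(small_trials):
    config = pk.RunConfig(n_permutations=300, rng_seed=4)
    tables, report = pk.analyze_trials(small_trials, config)
    return tables, report, config
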