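import numpy as np
import pytest

from hcsurrogacy import TrialGeneratorConfig, generate_markov_trial, generate_trial

# Configuration for the conditional-independence (Markov) scenarios: the
# generator's Markov property concerns the endpoint-free surrogate process, so
# the exact T _||_ Z | S statement requires the full visit schedule in the
# conditioning set and no endpoint->surrogate feedback (beta_j = 0).
MARKOV_TEST_CONFIG = dict(
    n_control=100,
    n_treatment=100,
    endpoint_effects=(0.0, 0.0, 0.0, 0.0, 0.0),
)


@pytest.fixture(scope="session")
def markov_trial():
    return generate_markov_trial(TrialGeneratorConfig(**MARKOV_TEST_CONFIG))


@pytest.fixture(scope="session")
def direct_trial():
    """Same conditions but with the direct (unmediated) treatment effect on T."""
    return generate_trial(TrialGeneratorConfig(**MARKOV_TEST_CONFIG))


@pytest.fixture(scope="session")
def nct_like_trial():
    """The default, fully calibrated two-arm trial (104 + 99 subjects)."""
    return generate_trial(TrialGeneratorConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(20220131)
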