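import numpy as np
import pytest

from tokensim.task import TaskConfig, TokenTrial


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def config():
    return TaskConfig()


def make_trial(directions, trial_type="random", condition="all_stay"):
    """Trial with an explicit jump sequence (15 entries of ±1)."""
    return TokenTrial(tuple(directions), trial_type, condition, "right")


@pytest.fixture
def bias_for_trial():
    # deterministic tail: 7 of 9 toward the correct target
    return make_trial(
        [1, 1, 1, -1, -1, -1, 1, 1, 1, -1, 1, 1, -1, 1, 1], "bias_for"
    )


@pytest.fixture
def bias_against_trial():
    return make_trial(
        [-1, -1, -1, 1, 1, 1, 1, 1, 1, -1, 1, 1, -1, 1, 1], "bias_against"
    )
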