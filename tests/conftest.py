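import numpy as np
import pytest

from futurestate import (SimTruth, generate_design, simulate_behavior,
                         simulate_patterns)
from futurestate.pipeline import PipelineConfig, run_participant


@pytest.fixture(scope="session")
def design():
    return generate_design(seed=7)


@pytest.fixture(scope="session")
def behavior(design):
    return simulate_behavior(design, seed=7)


@pytest.fixture(scope="session")
def truth():
    return SimTruth.default(seed=7)


@pytest.fixture(scope="session")
def pattern_sets(design, behavior, truth):
    return simulate_patterns(design, behavior, truth)


@pytest.fixture(scope="session")
def participant_result():
    """One fully analyzed synthetic participant (signal world)."""
    return run_participant(PipelineConfig(seed=11), 0)


@pytest.fixture(scope="session")
def noiseless_truth():
    return SimTruth.default(seed=7, noise_sd=0.0)


def rng(seed=0):
    return np.random.default_rng(seed)
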