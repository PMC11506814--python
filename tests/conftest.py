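import numpy as np
import pytest

from vplearn.observers import StudyConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A scaled-down simulated study shared by IO/pipeline/analysis tests:
    3 participants, 150-trial blocks, no between-participant jitter."""
    config = StudyConfig(
        n_participants=3, trials_per_block=150, jitter_sd=0.0, master_seed=42
    )
    return simulate_study(config)
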