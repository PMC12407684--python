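import numpy as np
import pytest

from popdecode import synth


@pytest.fixture(scope="session")
def task_config():
    return synth.TaskConfig()


@pytest.fixture(scope="session")
def small_metadata(task_config):
    """~180 trials: 2 sessions x 3 small blocks."""
    cfg = synth.TaskConfig(n_blocks=3, trials_per_block=(25, 35), n_sessions=2)
    return synth.generate_metadata(cfg, seed=11)


@pytest.fixture(scope="session")
def small_meta_frame(small_metadata):
    return synth.metadata_frame(small_metadata)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
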