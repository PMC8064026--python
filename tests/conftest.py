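import numpy as np
import pytest

from handeye import PipelineConfig, TrialGenConfig, generate_trial


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_trial():
    """One deterministic noise-free, gap-free trial plus its truth."""
    cfg = TrialGenConfig(seed=7, coupling_noise_sd=0.0, gaze_gap_prob=0.0)
    return generate_trial(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
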