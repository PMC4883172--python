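import numpy as np
import pytest

from spikedet import PipelineConfig, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 10-minute synthetic recording with all three event kinds."""
    cfg = SyntheticConfig(
        duration=600.0,
        n_spikes=15,
        n_distractors=10,
        n_sharp_transients=20,
        seed=5,
    )
    return generate_dataset(cfg)


@pytest.fixture()
def pipeline_config():
    cfg = PipelineConfig()
    cfg.evaluation.folds = 5
    return cfg
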