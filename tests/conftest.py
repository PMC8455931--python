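import numpy as np
import pytest

from emotqwt.preprocess import preprocess_recording, ratings_to_classes
from emotqwt.synth import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """One small synthetic subject (8 channels, 8 s trials) plus labels;
    shared by pipeline-level tests to keep the suite fast."""
    cfg = SynthConfig(n_subjects=1, n_channels=8, duration=8.0,
                      effect_size=0.5, seed=7)
    recordings, ratings = generate_cohort(cfg)
    rec = preprocess_recording(recordings[0])
    y = ratings_to_classes(ratings[0])
    return rec, ratings[0], y
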