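import numpy as np
import pytest

from hypnostats import GeneratorConfig, generate_recording, hyperparameter_table


@pytest.fixture(scope="session")
def small_recording():
    """One short surrogate recording shared by read-only tests."""
    cfg = GeneratorConfig(n_epochs=60, seed=42, artifact_rate=0.05)
    recording, hypnogram, truth = generate_recording(cfg)
    return cfg, recording, hypnogram, truth


@pytest.fixture(scope="session")
def small_table(small_recording):
    cfg, recording, hypnogram, _ = small_recording
    return hyperparameter_table(recording, hypnogram)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
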