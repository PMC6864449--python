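import numpy as np
import pytest

from pcglearn import ClassLabel, SynthConfig, generate_recordings


@pytest.fixture(scope="session")
def small_synth_config() -> SynthConfig:
    """A small, fast synthetic dataset: 8 recordings per class, 3-8 s."""
    return SynthConfig(
        duration_range_s=(3.0, 8.0),
        n_per_class={lab: 8 for lab in ClassLabel},
        seed=123,
    )


@pytest.fixture(scope="session")
def small_recordings(small_synth_config):
    return generate_recordings(small_synth_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(99)
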