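import numpy as np
import pytest

from colourpref.synthetic import default_config, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """30 synthetic participants, fixed seed; shared across read-only tests."""
    return generate_dataset(default_config(n_participants=30), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
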