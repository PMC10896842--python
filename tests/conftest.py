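import numpy as np
import pytest

from sostim.synthetic import SyntheticCDSpec, gen_cd_dataset


@pytest.fixture(scope="session")
def default_cd_dataset():
    """Labelled CD dataset at the default study conditions (3 SD effect,
    150 global / 300 non-global, dt = 20 ms)."""
    return gen_cd_dataset(SyntheticCDSpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
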