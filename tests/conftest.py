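import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom_dataset(tmp_path):
    """Small phantom PNG dataset on disk; returns its root directory."""
    from lesionseg.phantom import PhantomSpec, generate_dataset

    spec = PhantomSpec(size=32, seed=7)
    generate_dataset(6, spec, tmp_path / "data")
    return tmp_path / "data"
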