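import numpy as np
import pytest

from p300wave import SyntheticConfig, extract_epochs, generate_session


@pytest.fixture(scope="session")
def tiny_session():
    """Three-letter synthetic session with a strong P300 (fast to build)."""
    cfg = SyntheticConfig(n_letters=3, seed=11)
    return cfg, generate_session(cfg)


@pytest.fixture(scope="session")
def tiny_epochs(tiny_session):
    _cfg, rec = tiny_session
    return extract_epochs(rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
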