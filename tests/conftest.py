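import numpy as np
import pytest

from socimotor.synthetic_dyad import DyadConfig, simulate_session


@pytest.fixture(scope="session")
def short_session():
    """One 200-s synthetic dyadic session with moderate coupling."""
    cfg = DyadConfig(duration_s=200.0, seed=42, c_cl_to_ch=0.5,
                     c_ch_to_cl=0.1, child_jitter=0.3)
    manifest, streams, truth = simulate_session(cfg)
    return cfg, manifest, streams, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
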