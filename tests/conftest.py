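import numpy as np
import pytest

from ca1nac import synthetic


@pytest.fixture(scope="session")
def recovery_session():
    """A 20-min, 50-PYR session with 5 embedded assemblies (6 members,
    participation 0.8, 1 event/s) — the standard recovery benchmark."""
    members = [tuple(range(6 * k, 6 * k + 6)) for k in range(5)]
    cfg = synthetic.SessionConfig(
        duration=1200.0,
        n_pyr=50,
        assembly_spec=[(m, 1.0, 0.8) for m in members],
        seed=7,
    )
    return cfg, synthetic.generate_session(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
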