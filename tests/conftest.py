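import numpy as np
import pytest

from tumblecm import GammaTumbleDist, SimConfig, simulate_ensemble


@pytest.fixture(scope="session")
def ecoli_dist():
    """Truncated-gamma tumble-angle law with the inferred E. coli parameters."""
    return GammaTumbleDist(sigma=0.64, k=2.73)


@pytest.fixture(scope="session")
def small_ensemble(ecoli_dist):
    """A modest labeled ensemble at standard conditions, shared across tests."""
    cfg = SimConfig(
        lambda0=0.39,
        tumble_dist=ecoli_dist,
        seed=1234,
        d_rot=0.06,
        n_tracks=50,
        duration=10.0,
    )
    return simulate_ensemble(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
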