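import numpy as np
import pytest

from mp3rage import MonteCarloConfig, PhantomSpec, mp3rage_7t_protocol
from mp3rage.phantom import synth_subjects


@pytest.fixture(scope="session")
def protocol():
    return mp3rage_7t_protocol()


@pytest.fixture(scope="session")
def posterior_cache():
    """Shared Monte-Carlo posterior tables across tests (keyed by config)."""
    return {}


@pytest.fixture(scope="session")
def mc_cfg():
    return MonteCarloConfig(n_trials=1_000_000, noise_sigma=0.005, seed=11)


@pytest.fixture(scope="session")
def phantom_subjects(mc_cfg, posterior_cache):
    """Four synthetic subjects with MAP maps, shared across the suite."""
    spec = PhantomSpec(seed=11)
    return spec, synth_subjects(spec, 4, mc_cfg=mc_cfg, posterior_cache=posterior_cache)
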