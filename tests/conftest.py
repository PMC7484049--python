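import numpy as np
import pytest

import rrochaos as rc

SEED = 1


def grid(lo, hi, step):
    return np.round(np.arange(lo, hi + step / 2, step), 10)


@pytest.fixture(scope="session")
def cfg():
    return rc.SimulationConfig(seed=SEED)


@pytest.fixture(scope="session")
def asweep_coarse(cfg):
    """A-sweep at K=0, alpha=0, grid step 0.1 (the landmark protocol)."""
    return rc.run_A_sweep(grid(5.0, 15.0, 0.1), cfg)


@pytest.fixture(scope="session")
def resonance_98(cfg):
    """Ensemble K profile at A=9.8, alpha=0.15, p=32, K step 0.01, 10 trials."""
    return rc.run_resonance(9.8, grid(0.0, 0.3, 0.01), [0.15], [32], cfg)[(0.15, 32)]


@pytest.fixture(scope="session")
def resonance_120(cfg):
    """Ensemble K profile at A=12.0, alpha=0.15, p=32, K step 0.01, 10 trials."""
    return rc.run_resonance(12.0, grid(0.0, 0.9, 0.01), [0.15], [32], cfg)[(0.15, 32)]


@pytest.fixture(scope="session")
def forced_98(cfg):
    """Drive-amplitude sweep at A=9.8, K=0, p=32, reference correlation 0.3."""
    return rc.run_forced(9.8, grid(0.0, 0.5, 0.01), 32, 0.3, cfg)
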