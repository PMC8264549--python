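import numpy as np
import pytest

from antforage import SimulationConfig, build_tmaze


@pytest.fixture
def arena():
    """Fresh default 40x40 T-maze."""
    return build_tmaze()


@pytest.fixture
def open_arena():
    """Fully walkable 40x40 grid (no walls) for diffusion checks."""
    a = build_tmaze()
    a.walkable[:] = True
    a._nbr_flat = None  # invalidate cached neighbourhood tables
    return a


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def short_config():
    """Small, fast run used by orchestration tests."""
    return SimulationConfig(n_ants=5, n_steps=60, snapshot_every=20, master_seed=7)
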