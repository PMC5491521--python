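"""Shared fixtures: fast simulation configs and seeded generators."""

import numpy as np
import pytest

from tetherpm import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def fast_config():
    """Short default-geometry run for unit tests (2 s instead of 33 s)."""
    return SimulationConfig(duration=2.0, seed=7)


@pytest.fixture
def free_particle_config():
    """No tethers, bulk-water drag: the Stokes–Einstein reference case."""
    return SimulationConfig(
        n_tethers_total=0,
        n_tethers_initial_bound=0,
        fluid_viscosity=1.0e-3,
        timestep=1.0e-3,
        duration=33.0,
        seed=11,
    )
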