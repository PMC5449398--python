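"""Shared fixtures: one medium-length Lorenz run reused across test modules.

The 260-time-unit trajectory is long enough to train the standard
embedding (200 time units at dt = 0.001 with a q*dt = 0.1 window) and
hold out 60 time units, while keeping the whole suite fast.
"""

import numpy as np
import pytest

from havok import (
    SystemSpec,
    build_hankel,
    compute_embedding,
    fit_havok,
    simulate_system,
)

LORENZ_IC = (-8.0, 8.0, 27.0)
DT = 0.001


@pytest.fixture(scope="session")
def lorenz_traj():
    """Lorenz trajectory: 10 transient time units discarded, 260 kept."""
    spec = SystemSpec("lorenz", initial_state=LORENZ_IC)
    return simulate_system(spec, DT, 260.0, transient=10.0)


@pytest.fixture(scope="session")
def lorenz_series(lorenz_traj):
    return lorenz_traj.observed


@pytest.fixture(scope="session")
def lorenz_embedding(lorenz_series):
    """Rank-15 embedding of the first 200 time units, q = 100."""
    train = lorenz_series.window(0.0, 200.0)
    return compute_embedding(build_hankel(train, 100), 15)


@pytest.fixture(scope="session")
def lorenz_model(lorenz_embedding):
    """Rank-15 forced linear model fitted on the training coordinates."""
    return fit_havok(lorenz_embedding.V, dt=DT, r=15)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
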