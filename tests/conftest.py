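"""Shared fixtures.

The full-cycle simulations are expensive, so the three-shape experiments
(original basal truncation and the equatorial-truncation rebuilds) are run
once per session and shared by the energetics, periodicity and acceptance
tests.
"""

import numpy as np
import pytest

from lvdyn import (FiberField, ModelConfig, Simulator, SolverSettings,
                   SHAPE_PRESETS)
from lvdyn.simulator import shapes_experiment

N_CYCLES = 12
CONVERGED = range(6, N_CYCLES)


def base_config() -> ModelConfig:
    return ModelConfig(solver=SolverSettings(n_cycles=N_CYCLES))


@pytest.fixture(scope="session")
def shape_runs():
    """12-cycle runs of the spherical/normal/ellipsoidal matched shapes."""
    return shapes_experiment(base_config(), n_cycles=N_CYCLES)


@pytest.fixture(scope="session")
def normal_run(shape_runs):
    return shape_runs["normal"]


@pytest.fixture(scope="session")
def pi2_runs():
    """The same three shapes rebuilt with the basal truncation at the
    equator (nu_up = pi/2), preserving cavity and wall volumes."""
    return shapes_experiment(base_config(), n_cycles=N_CYCLES,
                             nu_up=np.pi / 2)


@pytest.fixture
def normal_geom():
    return SHAPE_PRESETS["normal"]


@pytest.fixture
def fiber_field():
    return FiberField()


def converged_mean(work, col):
    m = work[work["cycle"].isin(CONVERGED)]
    return float(m[col].mean())
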