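"""Shared fixtures.

The expensive computations (stiff integrations of the N = 128
community, spatial scenario pipelines) are session-scoped so the
whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from dryveg import ModelParams, build_trait_grid
from dryveg.scenarios import run_downshift, run_hybrid
from dryveg.uniform import uniform_branch


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def grid128(params):
    return build_trait_grid(128, params)


@pytest.fixture(scope="session")
def grid64(params):
    return build_trait_grid(64, params)


@pytest.fixture(scope="session")
def uniform_sweep_128(grid128, params):
    """Uniform-community branch P = 150 -> 100 -> 80 at full N = 128."""
    return uniform_branch([150.0, 100.0, 80.0], grid128, params)


@pytest.fixture(scope="session")
def downshift_result(params):
    """Full-scale staged downshift 150 -> 100 -> 80 (spatial final stage)."""
    return run_downshift(params=params, seed=1)


@pytest.fixture(scope="session")
def hybrid_result(params):
    """Hybrid-state experiment at P = 100, fractions 0.25 / 0.5 / 0.75."""
    return run_hybrid(params=params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
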