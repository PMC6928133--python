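"""Shared fixtures: session-scoped cell states and meshes (all generated)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from vablate import (
    CellParams,
    SyntheticLAParams,
    apply_af_remodeling,
    calibrate_stimulus,
    extrude_monolayer,
    find_resting_state,
    generate_synthetic_la,
    rectangular_strip,
)


@pytest.fixture(scope="session")
def baseline_params() -> CellParams:
    return CellParams()


@pytest.fixture(scope="session")
def remodeled_params() -> CellParams:
    return apply_af_remodeling(CellParams())


@pytest.fixture(scope="session")
def resting_remodeled(remodeled_params):
    return find_resting_state(remodeled_params)


@pytest.fixture(scope="session")
def resting_baseline(baseline_params):
    return find_resting_state(baseline_params)


@pytest.fixture(scope="session")
def stim_amplitude(remodeled_params, resting_remodeled) -> float:
    return calibrate_stimulus(remodeled_params, resting=resting_remodeled)


@pytest.fixture(scope="session")
def la_surface():
    return generate_synthetic_la(SyntheticLAParams(random_seed=1))


@pytest.fixture(scope="session")
def la_mesh(la_surface):
    return extrude_monolayer(la_surface)


@pytest.fixture(scope="session")
def small_strip():
    """Coarse flat sheet for cheap tissue tests (189 nodes)."""
    return rectangular_strip(20.0, 8.0, 1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
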