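"""Shared fixtures: a small, fast acquisition grid and simulation helpers.

The test grid is 48x48x13 voxels at 5 mm isotropic (240 mm in-plane
FOV), large enough that the default 111 mm phantom and its half-FOV
ghost do not overlap, small enough that a full simulated session runs
in tens of milliseconds.
"""

import datetime

import numpy as np
import pytest

from phantomqc import (
    GridSpec,
    GroundTruth,
    PhantomGeometry,
    SessionMeta,
    simulate_phantom_series,
)


@pytest.fixture(scope="session")
def grid():
    return GridSpec(shape=(48, 48, 13), voxel_size_mm=(5.0, 5.0, 5.0), tr_s=2.0)


@pytest.fixture(scope="session")
def geom():
    return PhantomGeometry()


@pytest.fixture
def simulate(grid, geom):
    """Factory: simulate(seed=..., **ground-truth overrides) -> (vol, truth)."""

    def _sim(geom_override=None, grid_override=None, **truth_kw):
        truth = GroundTruth(**{"signal_mean": 1000.0, "noise_sd": 10.0, **truth_kw})
        return simulate_phantom_series(
            geom=geom_override or geom, truth=truth, grid=grid_override or grid
        )

    return _sim


@pytest.fixture
def phantom_meta():
    def _meta(date=datetime.date(2018, 6, 11), site="MA", scanner="scanner-MA"):
        return SessionMeta(
            site=site,
            scanner_id=scanner,
            date=date,
            session_type="phantom",
            subject_or_phantom_id="phantom01",
        )

    return _meta


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160101)
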