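import numpy as np
import pytest

import lorp


@pytest.fixture(scope="session")
def sim_anatomy():
    """Default synthetic simulation anatomy, seed 0."""
    return lorp.generate_simulation_anatomy(seed=0)


@pytest.fixture(scope="session")
def plan_library(sim_anatomy):
    """Full 16-entry plan library built on the default anatomy."""
    return lorp.build_plan_library(sim_anatomy)


@pytest.fixture(scope="session")
def criteria():
    return lorp.default_criteria()


@pytest.fixture(scope="session")
def small_grid():
    """24-voxel cube at 2 mm spacing, origin centered."""
    return lorp.make_grid((24, 24, 24), (2.0, 2.0, 2.0), (-24.0, -24.0, -24.0))


def box_mask(grid, lo_mm, hi_mm):
    """Axis-aligned box: voxels whose centers lie in [lo, hi] per axis."""
    x = grid.axis_coords_mm(0)[:, None, None]
    y = grid.axis_coords_mm(1)[None, :, None]
    z = grid.axis_coords_mm(2)[None, None, :]
    return (
        (x >= lo_mm[0]) & (x <= hi_mm[0])
        & (y >= lo_mm[1]) & (y <= hi_mm[1])
        & (z >= lo_mm[2]) & (z <= hi_mm[2])
    )


def sphere_mask(grid, center_mm, radius_mm):
    x = grid.axis_coords_mm(0)[:, None, None]
    y = grid.axis_coords_mm(1)[None, :, None]
    z = grid.axis_coords_mm(2)[None, None, :]
    return (
        (x - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2 + (z - center_mm[2]) ** 2
    ) <= radius_mm**2


@pytest.fixture(scope="session")
def ideal_criterion_values(criteria):
    """Metric values meeting every per-protocol bound with slack."""
    values = {}
    for row in criteria.rows:
        if row.direction == "at_least":
            values[row.key] = 100.0
        else:
            values[row.key] = 0.0
    return values
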