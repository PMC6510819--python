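"""Shared fixtures.

Heavy solved states (the intact flexion sweep and the full tear matrix) are
session-scoped so the acceptance tests share one set of solves.
"""

from __future__ import annotations

import numpy as np
import pytest

from meniscusfe.geometry import KneeGeometryParams, generate_geometry
from meniscusfe.meshing import DEFAULT_RESOLUTION, mesh_meniscus


@pytest.fixture(scope="session")
def geometry():
    return generate_geometry()


@pytest.fixture(scope="session")
def mm_mesh(geometry):
    return mesh_meniscus(geometry, "MM", DEFAULT_RESOLUTION)


@pytest.fixture(scope="session")
def symmetric_geometry():
    """Exactly sagittally mirror-symmetric knee (equal condyles and menisci)."""
    p = KneeGeometryParams(
        condyle_radius_medial=26.0, condyle_radius_lateral=26.0,
        meniscus_outer_radius_LM=20.0, meniscus_inner_radius_LM=10.0,
        meniscus_peripheral_height_LM=6.0,
        arc_start_deg_MM=55.0, arc_end_deg_MM=295.0,
        arc_start_deg_LM=55.0 - 180.0, arc_end_deg_LM=295.0 - 180.0,
    )
    return generate_geometry(p)


@pytest.fixture(scope="session")
def intact_sweep():
    """Intact knee solved at 0/20/30 degrees under full body weight."""
    from meniscusfe.experiment import solve_intact_sweep

    return solve_intact_sweep()


@pytest.fixture(scope="session")
def tear_matrix(intact_sweep):
    """The full tear matrix (2 menisci x 3 regions x 2 types x 2 lengths at
    0/20/30 degrees), warm-started from the intact sweep."""
    from meniscusfe.experiment import TEAR_MATRIX, TearCellResult, solve_tear_cell

    cells = []
    for ang, intact in intact_sweep.items():
        for spec in TEAR_MATRIX:
            try:
                cell = solve_tear_cell(spec, ang, intact)
            except Exception as exc:   # noqa: BLE001 - cell isolation
                cell = TearCellResult(spec, ang, None, None, None, repr(exc))
            cell.model = None
            cell.solution = None
            cells.append(cell)
    return cells


def box_mesh(nx, ny, nz, lx=1.0, ly=1.0, lz=1.0):
    from meniscusfe.meshing import mesh_box

    return mesh_box(nx, ny, nz, lx, ly, lz)


def random_rotation(seed=0):
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    return Rotation.random(random_state=rng).as_matrix()
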