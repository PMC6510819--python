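"""High-level experiment orchestration: intact sweeps and the tear matrix.

The intact model is solved at each flexion angle with load ramping at the
first angle and chained warm starts thereafter; every torn model is solved
directly at full load, warm-started from the intact solution of its angle.
All tear simulations use the full-body-weight load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import ConvergenceError, SolverParams, SolutionField
from .knee import FULL_BODY_WEIGHT, KneeLoadCase, KneeModel, build_knee_model
from .meshing import MeshResolution
from .postprocess import (apex_stress_delta, sample_transect,
                          tear_surface_difference)
from .tears import TearSpec

TEAR_MATRIX = tuple(
    TearSpec(tear_type, meniscus, region, stability)
    for meniscus in ("MM", "LM")
    for region in ("anterior", "middle", "posterior")
    for tear_type in ("longitudinal", "radial")
    for stability in ("stable", "unstable")
)

RAMP_PARAMS = SolverParams(n_steps=4, max_iter=100, step_max_disp=2.0)
DIRECT_PARAMS = SolverParams(n_steps=1, max_iter=150, step_max_disp=2.0)


@dataclass
class TearCellResult:
    spec: TearSpec
    flexion_angle: float
    model: KneeModel = field(repr=False)
    solution: SolutionField = field(repr=False)
    report: object = None          # TearSurfaceReport or ApexReport
    error: str | None = None


@dataclass
class IntactResult:
    flexion_angle: float
    model: KneeModel = field(repr=False)
    solution: SolutionField = field(repr=False)


def solve_intact_sweep(angles=(0.0, 20.0, 30.0), geometry=None,
                       resolution: MeshResolution | None = None,
                       axial_load: float = FULL_BODY_WEIGHT,
                       screw_home_coupling_deg: float = 5.0,
                       rollback_mm_per_deg: float = 0.1,
                       **model_kwargs) -> dict:
    """Solve the intact knee at each angle with chained warm starts."""
    results: dict[float, IntactResult] = {}
    prev = None
    for i, ang in enumerate(angles):
        model = build_knee_model(
            geometry=geometry, resolution=resolution,
            load_case=KneeLoadCase(flexion_angle=ang, axial_load=axial_load,
                                   screw_home_coupling_deg=screw_home_coupling_deg,
                                   rollback_mm_per_deg=rollback_mm_per_deg),
            **model_kwargs)
        if prev is None:
            sol = model.solve(RAMP_PARAMS)
        else:
            try:
                sol = model.solve(DIRECT_PARAMS, warm_from=prev)
            except ConvergenceError:
                sol = model.solve(RAMP_PARAMS)
        results[ang] = IntactResult(ang, model, sol)
        prev = sol
    return results


def solve_tear_cell(spec: TearSpec, flexion_angle: float,
                    intact: IntactResult, geometry=None,
                    resolution: MeshResolution | None = None,
                    **model_kwargs) -> TearCellResult:
    """Solve one torn configuration and attach its outcome report."""
    lc = intact.model.load_case
    model = build_knee_model(
        geometry=geometry, resolution=resolution,
        load_case=KneeLoadCase(flexion_angle=flexion_angle,
                               axial_load=FULL_BODY_WEIGHT,
                               screw_home_coupling_deg=lc.screw_home_coupling_deg,
                               rollback_mm_per_deg=lc.rollback_mm_per_deg),
        tear=spec, **model_kwargs)
    try:
        sol = model.solve(DIRECT_PARAMS, warm_from=intact.solution)
    except ConvergenceError:
        sol = model.solve(RAMP_PARAMS)
    if spec.tear_type == "longitudinal":
        report = tear_surface_difference(sol, model.mesh, model.tear,
                                         node_offset=model.tear_node_offset,
                                         flexion_angle=flexion_angle)
    else:
        report = apex_stress_delta(sol, intact.solution, model.mesh, model.tear,
                                   node_offset=model.tear_node_offset,
                                   flexion_angle=flexion_angle)
    return TearCellResult(spec, flexion_angle, model, sol, report)


def run_tear_matrix(angles=(0.0, 20.0, 30.0), geometry=None,
                    resolution: MeshResolution | None = None,
                    tears=TEAR_MATRIX, keep_fields: bool = False,
                    **model_kwargs) -> tuple[dict, list]:
    """Solve the full (or a reduced) tear matrix.

    Returns the intact sweep and a list of :class:`TearCellResult`.  Cells
    fail independently: a non-converged cell carries an error string instead
    of a report.  With ``keep_fields`` false the bulky per-cell model and
    solution objects are dropped once the report is extracted.
    """
    intact = solve_intact_sweep(angles, geometry=geometry,
                                resolution=resolution, **model_kwargs)
    cells: list[TearCellResult] = []
    for ang in angles:
        for spec in tears:
            try:
                cell = solve_tear_cell(spec, ang, intact[ang],
                                       geometry=geometry, resolution=resolution,
                                       **model_kwargs)
            except Exception as exc:   # noqa: BLE001 - cell isolation
                cell = TearCellResult(spec, ang, None, None, None, repr(exc))
            if not keep_fields:
                cell.model = None
                cell.solution = None
            cells.append(cell)
    return intact, cells


def intact_transects(intact: dict, n_samples: int = 13) -> list:
    """Hoop-stress transects of every region of both menisci, per angle."""
    out = []
    for ang, res in intact.items():
        for side in ("MM", "LM"):
            for region in ("anterior", "middle", "posterior"):
                out.append(sample_transect(res.solution, res.model.mesh, side,
                                           region, n_samples=n_samples,
                                           flexion_angle=ang))
    return out
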