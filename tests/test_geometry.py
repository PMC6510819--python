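"""Synthetic knee geometry: validation, poses, mirror symmetry, volumes."""

import dataclasses

import numpy as np
import pytest

from meniscusfe.geometry import (GeometryParameterError, KneeGeometryParams,
                                 generate_geometry, mirror_params, pose_femur)
from meniscusfe.meshing import DEFAULT_RESOLUTION, MeshResolution, mesh_meniscus


def test_default_geometry_structure(geometry):
    assert set(geometry.menisci) == {"MM", "LM"}
    assert len(geometry.ligament_attachments) == 4
    assert len(geometry.landmarks) == 3
    assert geometry.condyle_center_z > 0


def test_invalid_radii_rejected():
    params = KneeGeometryParams(meniscus_inner_radius_MM=21.0)  # >= outer (20)
    with pytest.raises(GeometryParameterError, match="outer_radius > inner_radius"):
        generate_geometry(params)


def test_arc_span_ordering_enforced():
    params = KneeGeometryParams(arc_start_deg_MM=100.0, arc_end_deg_MM=300.0)
    # MM span 200 < LM span 230
    with pytest.raises(GeometryParameterError, match="arc span"):
        generate_geometry(params)


def test_generation_is_deterministic():
    a = generate_geometry(KneeGeometryParams(random_seed=1))
    b = generate_geometry(KneeGeometryParams(random_seed=1))
    ma = mesh_meniscus(a, "MM", DEFAULT_RESOLUTION)
    mb = mesh_meniscus(b, "MM", DEFAULT_RESOLUTION)
    assert ma.nodes.tobytes() == mb.nodes.tobytes()
    assert ma.tets.tobytes() == mb.tets.tobytes()


def test_meniscus_inferior_congruent_with_dish(geometry):
    for side in ("MM", "LM"):
        men = geometry.menisci[side]
        phi = np.linspace(men.arc_start_deg, men.arc_end_deg, 40)
        pts = men.point(phi, np.full_like(phi, 0.5), np.zeros_like(phi))
        dish_z = men.dish.z(pts[:, 0], pts[:, 1])
        assert np.allclose(pts[:, 2], dish_z, atol=1e-10)


def test_pose_identity_at_zero(geometry):
    pose = pose_femur(geometry, 0.0)
    assert np.allclose(pose.transform.R, np.eye(3), atol=1e-12)
    assert np.allclose(pose.transform.t, 0.0, atol=1e-12)


def test_pose_invertibility(geometry):
    pose = pose_femur(geometry, 20.0)
    pts = np.array(list(geometry.landmarks.values()))
    back = pose.transform.inverse().apply(pose.transform.apply(pts))
    assert np.max(np.abs(back - pts)) < 1e-9


def test_pose_rotation_angle_within_coupling(geometry):
    coupling = 5.0
    pose = pose_femur(geometry, 30.0, screw_home_coupling_deg=coupling)
    angle = pose.transform.rotation_angle_deg()
    assert 30.0 - coupling <= angle <= 30.0 + coupling


def test_pose_rejects_out_of_range(geometry):
    with pytest.raises(ValueError):
        pose_femur(geometry, 45.0)


def test_mirrored_geometry_swaps_menisci(symmetric_geometry):
    """Within a symmetric knee, the LM mesh is the exact sagittal mirror of
    the MM mesh, node for node (the chirality conventions mirror)."""
    res = DEFAULT_RESOLUTION
    mm = mesh_meniscus(symmetric_geometry, "MM", res)
    lm = mesh_meniscus(symmetric_geometry, "LM", res)
    mirrored = mm.nodes * np.array([-1.0, 1.0, 1.0])
    assert np.max(np.abs(mirrored - lm.nodes)) < 1e-9


def test_mirror_params_roundtrip():
    p = KneeGeometryParams()
    q = mirror_params(mirror_params(p))
    for f in dataclasses.fields(KneeGeometryParams):
        a, b = getattr(p, f.name), getattr(q, f.name)
        if isinstance(a, (int, float)):
            assert np.isclose(a, b), f.name


def test_meniscus_volume_matches_swept_wedge_integral(geometry):
    """Meshed volume converges to the closed-form swept-wedge integral."""
    for side in ("MM", "LM"):
        analytic = geometry.menisci[side].analytic_volume()
        coarse = mesh_meniscus(geometry, side, DEFAULT_RESOLUTION).volumes().sum()
        fine = mesh_meniscus(geometry, side,
                             MeshResolution(44, 12, 4, 10, 2)).volumes().sum()
        err_c = abs(coarse - analytic) / analytic
        err_f = abs(fine - analytic) / analytic
        assert err_c < 0.02
        assert err_f < err_c


def test_ligament_insertions_offset_from_horns(geometry):
    for name, (horn, insertion) in geometry.ligament_attachments.items():
        d = np.linalg.norm(insertion - horn)
        assert 2.0 < d < 15.0, name
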