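"""Structured tet meshing: counts, volumes, facet sets, fibers, labels."""

import collections

import numpy as np
import pytest

from meniscusfe.materials import MENISCUS_DEFAULT, stiffness_transverse_isotropic
from meniscusfe.meshing import (DEFAULT_RESOLUTION, MeshResolution, MeshingError,
                                boundary_faces, mesh_femoral_cartilage,
                                mesh_meniscus, mesh_tibial_cartilage,
                                structured_tet_count)


def test_resolution_validation():
    with pytest.raises(MeshingError):
        MeshResolution(radial_divisions=4).validate()   # not a multiple of 3
    with pytest.raises(MeshingError):
        MeshResolution(vertical_divisions=1).validate()


def test_meniscus_element_count_matches_closed_form(geometry):
    res = MeshResolution(12, 3, 2, 4, 2)
    mesh = mesh_meniscus(geometry, "MM", res)
    assert mesh.n_elements == structured_tet_count(12, 3, 2)
    assert mesh.n_nodes == 13 * 4 * 3


def test_all_volumes_positive(geometry):
    for side in ("MM", "LM"):
        mesh = mesh_meniscus(geometry, side, DEFAULT_RESOLUTION)
        assert mesh.volumes().min() > 0
    for builder, comp in ((mesh_tibial_cartilage, "medial"),
                          (mesh_femoral_cartilage, "lateral")):
        assert builder(geometry, comp, DEFAULT_RESOLUTION).volumes().min() > 0


def test_facet_sets_partition_boundary(geometry, mm_mesh):
    tri, _ = boundary_faces(mm_mesh)
    total = sum(len(v) for v in mm_mesh.facet_sets.values())
    assert total == len(tri)
    # disjoint: the union of sorted triangle keys has no duplicates
    keys = np.concatenate([np.sort(v, axis=1) for v in mm_mesh.facet_sets.values()])
    assert len(np.unique(keys, axis=0)) == len(keys)


def test_fiber_directions_are_circumferential(geometry, mm_mesh):
    shape = geometry.menisci["MM"]
    cen = mm_mesh.centroids()
    norms = np.linalg.norm(mm_mesh.fiber_dir, axis=1)
    assert np.allclose(norms, 1.0, atol=1e-12)
    radial = np.stack([cen[:, 0] - shape.center_x, cen[:, 1],
                       np.zeros(len(cen))], axis=1)
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    dots = np.abs(np.einsum("ij,ij->i", mm_mesh.fiber_dir, radial))
    assert dots.max() < 1e-6


def test_circle_tangent_closed_form(geometry, mm_mesh):
    shape = geometry.menisci["MM"]
    cen = mm_mesh.centroids()
    phi, _ = shape.polar(cen)
    ang = shape._angle(phi)
    expected = np.stack([-np.sin(ang) * shape.chirality,
                         np.cos(ang) * shape.chirality,
                         np.zeros_like(ang)], axis=1)
    assert np.max(np.abs(mm_mesh.fiber_dir - expected)) < 1e-9


def test_fiber_sign_flip_leaves_stiffness_unchanged():
    f = np.array([0.6, 0.8, 0.0])
    C1 = stiffness_transverse_isotropic(MENISCUS_DEFAULT, f)
    C2 = stiffness_transverse_isotropic(MENISCUS_DEFAULT, -f)
    assert np.max(np.abs(C1 - C2)) < 1e-10


def test_region_zone_labels(geometry, mm_mesh):
    shape = geometry.menisci["MM"]
    cen = mm_mesh.centroids()
    phi, s = shape.polar(cen)
    frac = (phi - shape.arc_start_deg) / (shape.arc_end_deg - shape.arc_start_deg)
    # spot checks at known parameters
    assert set(mm_mesh.region[frac < 0.3]) == {"anterior"}
    assert set(mm_mesh.region[(frac > 0.4) & (frac < 0.6)]) == {"middle"}
    assert set(mm_mesh.zone[(s > 0.4) & (s < 0.6)]) == {"middle"}
    # equal-measure thirds: exact equality for divisible structured grids
    rc = collections.Counter(mm_mesh.region)
    zc = collections.Counter(mm_mesh.zone)
    ring = mm_mesh.n_elements // DEFAULT_RESOLUTION.circumferential_divisions
    assert max(rc.values()) - min(rc.values()) <= ring
    assert len(set(zc.values())) == 1


def test_labels_invariant_to_resolution(geometry):
    """An element's centroid determines its labels, not the subdivision."""
    for res in (MeshResolution(12, 6, 2, 4, 2), MeshResolution(24, 6, 4, 4, 2)):
        mesh = mesh_meniscus(geometry, "LM", res)
        shape = geometry.menisci["LM"]
        phi, s = shape.polar(mesh.centroids())
        frac = (phi - shape.arc_start_deg) / (shape.arc_end_deg - shape.arc_start_deg)
        expected = np.array(["anterior", "middle", "posterior"], dtype=object)[
            np.clip((frac * 3).astype(int), 0, 2)]
        assert (mesh.region == expected).all()


def test_cartilage_layer_thickness_bound(geometry):
    t = geometry.params.cartilage_thickness_tibial
    mesh = mesh_tibial_cartilage(geometry, "medial", DEFAULT_RESOLUTION)
    dish = geometry.dishes["medial"]
    depth = dish.z(mesh.nodes[:, 0], mesh.nodes[:, 1]) - mesh.nodes[:, 2]
    assert depth.min() > -1e-9
    assert depth.max() < t + 1e-9


def test_cartilage_element_count_and_bone_coverage(geometry):
    res = DEFAULT_RESOLUTION
    mesh = mesh_tibial_cartilage(geometry, "medial", res)
    n, nz = res.cartilage_divisions, res.cartilage_layers
    assert mesh.n_elements == structured_tet_count(n, n, nz)
    bone = mesh.facet_sets["bone"]
    assert len(bone) == 2 * n * n  # two triangles per cell over the full face
    assert len(mesh.facet_sets["articular"]) == 2 * n * n


def test_femoral_cap_bone_and_articular_radii(geometry):
    mesh = mesh_femoral_cartilage(geometry, "medial", DEFAULT_RESOLUTION)
    condyle = geometry.condyles["medial"]
    for name, radius in (("bone", condyle.bone_radius),
                         ("articular", condyle.articular_radius)):
        ids = np.unique(mesh.facet_sets[name])
        r = np.linalg.norm(mesh.nodes[ids] - condyle.center, axis=1)
        assert np.allclose(r, radius, atol=1e-9), name


def test_degenerate_cross_section_rejected(geometry):
    import dataclasses

    shape = geometry.menisci["MM"]
    bad = dataclasses.replace(shape, h_inner=0.0, h_peri=0.0)
    geom2 = dataclasses.replace(geometry)
    geom2.menisci = dict(geometry.menisci, MM=bad)
    with pytest.raises(MeshingError):
        mesh_meniscus(geom2, "MM", DEFAULT_RESOLUTION)
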