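"""Tear insertion: facet-path location, node duplication, topology checks."""

import numpy as np
import pytest
from scipy.sparse import csgraph, csr_matrix

from meniscusfe.meshing import DEFAULT_RESOLUTION, mesh_meniscus
from meniscusfe.tears import (TearSpec, TearSpecError, TearSurface, insert_tear,
                              locate_tear_surface, merge_tear, split_mesh)


def test_tear_spec_validation():
    with pytest.raises(TearSpecError):
        TearSpec("horizontal", "MM", "middle", "stable")
    with pytest.raises(TearSpecError):
        TearSpec("radial", "MM", "center", "stable")


def test_split_counting_oracle_on_box():
    """Hand-built box split along an interior half-plane: node count grows by
    exactly the number of interior plane nodes; element count is unchanged."""
    from conftest import box_mesh

    mesh = box_mesh(2, 2, 2)
    gi = mesh.meta["grid_index"]
    node_on = gi[:, 0] == 1
    from meniscusfe.tears import _facets_on

    facets = _facets_on(mesh, gi[mesh.tets], node_on)
    # plane has 9 nodes; keep the outer ring shared -> 1 interior node
    boundary_ring = node_on & (np.any((gi[:, 1:] == 0) | (gi[:, 1:] == 2), axis=1))
    surface = TearSurface(
        spec=TearSpec("longitudinal", "MM", "middle", "stable"),
        facets=facets, front_nodes=np.flatnonzero(boundary_ring),
        side_fn=lambda p: p[:, 0] > 0.5,
        achieved_length=0.0, achieved_fraction=0.0,
        apex_nodes=np.flatnonzero(boundary_ring))
    torn, topo = split_mesh(mesh, surface)
    assert torn.n_elements == mesh.n_elements
    assert torn.n_nodes == mesh.n_nodes + 1
    assert len(topo.node_pairs) == 1
    assert torn.volumes().min() > 0
    assert np.isclose(torn.volumes().sum(), mesh.volumes().sum())


@pytest.fixture(scope="module")
def mm(geometry_module=None):
    from meniscusfe.geometry import generate_geometry

    return mesh_meniscus(generate_geometry(), "MM", DEFAULT_RESOLUTION)


@pytest.mark.parametrize("stability,target", [("stable", 7.0), ("unstable", 14.0)])
def test_longitudinal_achieved_length(mm, stability, target):
    spec = TearSpec("longitudinal", "MM", "middle", stability)
    surface = locate_tear_surface(mm, spec)
    shape = mm.meta["shape"]
    nc = mm.meta["grid"][0]
    edge = (shape.r_inner + 5 / 6 * shape.rim_width) * shape.arc_span_rad / nc
    assert abs(surface.achieved_length - target) <= edge


@pytest.mark.parametrize("stability,target", [("stable", 1 / 6), ("unstable", 0.5)])
def test_radial_achieved_fraction(mm, stability, target):
    spec = TearSpec("radial", "LM", "posterior", stability)
    from meniscusfe.geometry import generate_geometry

    lm = mesh_meniscus(generate_geometry(), "LM", DEFAULT_RESOLUTION)
    surface = locate_tear_surface(lm, spec)
    nr = lm.meta["grid"][1]
    assert abs(surface.achieved_fraction - target) <= 1.0 / nr


def test_zero_length_tear_rejected(mm):
    spec = TearSpec("longitudinal", "MM", "middle", "stable", length_mm=0.0)
    with pytest.raises(TearSpecError):
        locate_tear_surface(mm, spec)
    spec = TearSpec("radial", "MM", "middle", "stable", rim_fraction=0.0)
    with pytest.raises(TearSpecError):
        locate_tear_surface(mm, spec)


def test_full_width_radial_tear_rejected(mm):
    spec = TearSpec("radial", "MM", "middle", "unstable", rim_fraction=1.0)
    with pytest.raises(TearSpecError):
        locate_tear_surface(mm, spec)


def test_oversized_longitudinal_tear_rejected(mm):
    spec = TearSpec("longitudinal", "MM", "middle", "unstable", length_mm=80.0)
    with pytest.raises(TearSpecError, match="exceed"):
        locate_tear_surface(mm, spec)


@pytest.mark.parametrize("tear_type,region", [("longitudinal", "middle"),
                                              ("radial", "posterior")])
def test_split_topology_invariants(mm, tear_type, region):
    spec = TearSpec(tear_type, "MM", region, "unstable")
    torn, topo = insert_tear(mm, spec)
    # element count unchanged; node growth = duplicated interior nodes
    assert torn.n_elements == mm.n_elements
    assert torn.n_nodes == mm.n_nodes + len(topo.node_pairs)
    # coincident faces in the unloaded state
    d = torn.nodes[topo.node_pairs[:, 0]] - torn.nodes[topo.node_pairs[:, 1]]
    assert np.max(np.abs(d)) == 0.0
    # volume conserved, all elements valid
    assert torn.volumes().min() > 0
    assert np.isclose(torn.volumes().sum(), mm.volumes().sum())


def test_split_then_merge_roundtrip(mm):
    spec = TearSpec("longitudinal", "MM", "posterior", "stable")
    torn, topo = insert_tear(mm, spec)
    merged = merge_tear(torn, topo)
    assert merged.n_nodes == mm.n_nodes
    assert np.array_equal(np.sort(merged.tets, axis=1), np.sort(mm.tets, axis=1))


def test_longitudinal_tear_keeps_one_component(mm):
    """The circumferential tear ends hold the inner flap: still 1 component."""
    spec = TearSpec("longitudinal", "MM", "middle", "unstable")
    torn, _ = insert_tear(mm, spec)
    edges = np.concatenate([torn.tets[:, [0, 1]], torn.tets[:, [0, 2]],
                            torn.tets[:, [0, 3]], torn.tets[:, [1, 2]],
                            torn.tets[:, [1, 3]], torn.tets[:, [2, 3]]])
    adj = csr_matrix((np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
                     shape=(torn.n_nodes, torn.n_nodes))
    n_comp, _ = csgraph.connected_components(adj, directed=False)
    assert n_comp == 1


def test_tear_faces_oriented_toward_positive_side(mm):
    spec = TearSpec("longitudinal", "MM", "middle", "stable")
    torn, topo = insert_tear(mm, spec)
    shape = mm.meta["shape"]
    p = torn.nodes[topo.face_neg]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    cen = p.mean(axis=1)
    # outward of the inner (- side) solid: normals point radially outward
    radial = np.stack([cen[:, 0] - shape.center_x, cen[:, 1],
                       np.zeros(len(cen))], axis=1)
    dots = np.einsum("ij,ij->i", n, radial)
    assert (dots > 0).all()
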