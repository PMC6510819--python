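"""Structured linear-tetrahedral meshing of the deformable knee tissues.

All solids are meshed as structured hexahedral lattices subdivided into six
tetrahedra per cell with the Freudenthal (main-diagonal) template, which is
conforming across a structured grid and makes meshes reproducible
bit-for-bit.  Meniscal meshes carry per-element circumferential fiber
directions, the anterior/middle/posterior circumferential region labels and
the inner (white) / middle (red-white) / outer (red) radial zone labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import KneeGeometry, MeniscusShape

PART_MENISCUS = {"MM": "meniscus_MM", "LM": "meniscus_LM"}
REGIONS = ("anterior", "middle", "posterior")
ZONES = ("inner", "middle", "outer")


class MeshingError(RuntimeError):
    """Degenerate geometry or resolution prevents valid meshing."""


@dataclass(frozen=True)
class MeshResolution:
    """Structured subdivision counts.

    circumferential/radial/vertical divisions control the meniscal sweep;
    radial divisions must be a multiple of 3 so zone boundaries fall on
    element boundaries (and of 6 for tears centered at s = 5/6 to fall on a
    node layer).  cartilage_divisions is the in-plane subdivision of each
    cartilage patch, cartilage_layers the through-thickness count.
    """

    circumferential_divisions: int = 22
    radial_divisions: int = 6
    vertical_divisions: int = 2
    cartilage_divisions: int = 10
    cartilage_layers: int = 2

    def validate(self) -> None:
        if min(self.circumferential_divisions, self.radial_divisions,
               self.vertical_divisions, self.cartilage_divisions,
               self.cartilage_layers) < 2:
            raise MeshingError("all subdivision counts must be >= 2")
        if self.radial_divisions % 3:
            raise MeshingError("radial_divisions must be a multiple of 3")

    def refined(self, factor: float = 1.5) -> "MeshResolution":
        """Uniformly refined resolution (radial rounded to a multiple of 3)."""
        r = max(3 * round(self.radial_divisions * factor / 3), self.radial_divisions + 3)
        return MeshResolution(
            circumferential_divisions=round(self.circumferential_divisions * factor),
            radial_divisions=r,
            vertical_divisions=round(self.vertical_divisions * factor),
            cartilage_divisions=round(self.cartilage_divisions * factor),
            cartilage_layers=round(self.cartilage_layers * factor),
        )


DEFAULT_RESOLUTION = MeshResolution(22, 6, 2, 9, 2)


@dataclass
class FEMesh:
    """Nodes + linear tets with part/region/zone labels and boundary facet sets.

    facet_sets maps names to (F, 3) triangle node-index arrays oriented
    outward.  ``meta`` keeps the structured-grid bookkeeping (per-node grid
    indices, sweep shape) used by tear insertion and labelling.
    """

    nodes: np.ndarray
    tets: np.ndarray
    part: np.ndarray                     # (M,) str
    region: np.ndarray                   # (M,) str, '' outside menisci
    zone: np.ndarray                     # (M,) str
    fiber_dir: np.ndarray                # (M, 3), zeros outside menisci
    facet_sets: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.tets)

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def copy(self) -> "FEMesh":
        return FEMesh(self.nodes.copy(), self.tets.copy(), self.part.copy(),
                      self.region.copy(), self.zone.copy(), self.fiber_dir.copy(),
                      {k: v.copy() for k, v in self.facet_sets.items()},
                      dict(self.meta))


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for correct orientation)."""
    p = nodes[tets]
    a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


_FREUDENTHAL = np.array([
    [0, 1, 2, 6], [0, 2, 3, 6], [0, 3, 7, 6],
    [0, 7, 4, 6], [0, 4, 5, 6], [0, 5, 1, 6],
])


def structured_tet_count(n1: int, n2: int, n3: int) -> int:
    """Closed-form element count of the structured hex->6-tet subdivision."""
    return 6 * n1 * n2 * n3


def _structured_tets(n1: int, n2: int, n3: int) -> tuple[np.ndarray, np.ndarray]:
    """Tets and per-node (i, j, k) grid indices for an (n1, n2, n3)-cell grid."""

    def nid(i, j, k):
        return (i * (n2 + 1) + j) * (n3 + 1) + k

    i, j, k = np.meshgrid(np.arange(n1), np.arange(n2), np.arange(n3), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    corners = np.stack([
        nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
        nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
    ], axis=1)
    tets = corners[:, _FREUDENTHAL].reshape(-1, 4)
    gi, gj, gk = np.meshgrid(np.arange(n1 + 1), np.arange(n2 + 1), np.arange(n3 + 1),
                             indexing="ij")
    grid_index = np.stack([gi.ravel(), gj.ravel(), gk.ravel()], axis=1)
    return tets, grid_index


def _fix_orientation(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    v = tet_volumes(nodes, tets)
    flip = v < 0
    tets = tets.copy()
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return tets


def boundary_faces(mesh_or_tets, nodes: np.ndarray | None = None):
    """Boundary triangles (outward-oriented) and the owning element index."""
    if isinstance(mesh_or_tets, FEMesh):
        tets, nodes = mesh_or_tets.tets, mesh_or_tets.nodes
    else:
        tets = mesh_or_tets
    faces_idx = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    opp_idx = np.array([3, 2, 1, 0])
    faces = tets[:, faces_idx].reshape(-1, 3)
    opp = tets[:, opp_idx].reshape(-1)
    owner = np.repeat(np.arange(len(tets)), 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    key_s, faces_s, opp_s, owner_s = key[order], faces[order], opp[order], owner[order]
    dup_prev = np.zeros(len(key_s), bool)
    dup_prev[1:] = np.all(key_s[1:] == key_s[:-1], axis=1)
    dup_next = np.zeros(len(key_s), bool)
    dup_next[:-1] = dup_prev[1:]
    single = ~(dup_prev | dup_next)
    tri, opp_n, own = faces_s[single], opp_s[single], owner_s[single]
    # orient outward: normal should point away from the opposite node
    p = nodes[tri]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    cen = p.mean(axis=1)
    inward = np.einsum("ij,ij->i", n, cen - nodes[opp_n]) < 0
    tri[inward] = tri[inward][:, [0, 2, 1]]
    return tri, own


def _classify_structured_boundary(tri: np.ndarray, grid_index: np.ndarray,
                                  dims: tuple, names: dict) -> dict:
    """Assign boundary triangles to facet sets by constant grid-index planes.

    ``names`` maps (axis, 'lo'|'hi') -> set name.  Every boundary triangle of
    a structured grid lies in exactly one extreme index plane, so the sets
    form a watertight partition of the boundary.
    """
    gi = grid_index[tri]  # (F, 3 nodes, 3 axes)
    sets: dict[str, list] = {v: [] for v in names.values()}
    assigned = np.zeros(len(tri), bool)
    for (axis, end), name in names.items():
        val = 0 if end == "lo" else dims[axis]
        on = np.all(gi[:, :, axis] == val, axis=1) & ~assigned
        sets[name].append(tri[on])
        assigned |= on
    if not assigned.all():
        raise MeshingError("boundary facet classification left facets unassigned")
    return {k: (np.concatenate(v) if v else np.zeros((0, 3), int)) for k, v in sets.items()}


def mesh_meniscus(geometry: KneeGeometry, side: str,
                  resolution: MeshResolution | None = None) -> FEMesh:
    """Structured swept-wedge mesh of one meniscus with labels and fibers."""
    resolution = resolution or DEFAULT_RESOLUTION
    resolution.validate()
    shape = geometry.menisci[side]
    if shape.h_peri <= 0 or shape.h_inner <= 0:
        raise MeshingError(f"meniscus {side}: degenerate (non-positive height) cross-section")
    nc, nr, nv = (resolution.circumferential_divisions, resolution.radial_divisions,
                  resolution.vertical_divisions)
    phi = np.linspace(shape.arc_start_deg, shape.arc_end_deg, nc + 1)
    s = np.linspace(0.0, 1.0, nr + 1)
    v = np.linspace(0.0, 1.0, nv + 1)
    P, S, V = np.meshgrid(phi, s, v, indexing="ij")
    nodes = shape.point(P, S, V).reshape(-1, 3)
    tets, grid_index = _structured_tets(nc, nr, nv)
    tets = _fix_orientation(nodes, tets)
    vol = tet_volumes(nodes, tets)
    if vol.min() <= 1e-9:
        raise MeshingError(f"meniscus {side}: degenerate elements (min volume {vol.min():.3g})")

    tri, _ = boundary_faces(tets, nodes)
    facet_sets = _classify_structured_boundary(
        tri, grid_index, (nc, nr, nv),
        {(0, "lo"): "terminal_anterior", (0, "hi"): "terminal_posterior",
         (1, "lo"): "inner_wall", (1, "hi"): "outer_wall",
         (2, "lo"): "inferior", (2, "hi"): "superior"},
    )

    m = len(tets)
    part_name = PART_MENISCUS[side]
    mesh = FEMesh(
        nodes=nodes, tets=tets,
        part=np.full(m, part_name, dtype=object),
        region=np.full(m, "", dtype=object),
        zone=np.full(m, "", dtype=object),
        fiber_dir=np.zeros((m, 3)),
        facet_sets=facet_sets,
        meta={"kind": "meniscus", "side": side, "grid": (nc, nr, nv),
              "grid_index": grid_index, "shape": shape},
    )
    assign_fiber_directions(mesh)
    label_regions_zones(mesh, geometry)
    return mesh


def assign_fiber_directions(mesh: FEMesh) -> FEMesh:
    """Set each meniscal element's fiber direction to the local circumferential
    sweep tangent at its centroid.  Idempotent."""
    shape: MeniscusShape = mesh.meta.get("shape")
    if shape is None:
        raise MeshingError("mesh has no sweep parameterization (not a meniscus mesh)")
    cen = mesh.centroids()
    phi, _ = shape.polar(cen)
    mesh.fiber_dir[:] = shape.fiber_direction(phi)
    return mesh


def label_regions_zones(mesh: FEMesh, geometry: KneeGeometry) -> FEMesh:
    """Label meniscal elements by circumferential region tercile (anterior /
    middle / posterior) and radial zone tercile (inner white, middle
    red-white, outer red), from the element centroid's sweep coordinates.
    Labels depend only on centroid position, hence are resolution-invariant.
    """
    shape: MeniscusShape = mesh.meta.get("shape")
    if shape is None:
        raise MeshingError("mesh has no sweep parameterization (not a meniscus mesh)")
    cen = mesh.centroids()
    phi, s = shape.polar(cen)
    f = (phi - shape.arc_start_deg) / (shape.arc_end_deg - shape.arc_start_deg)
    mesh.region[:] = np.array(REGIONS, dtype=object)[
        np.clip((np.asarray(f) * 3).astype(int), 0, 2)]
    mesh.zone[:] = np.array(ZONES, dtype=object)[
        np.clip((np.asarray(s) * 3).astype(int), 0, 2)]
    return mesh


def _square_to_disk(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Area-preserving-ish elliptical mapping of [-1,1]^2 onto the unit disk."""
    return u * np.sqrt(1 - v**2 / 2), v * np.sqrt(1 - u**2 / 2)


def mesh_tibial_cartilage(geometry: KneeGeometry, compartment: str,
                          resolution: MeshResolution | None = None) -> FEMesh:
    """Layer mesh of one tibial cartilage compartment following the dish."""
    resolution = resolution or DEFAULT_RESOLUTION
    resolution.validate()
    dish = geometry.dishes[compartment]
    side = "MM" if compartment == "medial" else "LM"
    men = geometry.menisci[side]
    t = geometry.params.cartilage_thickness_tibial
    a_dom = min(men.r_outer + 2.0, dish.semiaxis_ml)
    b_dom = min(men.r_outer + 2.0, dish.semiaxis_ap)
    n, nz = resolution.cartilage_divisions, resolution.cartilage_layers
    g = np.linspace(-1.0, 1.0, n + 1)
    U, V, W = np.meshgrid(g, g, np.linspace(0.0, 1.0, nz + 1), indexing="ij")
    dx, dy = _square_to_disk(U, V)
    # local +x points laterally outward on both sides, so the medial and
    # lateral triangulations are exact sagittal mirrors of each other
    outward = -1.0 if compartment == "medial" else 1.0
    x = dish.center_x + outward * a_dom * dx
    y = b_dom * dy
    ztop = dish.z(x, y)
    z = ztop - t * (1.0 - W)
    nodes = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=-1)
    tets, grid_index = _structured_tets(n, n, nz)
    tets = _fix_orientation(nodes, tets)
    if tet_volumes(nodes, tets).min() <= 1e-9:
        raise MeshingError(f"tibial cartilage ({compartment}): degenerate elements")
    tri, _ = boundary_faces(tets, nodes)
    facet_sets = _classify_structured_boundary(
        tri, grid_index, (n, n, nz),
        {(2, "lo"): "bone", (2, "hi"): "articular",
         (0, "lo"): "rim", (0, "hi"): "rim2", (1, "lo"): "rim3", (1, "hi"): "rim4"},
    )
    facet_sets["rim"] = np.concatenate([facet_sets.pop(k) for k in ("rim", "rim2", "rim3", "rim4")])
    m = len(tets)
    part = "tibial_cartilage_med" if compartment == "medial" else "tibial_cartilage_lat"
    return FEMesh(nodes, tets, np.full(m, part, dtype=object),
                  np.full(m, "", dtype=object), np.full(m, "", dtype=object),
                  np.zeros((m, 3)), facet_sets,
                  {"kind": "tibial_cartilage", "compartment": compartment,
                   "grid": (n, n, nz), "grid_index": grid_index})


def mesh_femoral_cartilage(geometry: KneeGeometry, compartment: str,
                           resolution: MeshResolution | None = None) -> FEMesh:
    """Spherical-cap cartilage layer of one femoral condyle (reference pose)."""
    resolution = resolution or DEFAULT_RESOLUTION
    resolution.validate()
    condyle = geometry.condyles[compartment]
    t = condyle.cartilage_thickness
    aml = np.radians(geometry.params.condyle_cap_angle_ml_deg)
    aap = np.radians(geometry.params.condyle_cap_angle_ap_deg)
    n, nz = resolution.cartilage_divisions, resolution.cartilage_layers
    g = np.linspace(-1.0, 1.0, n + 1)
    U, V, W = np.meshgrid(g, g, np.linspace(0.0, 1.0, nz + 1), indexing="ij")
    d1, d2 = _square_to_disk(U, V)
    # elliptical cap: narrower medial-laterally than antero-posteriorly,
    # since flexion sweeps contact posteriorly but not sideways
    a1, a2 = aml * d1, aap * d2
    alpha = np.hypot(a1, a2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sindir = np.where(alpha > 1e-12, np.sin(alpha) / np.where(alpha > 1e-12, alpha, 1.0), 1.0)
    # mirrored local frames per side (see mesh_tibial_cartilage)
    outward = -1.0 if compartment == "medial" else 1.0
    dirs = np.stack([outward * a1 * sindir, a2 * sindir, -np.cos(alpha)], axis=-1)
    # k = 0 is the articular (outer) surface, k = nz the bone surface
    radius = condyle.bone_radius + t * (1.0 - W)
    nodes = (condyle.center + radius[..., None] * dirs).reshape(-1, 3)
    tets, grid_index = _structured_tets(n, n, nz)
    tets = _fix_orientation(nodes, tets)
    if tet_volumes(nodes, tets).min() <= 1e-9:
        raise MeshingError(f"femoral cartilage ({compartment}): degenerate elements")
    tri, _ = boundary_faces(tets, nodes)
    facet_sets = _classify_structured_boundary(
        tri, grid_index, (n, n, nz),
        {(2, "lo"): "articular", (2, "hi"): "bone",
         (0, "lo"): "rim", (0, "hi"): "rim2", (1, "lo"): "rim3", (1, "hi"): "rim4"},
    )
    facet_sets["rim"] = np.concatenate([facet_sets.pop(k) for k in ("rim", "rim2", "rim3", "rim4")])
    m = len(tets)
    return FEMesh(nodes, tets, np.full(m, "femoral_cartilage", dtype=object),
                  np.full(m, "", dtype=object), np.full(m, "", dtype=object),
                  np.zeros((m, 3)), facet_sets,
                  {"kind": "femoral_cartilage", "compartment": compartment,
                   "grid": (n, n, nz), "grid_index": grid_index})


def mesh_cartilage(geometry: KneeGeometry,
                   resolution: MeshResolution | None = None) -> dict:
    """All four cartilage part meshes keyed by name."""
    return {
        "femoral_cartilage_med": mesh_femoral_cartilage(geometry, "medial", resolution),
        "femoral_cartilage_lat": mesh_femoral_cartilage(geometry, "lateral", resolution),
        "tibial_cartilage_med": mesh_tibial_cartilage(geometry, "medial", resolution),
        "tibial_cartilage_lat": mesh_tibial_cartilage(geometry, "lateral", resolution),
    }


def mesh_box(nx: int, ny: int, nz: int,
             x: np.ndarray | float = 1.0, y: np.ndarray | float = 1.0,
             z: np.ndarray | float = 1.0, part: str = "block") -> FEMesh:
    """Structured tet mesh of a box; axes given as lengths or node-coordinate
    arrays (for graded grids).  Used by verification experiments and tests."""
    gx = np.linspace(0.0, x, nx + 1) if np.isscalar(x) else np.asarray(x, float)
    gy = np.linspace(0.0, y, ny + 1) if np.isscalar(y) else np.asarray(y, float)
    gz = np.linspace(0.0, z, nz + 1) if np.isscalar(z) else np.asarray(z, float)
    X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    tets, gi = _structured_tets(nx, ny, nz)
    tets = _fix_orientation(nodes, tets)
    m = len(tets)
    return FEMesh(nodes, tets, np.full(m, part, dtype=object),
                  np.full(m, "", dtype=object), np.full(m, "", dtype=object),
                  np.zeros((m, 3)), {},
                  {"kind": "box", "grid": (nx, ny, nz), "grid_index": gi})


def transform_mesh(mesh: FEMesh, xform) -> FEMesh:
    """Rigidly transform a mesh (nodes and fiber directions)."""
    out = mesh.copy()
    out.nodes = xform.apply(mesh.nodes)
    out.fiber_dir = mesh.fiber_dir @ xform.R.T
    return out


def merge_meshes(named_meshes: dict) -> FEMesh:
    """Concatenate part meshes into one model mesh.

    Facet sets are namespaced as ``"<name>/<set>"``; node offsets per part
    are kept in ``meta['offsets']`` and the source meshes in
    ``meta['sources']``.
    """
    nodes, tets, part, region, zone, fiber = [], [], [], [], [], []
    facet_sets, offsets, elem_offsets = {}, {}, {}
    n_off = e_off = 0
    for name, mesh in named_meshes.items():
        offsets[name] = n_off
        elem_offsets[name] = e_off
        nodes.append(mesh.nodes)
        tets.append(mesh.tets + n_off)
        part.append(mesh.part)
        region.append(mesh.region)
        zone.append(mesh.zone)
        fiber.append(mesh.fiber_dir)
        for sname, tri in mesh.facet_sets.items():
            facet_sets[f"{name}/{sname}"] = tri + n_off
        n_off += mesh.n_nodes
        e_off += mesh.n_elements
    return FEMesh(np.concatenate(nodes), np.concatenate(tets),
                  np.concatenate(part), np.concatenate(region),
                  np.concatenate(zone), np.concatenate(fiber), facet_sets,
                  {"offsets": offsets, "elem_offsets": elem_offsets,
                   "sources": dict(named_meshes)})
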