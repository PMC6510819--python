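"""Insertion of longitudinal and radial meniscal tears by node duplication.

Tears are realized on existing element faces (snap-to-mesh): a connected set
of interior triangular facets approximating the specified tear plane is
selected, the nodes strictly interior to it are duplicated, and elements on
the positive side are reconnected to the copies.  Element count and total
volume are unchanged; the two tear faces are geometrically coincident in the
unloaded state and are enrolled as a frictional self-contact pair.

Taxonomy: full-thickness vertical longitudinal tears (parallel to the
circumferential fibers) are centered radially at s = 5/6 — the center of the
outer (red) third — and are 7 mm (stable) or 14 mm (unstable) long.  Radial
tears start at the inner rim (white zone) and extend outward over 1/6
(stable) or 1/2 (unstable) of the local rim width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact import ContactPair, tributary_areas
from .meshing import FEMesh, tet_volumes

LONGITUDINAL_LENGTHS = {"stable": 7.0, "unstable": 14.0}   # mm
RADIAL_FRACTIONS = {"stable": 1.0 / 6.0, "unstable": 0.5}  # of local rim width
LONGITUDINAL_RADIAL_CENTER = 5.0 / 6.0                     # center of red zone


class TearSpecError(ValueError):
    """Invalid or unachievable tear specification."""


@dataclass(frozen=True)
class TearSpec:
    """Tear taxonomy: type, meniscus, circumferential region, stability."""

    tear_type: str                 # 'longitudinal' | 'radial'
    meniscus: str                  # 'MM' | 'LM'
    region: str                    # 'anterior' | 'middle' | 'posterior'
    stability: str                 # 'stable' | 'unstable'
    length_mm: float | None = None       # longitudinal override
    rim_fraction: float | None = None    # radial override

    def __post_init__(self) -> None:
        if self.tear_type not in ("longitudinal", "radial"):
            raise TearSpecError(f"unknown tear type {self.tear_type!r}")
        if self.meniscus not in ("MM", "LM"):
            raise TearSpecError(f"unknown meniscus {self.meniscus!r}")
        if self.region not in ("anterior", "middle", "posterior"):
            raise TearSpecError(f"unknown region {self.region!r}")
        if self.stability not in ("stable", "unstable"):
            raise TearSpecError(f"unknown stability {self.stability!r}")

    @property
    def target_length(self) -> float:
        if self.tear_type != "longitudinal":
            raise TearSpecError("length is defined for longitudinal tears")
        return self.length_mm if self.length_mm is not None else \
            LONGITUDINAL_LENGTHS[self.stability]

    @property
    def target_fraction(self) -> float:
        if self.tear_type != "radial":
            raise TearSpecError("rim fraction is defined for radial tears")
        return self.rim_fraction if self.rim_fraction is not None else \
            RADIAL_FRACTIONS[self.stability]

    @property
    def label(self) -> str:
        return f"{self.meniscus}_{self.region}_{self.tear_type}_{self.stability}"


@dataclass
class TearSurface:
    """Snap-to-mesh internal facet path realizing a tear plane."""

    spec: TearSpec
    facets: np.ndarray            # (F, 3) node indices (interior triangles)
    front_nodes: np.ndarray       # nodes that remain shared (tear front/apex)
    side_fn: object               # callable(points) -> bool array (True = + side)
    achieved_length: float        # mm (longitudinal) arc length on the surface
    achieved_fraction: float      # radial extent fraction of rim width
    apex_nodes: np.ndarray = None # radial: outermost front column


@dataclass
class TearTopology:
    """Bookkeeping of a performed mesh split."""

    spec: TearSpec
    node_pairs: np.ndarray        # (P, 2): (original, duplicate)
    face_neg: np.ndarray          # (F, 3) tear face bordering the - side
    face_pos: np.ndarray          # (F, 3) tear face bordering the + side
    front_nodes: np.ndarray
    apex_nodes: np.ndarray
    original_node_count: int
    achieved_length: float
    achieved_fraction: float
    node_map: np.ndarray = None   # torn-node -> original-node index map


def _meniscus_grid(mesh: FEMesh):
    if mesh.meta.get("kind") != "meniscus":
        raise TearSpecError("tears can only be inserted into a meniscus mesh")
    return mesh.meta["grid"], mesh.meta["grid_index"], mesh.meta["shape"]


def locate_tear_surface(mesh: FEMesh, spec: TearSpec) -> TearSurface:
    """Select the interior facet path realizing a tear spec on a meniscus mesh.

    Returns the path plus the achieved arc length (longitudinal) or radial
    extent fraction (radial), which quantify the snap-to-mesh discretization
    of the requested 7/14 mm lengths and 1/6 / 1/2 rim-width fractions.
    """
    (nc, nr, nv), grid_index, shape = _meniscus_grid(mesh)
    if mesh.meta.get("side") != spec.meniscus:
        raise TearSpecError(
            f"spec targets {spec.meniscus} but mesh is {mesh.meta.get('side')}")

    span = shape.arc_end_deg - shape.arc_start_deg
    region_index = ("anterior", "middle", "posterior").index(spec.region)
    phi_grid = shape.arc_start_deg + span * np.arange(nc + 1) / nc

    gi = grid_index
    tet_gi = gi[mesh.tets]  # (M, 4, 3)

    if spec.tear_type == "longitudinal":
        length = spec.target_length
        if length <= 0:
            raise TearSpecError("requested tear length must be > 0 (empty path)")
        j_star = round(LONGITUDINAL_RADIAL_CENTER * nr)
        if not (0 < j_star < nr):
            raise TearSpecError("resolution too coarse for an interior tear plane")
        s_star = j_star / nr
        r_star = shape.r_inner + s_star * shape.rim_width
        edge_len = r_star * np.radians(span) / nc
        n_edges = max(2, round(length / edge_len))
        region_cells = nc / 3.0
        if n_edges > region_cells:
            raise TearSpecError(
                f"requested length {length} mm spans {n_edges} element edges, "
                f"exceeding the {spec.region} region extent ({region_cells:.0f} cells)")
        center_cell = (2 * region_index + 1) * nc / 6.0
        i0 = int(round(center_cell - n_edges / 2.0))
        i0 = max(0, min(i0, nc - n_edges))
        i1 = i0 + n_edges
        achieved = n_edges * edge_len

        node_on = ((gi[:, 1] == j_star) & (gi[:, 0] >= i0) & (gi[:, 0] <= i1))
        front = node_on & ((gi[:, 0] == i0) | (gi[:, 0] == i1))
        phi_mid = 0.5 * (phi_grid[i0] + phi_grid[i1])

        def side_fn(points):
            _, s = shape.polar(points)
            return s > s_star

        surface = TearSurface(spec, _facets_on(mesh, tet_gi, node_on),
                              np.flatnonzero(front), side_fn,
                              achieved_length=float(achieved),
                              achieved_fraction=0.0,
                              apex_nodes=np.flatnonzero(front))
    else:
        frac = spec.target_fraction
        if frac <= 0:
            raise TearSpecError("requested rim fraction must be > 0 (empty path)")
        j_ext = max(1, round(frac * nr))
        if j_ext >= nr:
            raise TearSpecError("radial tear may not sever the full rim width")
        achieved_frac = j_ext / nr
        center_line = round((2 * region_index + 1) * nc / 6.0)
        i_star = int(min(max(center_line, 1), nc - 1))
        phi_star = phi_grid[i_star]

        node_on = (gi[:, 0] == i_star) & (gi[:, 1] <= j_ext)
        front = node_on & (gi[:, 1] == j_ext)

        def side_fn(points, _phi_star=phi_star):
            phi, _ = shape.polar(points)
            return phi > _phi_star

        surface = TearSurface(spec, _facets_on(mesh, tet_gi, node_on),
                              np.flatnonzero(front), side_fn,
                              achieved_length=0.0,
                              achieved_fraction=float(achieved_frac),
                              apex_nodes=np.flatnonzero(front))
    if len(surface.facets) == 0:
        raise TearSpecError("tear surface selection produced an empty facet path")
    return surface


def _facets_on(mesh: FEMesh, tet_gi: np.ndarray, node_on: np.ndarray) -> np.ndarray:
    """Interior triangular tet faces whose three nodes all lie on the tear plane."""
    faces_idx = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    faces = mesh.tets[:, faces_idx].reshape(-1, 3)
    on = node_on[faces].all(axis=1)
    tri = faces[on]
    key = np.sort(tri, axis=1)
    # interior faces appear exactly twice (once per adjacent element)
    _, first, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return tri[first[counts == 2]]


def split_mesh(mesh: FEMesh, surface: TearSurface) -> tuple[FEMesh, TearTopology]:
    """Duplicate the interior tear-surface nodes and reconnect the + side.

    Tear-front nodes stay shared, so element count is unchanged, node count
    grows by exactly the number of interior surface nodes, all element
    volumes stay positive, and the two faces coincide while unloaded.
    """
    surf_nodes = np.unique(surface.facets)
    front = np.asarray(surface.front_nodes, dtype=int)
    dup = np.setdiff1d(surf_nodes, front)
    if len(dup) == 0:
        raise TearSpecError("tear surface has no interior nodes to split "
                            "(resolution too coarse)")

    out = mesh.copy()
    n0 = mesh.n_nodes
    new_ids = n0 + np.arange(len(dup))
    out.nodes = np.vstack([mesh.nodes, mesh.nodes[dup]])
    remap = np.arange(n0 + len(dup))

    lookup = np.full(n0, -1, dtype=int)
    lookup[dup] = new_ids

    # orient tear facets so their normals point toward the + side (the side
    # that will be reconnected to the duplicates); needed for the tear-face
    # contact pair's gap sign.  Orientation is decided from the adjacent
    # element on the - side, which is exact even for chorded facets.
    facets = surface.facets.copy()
    cen = mesh.centroids()
    elem_side = np.asarray(surface.side_fn(cen), dtype=bool)
    node_elems: dict[int, set] = {}
    for e, tet in enumerate(mesh.tets):
        for nd in tet:
            node_elems.setdefault(int(nd), set()).add(e)
    for k, tri in enumerate(facets):
        adj = node_elems[int(tri[0])] & node_elems[int(tri[1])] & node_elems[int(tri[2])]
        neg = [e for e in adj if not elem_side[e]]
        if not neg:
            raise TearSpecError("tear facet has no adjacent element on the - side")
        tet = mesh.tets[neg[0]]
        opp = [nd for nd in tet if nd not in tri][0]
        p = mesh.nodes[tri]
        n = np.cross(p[1] - p[0], p[2] - p[0])
        if np.dot(n, p.mean(axis=0) - mesh.nodes[opp]) < 0:
            facets[k] = tri[[0, 2, 1]]
    surface = TearSurface(surface.spec, facets, surface.front_nodes,
                          surface.side_fn, surface.achieved_length,
                          surface.achieved_fraction, surface.apex_nodes)

    pos_side = np.asarray(surface.side_fn(cen), dtype=bool)
    touches = np.isin(mesh.tets, dup).any(axis=1)
    swap_elems = np.flatnonzero(pos_side & touches)
    tets = out.tets
    sub = tets[swap_elems]
    repl = lookup[sub]
    tets[swap_elems] = np.where(repl >= 0, repl, sub)
    out.tets = tets

    if tet_volumes(out.nodes, out.tets).min() <= 0:
        raise TearSpecError("tear insertion produced inverted elements")

    # facet sets referencing duplicated nodes: keep original (- side) labels;
    # append explicit tear faces
    face_neg = surface.facets
    repl_f = lookup[face_neg]
    face_pos = np.where(repl_f >= 0, repl_f, face_neg)
    out.facet_sets = dict(out.facet_sets)
    out.facet_sets["tear_face_neg"] = face_neg
    out.facet_sets["tear_face_pos"] = face_pos

    # grid bookkeeping for duplicated nodes
    if "grid_index" in out.meta:
        gi = out.meta["grid_index"]
        out.meta = dict(out.meta)
        out.meta["grid_index"] = np.vstack([gi, gi[dup]])

    node_map = np.concatenate([np.arange(n0), dup])
    topo = TearTopology(
        spec=surface.spec,
        node_pairs=np.stack([dup, new_ids], axis=1),
        face_neg=face_neg, face_pos=face_pos,
        front_nodes=front, apex_nodes=np.asarray(surface.apex_nodes, dtype=int),
        original_node_count=n0,
        achieved_length=surface.achieved_length,
        achieved_fraction=surface.achieved_fraction,
        node_map=node_map)
    out.meta["tear"] = topo
    return out, topo


def merge_tear(mesh: FEMesh, topology: TearTopology) -> FEMesh:
    """Undo a split: collapse duplicate pairs back to the original nodes."""
    out = mesh.copy()
    n0 = topology.original_node_count
    lookup = np.arange(mesh.n_nodes)
    lookup[topology.node_pairs[:, 1]] = topology.node_pairs[:, 0]
    out.tets = lookup[mesh.tets]
    out.nodes = mesh.nodes[:n0]
    out.facet_sets = {k: lookup[v] for k, v in mesh.facet_sets.items()
                      if not k.startswith("tear_face")}
    if "grid_index" in out.meta:
        out.meta = dict(out.meta)
        out.meta["grid_index"] = out.meta["grid_index"][:n0]
        out.meta.pop("tear", None)
    return out


def insert_tear(mesh: FEMesh, spec: TearSpec) -> tuple[FEMesh, TearTopology]:
    """Locate and split in one call."""
    surface = locate_tear_surface(mesh, spec)
    return split_mesh(mesh, surface)


def tear_contact_pairs(mesh: FEMesh, topology: TearTopology,
                       friction_mu: float = 0.02,
                       penalty_normal: float = 650.0,
                       node_offset: int = 0) -> ContactPair:
    """Frictional self-contact pair between the two tear faces.

    ``node_offset`` shifts indices when the meniscus mesh has been merged
    into a multi-part model mesh.
    """
    slave = np.unique(topology.face_pos) + node_offset
    areas = tributary_areas(mesh.nodes, topology.face_pos, slave - node_offset)
    # orient the - face outward of the - side solid (toward the + side):
    # winding of face_neg came from boundary-style extraction on interior
    # facets, so orient by the local fiber/plane geometry instead: flip so
    # normals point from - face toward the matching + slave nodes' side.
    return ContactPair(
        name=f"tear_{topology.spec.label}",
        slave_nodes=slave, slave_areas=areas,
        master=topology.face_neg + node_offset,
        friction_mu=friction_mu, penalty_normal=penalty_normal,
        kind="tear-face self-contact", search_radius=1.0)
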