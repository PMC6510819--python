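"""Outcome measures computed from solved fields.

Hoop stress is operationalized as the maximum principal stress (max PCS),
with the fiber-projected normal stress available as a cross-check; the
compressive contact indicator is the minimum principal stress (min PCS).
All reports are pure functions of (solution, mesh): repeated evaluation is
bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import cKDTree

from .materials import principal_stresses
from .meshing import FEMesh
from .tears import TearTopology


class ReportError(ValueError):
    pass


# -- generic field sampling --------------------------------------------------

def nodal_stress_recovery(mesh: FEMesh, stress: np.ndarray) -> np.ndarray:
    """Volume-weighted average of element Voigt stresses at the nodes."""
    vols = mesh.volumes()
    acc = np.zeros((mesh.n_nodes, 6))
    wacc = np.zeros(mesh.n_nodes)
    w = np.repeat(vols, 4)
    np.add.at(acc, mesh.tets.ravel(), stress.repeat(4, axis=0) * w[:, None])
    np.add.at(wacc, mesh.tets.ravel(), w)
    return acc / np.maximum(wacc, 1e-30)[:, None]


def _barycentric(tet_nodes: np.ndarray, p: np.ndarray) -> np.ndarray:
    M = np.concatenate([np.ones((len(tet_nodes), 4, 1)), tet_nodes], axis=2)
    rhs = np.concatenate([np.ones((len(p), 1)), p], axis=1)
    return np.linalg.solve(np.transpose(M, (0, 2, 1)), rhs[..., None])[..., 0]


def interpolate_voigt(mesh: FEMesh, nodal_field: np.ndarray, points: np.ndarray,
                      element_subset: np.ndarray | None = None,
                      k_candidates: int = 30) -> np.ndarray:
    """Interpolate a nodal Voigt field at arbitrary points.

    Locates the containing tet among KD-tree candidates (restricted to
    ``element_subset`` if given) and interpolates barycentrically; falls back
    to the nearest candidate element if a point sits marginally outside the
    mesh (for instance on a curved boundary).
    """
    elems = np.arange(mesh.n_elements) if element_subset is None else element_subset
    cents = mesh.centroids()[elems]
    tree = cKDTree(cents)
    k = min(k_candidates, len(elems))
    _, cand = tree.query(points, k=k)
    cand = cand[:, None] if cand.ndim == 1 else cand
    out = np.zeros((len(points), nodal_field.shape[1]))
    for i, p in enumerate(points):
        cand_elems = elems[cand[i]]
        bar = _barycentric(mesh.nodes[mesh.tets[cand_elems]], np.tile(p, (len(cand_elems), 1)))
        # containment score: most-negative barycentric coordinate
        score = bar.min(axis=1)
        best = int(np.argmax(score))
        wts = np.clip(bar[best], 0.0, None)
        wts = wts / wts.sum()
        out[i] = wts @ nodal_field[mesh.tets[cand_elems[best]]]
    return out


# -- transects ---------------------------------------------------------------

@dataclass
class TransectProfile:
    """Max PCS sampled inner rim (s = 0) to outer rim (s = 1) at the mid-arc,
    mid-height line of one circumferential region."""

    meniscus: str
    region: str
    flexion_angle: float
    s: np.ndarray
    max_pcs: np.ndarray

    def to_dict(self) -> dict:
        d = asdict(self)
        d["s"] = self.s.tolist()
        d["max_pcs"] = self.max_pcs.tolist()
        return d


def _part_mask(mesh: FEMesh, meniscus: str) -> np.ndarray:
    return mesh.part == f"meniscus_{meniscus}"


def _meniscus_shape_from(mesh: FEMesh, meniscus: str):
    sources = mesh.meta.get("sources", {})
    for src in sources.values():
        if src.meta.get("kind") == "meniscus" and src.meta.get("side") == meniscus:
            return src.meta["shape"]
    if mesh.meta.get("kind") == "meniscus" and mesh.meta.get("side") == meniscus:
        return mesh.meta["shape"]
    raise ReportError(f"mesh does not contain meniscus {meniscus}")


def sample_transect(solution, mesh: FEMesh, meniscus: str, region: str,
                    n_samples: int = 13, flexion_angle: float = 0.0) -> TransectProfile:
    """Sample max PCS along the regional mid-arc transect, inner to outer rim."""
    shape = _meniscus_shape_from(mesh, meniscus)
    mask = _part_mask(mesh, meniscus)
    elems = np.flatnonzero(mask & (mesh.region == region))
    if len(elems) == 0:
        raise ReportError(f"region {region!r} of {meniscus} has no elements")
    span = shape.arc_end_deg - shape.arc_start_deg
    frac_mid = {"anterior": 1 / 6, "middle": 1 / 2, "posterior": 5 / 6}[region]
    phi_mid = shape.arc_start_deg + frac_mid * span
    s = np.linspace(0.0, 1.0, n_samples)
    pts = shape.point(np.full(n_samples, phi_mid), s, np.full(n_samples, 0.5))
    nodal = nodal_stress_recovery(mesh, solution.stress)
    sigma = interpolate_voigt(mesh, nodal, pts, element_subset=np.flatnonzero(mask))
    pcs = principal_stresses(sigma)[:, 0]
    return TransectProfile(meniscus, region, flexion_angle, s, pcs)


# -- tear-surface reports ----------------------------------------------------

@dataclass
class TearSurfaceReport:
    """Hoop stress on the two faces of a longitudinal tear.

    ``difference`` = outer - inner; positive differences press the tear
    surfaces together and are classified favourable (strict inequality: a
    tie is unfavourable).
    """

    meniscus: str
    region: str
    stability: str
    flexion_angle: float
    inner_face_hoop: float      # MPa (max PCS mean over inner-face elements)
    outer_face_hoop: float
    difference: float
    favourable: bool
    inner_face_fiber_stress: float  # fiber-projected normal stress cross-check
    outer_face_fiber_stress: float


def _face_adjacent_elements(mesh: FEMesh, face: np.ndarray) -> np.ndarray:
    node_set = np.zeros(mesh.n_nodes, bool)
    node_set[np.unique(face)] = True
    count = node_set[mesh.tets].sum(axis=1)
    return np.flatnonzero(count >= 3)


def _fiber_normal_stress(stress: np.ndarray, fiber: np.ndarray) -> np.ndarray:
    """sigma_ff = f . sigma . f from Voigt components."""
    s = stress
    f = fiber
    return (f[:, 0] ** 2 * s[:, 0] + f[:, 1] ** 2 * s[:, 1] + f[:, 2] ** 2 * s[:, 2]
            + 2 * f[:, 1] * f[:, 2] * s[:, 3] + 2 * f[:, 0] * f[:, 2] * s[:, 4]
            + 2 * f[:, 0] * f[:, 1] * s[:, 5])


def tear_surface_difference(solution, mesh: FEMesh, topology: TearTopology,
                            node_offset: int = 0,
                            flexion_angle: float = 0.0) -> TearSurfaceReport:
    """Stress difference across a longitudinal tear interface."""
    if topology.spec.tear_type != "longitudinal":
        raise ReportError(
            "tear-surface hoop difference is defined for longitudinal tears; "
            "use apex_stress_delta for radial tears")
    inner_elems = _face_adjacent_elements(mesh, topology.face_neg + node_offset)
    outer_elems = _face_adjacent_elements(mesh, topology.face_pos + node_offset)
    if len(inner_elems) == 0 or len(outer_elems) == 0:
        raise ReportError("no elements adjacent to the tear faces")
    pcs = principal_stresses(solution.stress)[:, 0]
    fib = _fiber_normal_stress(solution.stress, mesh.fiber_dir)
    inner = float(pcs[inner_elems].mean())
    outer = float(pcs[outer_elems].mean())
    diff = outer - inner
    return TearSurfaceReport(
        meniscus=topology.spec.meniscus, region=topology.spec.region,
        stability=topology.spec.stability, flexion_angle=flexion_angle,
        inner_face_hoop=inner, outer_face_hoop=outer, difference=diff,
        favourable=bool(diff > 0.0),
        inner_face_fiber_stress=float(fib[inner_elems].mean()),
        outer_face_fiber_stress=float(fib[outer_elems].mean()))


@dataclass
class ApexReport:
    """Max PCS at the tear apex versus the intact model at the same material
    points; positive delta = added tension, negative = added compression."""

    meniscus: str
    region: str
    stability: str
    flexion_angle: float
    apex_max_pcs_torn: float
    apex_max_pcs_intact: float
    delta: float


def apex_stress_delta(solution_torn, solution_intact, mesh_torn: FEMesh,
                      topology: TearTopology, node_offset: int = 0,
                      flexion_angle: float = 0.0) -> ApexReport:
    """Apex stress concentration of a (radial) tear relative to intact.

    Torn and intact models must share the element ordering (tear insertion
    preserves it), so the delta is taken at identical material points.
    """
    if len(solution_torn.stress) != len(solution_intact.stress):
        raise ReportError("torn and intact runs have mismatched element counts")
    apex = topology.apex_nodes + node_offset
    node_set = np.zeros(mesh_torn.n_nodes, bool)
    node_set[apex] = True
    elems = np.flatnonzero(node_set[mesh_torn.tets].any(axis=1))
    if len(elems) == 0:
        raise ReportError("no elements adjacent to the tear apex")
    pcs_t = principal_stresses(solution_torn.stress[elems])[:, 0]
    pcs_i = principal_stresses(solution_intact.stress[elems])[:, 0]
    return ApexReport(
        meniscus=topology.spec.meniscus, region=topology.spec.region,
        stability=topology.spec.stability, flexion_angle=flexion_angle,
        apex_max_pcs_torn=float(pcs_t.mean()),
        apex_max_pcs_intact=float(pcs_i.mean()),
        delta=float(pcs_t.mean() - pcs_i.mean()))


# -- compartment contact -----------------------------------------------------

@dataclass
class CompartmentContact:
    side: str                    # 'medial' | 'lateral'
    peak_pressure: float         # |min principal stress| peak in tibial cartilage, MPa
    contact_area: float          # mm^2 of master facets carrying contact
    centroid: np.ndarray         # force-weighted contact centroid, mm


def compartment_contact_metrics(solution, model) -> dict:
    """Peak compressive stress, active contact area and centroid per side.

    ``model`` is the assembled knee model (mesh + contact pairs); the area is
    the summed area of master facets on the tibial articular surfaces that
    carry at least one active contact projection.
    """
    mesh = model.mesh
    out = {}
    for side, part in (("medial", "tibial_cartilage_med"),
                       ("lateral", "tibial_cartilage_lat")):
        elems = np.flatnonzero(mesh.part == part)
        pcs_min = principal_stresses(solution.stress[elems])[:, 2] if len(elems) else np.zeros(0)
        peak = float(-min(pcs_min.min(), 0.0)) if len(elems) else 0.0

        area = 0.0
        wsum = 0.0
        cen = np.zeros(3)
        for pair in model.contact_pairs:
            if pair.is_rigid or side[:3] not in pair.name:
                continue
            if "tib" not in pair.name:
                continue
            state = solution.contact.get(pair.name)
            if state is None or state.fn is None or not len(state.active):
                continue
            tris = pair.master[np.unique(state.facet)]
            p = mesh.nodes[tris]
            area += float(np.sum(0.5 * np.linalg.norm(
                np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)))
            pos = mesh.nodes[pair.slave_nodes[state.active]] + \
                solution.u[pair.slave_nodes[state.active]]
            cen += (state.fn[:, None] * pos).sum(axis=0)
            wsum += state.fn.sum()
        out[side] = CompartmentContact(
            side=side, peak_pressure=peak, contact_area=area,
            centroid=cen / wsum if wsum > 0 else np.full(3, np.nan))
    return out


# -- segment displacements ---------------------------------------------------

@dataclass
class SegmentDisplacement:
    """Displacement of a meniscal segment between two load cases.

    Sign conventions: AP positive anterior (+y), ML positive medial (-x).
    """

    meniscus: str
    segment: str                 # 'anterior' | 'posterior' | 'midsection'
    ap_mm: float
    ml_mm: float
    interval: tuple


def segment_displacements(solution_a, solution_b, mesh: FEMesh,
                          interval: tuple = (0.0, 20.0)) -> list:
    """Anterior/posterior segment AP motion and midsection ML motion between
    two flexion angles solved on the same mesh."""
    if solution_a.u.shape != solution_b.u.shape:
        raise ReportError("solutions live on different meshes")
    du = solution_b.u - solution_a.u
    reports = []
    for side in ("MM", "LM"):
        mask = _part_mask(mesh, side)
        for segment, region in (("anterior", "anterior"), ("posterior", "posterior")):
            elems = np.flatnonzero(mask & (mesh.region == region))
            nodes = np.unique(mesh.tets[elems])
            d = du[nodes].mean(axis=0)
            reports.append(SegmentDisplacement(side, segment,
                                               ap_mm=float(d[1]), ml_mm=float(-d[0]),
                                               interval=interval))
        # midsection: most-external point (max radial distance from the
        # compartment center)
        shape = _meniscus_shape_from(mesh, side)
        elems = np.flatnonzero(mask & (mesh.region == "middle"))
        nodes = np.unique(mesh.tets[elems])
        radial = np.hypot(mesh.nodes[nodes, 0] - shape.center_x, mesh.nodes[nodes, 1])
        ext = nodes[int(np.argmax(radial))]
        reports.append(SegmentDisplacement(side, "midsection",
                                           ap_mm=float(du[ext, 1]),
                                           ml_mm=float(-du[ext, 0]),
                                           interval=interval))
    return reports


def plot_transects(profiles: list, path) -> None:
    """Plot hoop-stress transects (one panel per meniscus x region) as an
    image file; lines are flexion angles."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    menisci = sorted({p.meniscus for p in profiles})
    regions = ["anterior", "middle", "posterior"]
    fig, axes = plt.subplots(len(menisci), len(regions),
                             figsize=(11, 3.2 * len(menisci)),
                             sharex=True, squeeze=False)
    for i, men in enumerate(menisci):
        for j, region in enumerate(regions):
            ax = axes[i][j]
            for p in profiles:
                if p.meniscus == men and p.region == region:
                    ax.plot(p.s, p.max_pcs, label=f"{p.flexion_angle:g}\u00b0")
            ax.set_title(f"{men} {region}")
            if i == len(menisci) - 1:
                ax.set_xlabel("normalised length (inner \u2192 outer rim)")
            if j == 0:
                ax.set_ylabel("max PCS (MPa)")
    axes[0][0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
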