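"""Assembly of the full tibiofemoral FE model for one load case.

Pipeline per case: analytic geometry -> part meshes -> optional tear
insertion -> femur posing and seating -> merged model with materials,
insertional-ligament springs, contact pairs and boundary conditions.

Load cases follow the study protocol: compressive load applied to the femur
along the tibial long axis (375 N half body weight for validation poses,
750 N full body weight for all tear simulations) at 0/20/30 degrees of
flexion; femur free in medial-lateral translation, axial translation and
varus-valgus rotation; tibia fully fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry as geo
from .contact import ContactPair, tributary_areas
from .fem import (FEModel, LIGAMENT_STIFFNESS, RigidBodyConstraint, SolverParams,
                  SolutionField, SpringLigament)
from .materials import (CARTILAGE_DEFAULT, MENISCUS_DEFAULT, IsotropicElastic,
                        TransverselyIsotropicElastic, stiffness_isotropic,
                        stiffness_transverse_isotropic_batch)
from .meshing import (DEFAULT_RESOLUTION, FEMesh, MeshResolution, merge_meshes,
                      mesh_femoral_cartilage, mesh_meniscus, mesh_tibial_cartilage,
                      transform_mesh)
from .tears import TearSpec, TearTopology, insert_tear, tear_contact_pairs
from .transforms import RigidTransform

HALF_BODY_WEIGHT = 375.0   # N
FULL_BODY_WEIGHT = 750.0   # N


def default_penalty(cartilage: IsotropicElastic, meniscus: TransverselyIsotropicElastic,
                    char_length: float = 1.0, scale: float = 50.0) -> float:
    """Penalty stiffness: ``scale`` x the softest participating modulus per
    unit characteristic length (1 mm), sized so equilibrium penetrations stay
    below 1% of the cartilage thickness."""
    softest = min(cartilage.E, meniscus.E_p)
    return scale * softest / char_length


@dataclass
class KneeLoadCase:
    flexion_angle: float = 0.0
    axial_load: float = FULL_BODY_WEIGHT
    screw_home_coupling_deg: float = 5.0
    rollback_mm_per_deg: float = 0.1


@dataclass
class KneeModel:
    """Assembled knee FE model plus the bookkeeping postprocessing needs."""

    geometry: geo.KneeGeometry
    load_case: KneeLoadCase
    pose: geo.BonePose
    seat_shift: float
    mesh: FEMesh                  # merged model mesh
    fe: FEModel
    resolution: MeshResolution
    tear: TearTopology | None
    tear_node_offset: int
    part_meshes: dict = field(repr=False, default_factory=dict)

    @property
    def contact_pairs(self):
        return self.fe.contact_pairs

    def solve(self, params: SolverParams | None = None,
              warm_from: SolutionField | None = None) -> SolutionField:
        """Solve the load case.  ``warm_from`` accepts the solution of the
        intact model of the same load case as an initial guess (torn-model
        duplicates inherit their original node's displacement); otherwise the
        menisci are warm-started by convecting them with the femur pose."""
        if warm_from is not None:
            u0 = self.map_intact_displacement(warm_from)
        else:
            u0 = self.warm_start_displacement()
        return self.fe.solve(params, initial_guess=u0)

    def map_intact_displacement(self, solution: SolutionField) -> np.ndarray:
        u0 = np.zeros((self.mesh.n_nodes, 3))
        offsets = self.mesh.meta["offsets"]
        sources = self.mesh.meta["sources"]
        src_off = 0
        for name, src_mesh in sources.items():
            o = offsets[name]
            n = src_mesh.n_nodes
            topo = src_mesh.meta.get("tear")
            if topo is not None:
                n_orig = topo.original_node_count
                u0[o:o + n] = solution.u[src_off + topo.node_map]
                src_off += n_orig
            else:
                u0[o:o + n] = solution.u[src_off:src_off + n]
                src_off += n
        return u0.reshape(-1)

    def warm_start_displacement(self) -> np.ndarray:
        """Initial Newton guess: menisci convect with the in-plane part of
        the femur pose (twist + rollback, no flexion or seating), emulating
        how they track the bones during flexion; everything else starts at
        zero.  Pure initial guess -- the converged solution is unaffected."""
        u0 = np.zeros((self.mesh.n_nodes, 3))
        lc = self.load_case
        psi = -lc.screw_home_coupling_deg * min(lc.flexion_angle, 20.0) / 20.0
        twist = RigidTransform.about_axis([0, 0, 1.0], psi)
        roll = RigidTransform.translation(
            [0.0, -lc.rollback_mm_per_deg * lc.flexion_angle, 0.0])
        xf = roll.compose(twist)
        offsets = self.mesh.meta["offsets"]
        sources = self.mesh.meta["sources"]
        for name, src_mesh in sources.items():
            if not name.startswith("meniscus"):
                continue
            o = offsets[name]
            pts = self.mesh.nodes[o:o + src_mesh.n_nodes]
            disp = xf.apply(pts) - pts
            disp[:, 2] = 0.0
            u0[o:o + src_mesh.n_nodes] = disp
        return u0.reshape(-1)

    def node_offset(self, part: str) -> int:
        return self.mesh.meta["offsets"][part]

    def tibia_vertical_reaction(self, solution: SolutionField) -> float:
        """Summed vertical reaction on the fully constrained tibia: fixed
        bone-bonded cartilage nodes plus the insertional-ligament grounds."""
        fixed = self.fe.fixed_nodes
        # support force on the structure at the fixed bone-bonded nodes ...
        rz = solution.reactions.reshape(-1, 3)[fixed, 2].sum()
        # ... plus the spring ground forces: the ground pulls each horn node
        # with f, so the joint pushes the tibia with -f (Newton's third law);
        # the tibia's total vertical reaction magnitude is the sum of both.
        for rec in solution.springs.values():
            rz += rec["nodal_forces"][:, 2].sum()
        return float(rz)


def _vertical_clearance(points: np.ndarray, geometry: geo.KneeGeometry) -> np.ndarray:
    """Vertical gap from points down to the tibial-side surfaces (cartilage
    top or meniscus superior surface), evaluated analytically."""
    z_target = np.full(len(points), -np.inf)
    for comp in ("medial", "lateral"):
        dish = geometry.dishes[comp]
        men = geometry.menisci["MM" if comp == "medial" else "LM"]
        inside = (np.abs(points[:, 0] - dish.center_x) < dish.semiaxis_ml) & \
                 (np.abs(points[:, 1]) < dish.semiaxis_ap)
        zt = np.where(inside, dish.z(points[:, 0], points[:, 1]), -np.inf)
        z_target = np.maximum(z_target, zt)
        phi, s = men.polar(points)
        on_men = (s >= 0) & (s <= 1) & (phi >= men.arc_start_deg) & (phi <= men.arc_end_deg)
        zm = np.where(on_men, dish.z(points[:, 0], points[:, 1]) + men.height(np.clip(s, 0, 1)),
                      -np.inf)
        z_target = np.maximum(z_target, zm)
    return points[:, 2] - z_target


def build_knee_model(
    geometry: geo.KneeGeometry | None = None,
    load_case: KneeLoadCase | None = None,
    resolution: MeshResolution | None = None,
    tear: TearSpec | None = None,
    cartilage: IsotropicElastic = CARTILAGE_DEFAULT,
    meniscus: TransverselyIsotropicElastic = MENISCUS_DEFAULT,
    ligament_stiffness: dict | None = None,
    friction_mu: float = 0.02,
    penalty_scale: float = 50.0,
    seating_preload: float = 0.05,
    tear_face_contact: bool = True,
) -> KneeModel:
    """Build the complete FE model for one load case (optionally torn)."""
    geometry = geometry or geo.generate_geometry()
    load_case = load_case or KneeLoadCase()
    resolution = resolution or DEFAULT_RESOLUTION
    ligament_stiffness = ligament_stiffness or LIGAMENT_STIFFNESS

    pose = geo.pose_femur(geometry, load_case.flexion_angle,
                          load_case.screw_home_coupling_deg,
                          load_case.rollback_mm_per_deg)

    parts = {
        "meniscus_MM": mesh_meniscus(geometry, "MM", resolution),
        "meniscus_LM": mesh_meniscus(geometry, "LM", resolution),
        "tibial_cartilage_med": mesh_tibial_cartilage(geometry, "medial", resolution),
        "tibial_cartilage_lat": mesh_tibial_cartilage(geometry, "lateral", resolution),
        "femoral_cartilage_med": mesh_femoral_cartilage(geometry, "medial", resolution),
        "femoral_cartilage_lat": mesh_femoral_cartilage(geometry, "lateral", resolution),
    }

    topo = None
    if tear is not None:
        part = f"meniscus_{tear.meniscus}"
        parts[part], topo = insert_tear(parts[part], tear)

    # pose the femoral cartilage, then seat it vertically so the articular
    # surface just engages the tibial side with a small preload penetration
    for name in ("femoral_cartilage_med", "femoral_cartilage_lat"):
        parts[name] = transform_mesh(parts[name], pose.transform)
    art_pts = np.vstack([parts["femoral_cartilage_med"].nodes[
                             np.unique(parts["femoral_cartilage_med"].facet_sets["articular"])],
                         parts["femoral_cartilage_lat"].nodes[
                             np.unique(parts["femoral_cartilage_lat"].facet_sets["articular"])]])
    clearance = _vertical_clearance(art_pts, geometry)
    seat_shift = -(np.min(clearance) + seating_preload)
    shift = RigidTransform.translation([0.0, 0.0, seat_shift])
    for name in ("femoral_cartilage_med", "femoral_cartilage_lat"):
        parts[name] = transform_mesh(parts[name], shift)
    seated_pose = geo.BonePose(pose.flexion_angle, shift.compose(pose.transform),
                               pose.source)

    mesh = merge_meshes(parts)
    offsets = mesh.meta["offsets"]
    tear_offset = offsets[f"meniscus_{tear.meniscus}"] if tear is not None else 0

    # per-element constitutive matrices
    C = np.zeros((mesh.n_elements, 6, 6))
    C_cart = stiffness_isotropic(cartilage)
    is_meniscal = np.char.startswith(mesh.part.astype(str), "meniscus")
    C[~is_meniscal] = C_cart
    men_idx = np.flatnonzero(is_meniscal)
    C[men_idx] = stiffness_transverse_isotropic_batch(meniscus, mesh.fiber_dir[men_idx])

    # boundary conditions
    fixed = np.unique(np.concatenate([
        mesh.facet_sets["tibial_cartilage_med/bone"].ravel(),
        mesh.facet_sets["tibial_cartilage_lat/bone"].ravel()]))
    femur_nodes = np.unique(np.concatenate([
        mesh.facet_sets["femoral_cartilage_med/bone"].ravel(),
        mesh.facet_sets["femoral_cartilage_lat/bone"].ravel()]))
    centers = np.stack([seated_pose.transform.apply(geometry.condyles[c].center)
                        for c in ("medial", "lateral")])
    femur = RigidBodyConstraint(
        name="femur", node_ids=femur_nodes, ref_point=centers.mean(axis=0),
        trans_dirs=((1.0, 0.0, 0.0), (0.0, 0.0, 1.0)),   # medial-lateral, axial
        rot_axes=((0.0, 1.0, 0.0),))                      # varus-valgus
    body_loads = {"femur": np.array([0.0, -load_case.axial_load, 0.0])}

    # insertional-ligament springs (tension-only, zero pretension)
    springs = []
    for lig, k in ligament_stiffness.items():
        comp, horn = lig.split("_")
        side = "MM" if comp == "medial" else "LM"
        part = f"meniscus_{side}"
        tri = mesh.facet_sets[f"{part}/terminal_{horn}"]
        ids = np.unique(tri)
        horn_pt, insertion = geometry.ligament_attachments[lig]
        offset = insertion - horn_pt
        springs.append(SpringLigament(
            name=lig, node_ids=ids, ground_points=mesh.nodes[ids] + offset,
            stiffness=float(k)))

    pn = default_penalty(cartilage, meniscus, scale=penalty_scale)
    pairs = []
    for comp, side in (("med", "MM"), ("lat", "LM")):
        fem_art = mesh.facet_sets[f"femoral_cartilage_{comp}/articular"]
        men_sup = mesh.facet_sets[f"meniscus_{side}/superior"]
        men_sup_nodes = np.unique(men_sup)
        men_sup_areas = tributary_areas(mesh.nodes, men_sup, men_sup_nodes)
        # followers on the tibial side (finer meshes), master the femoral cap
        pairs.append(ContactPair(
            name=f"fem_men_{comp}", slave_nodes=men_sup_nodes,
            slave_areas=men_sup_areas, master=fem_art,
            friction_mu=friction_mu, penalty_normal=pn, search_radius=3.0))
        tib_art = mesh.facet_sets[f"tibial_cartilage_{comp}/articular"]
        tib_nodes = np.unique(tib_art)
        tib_areas = tributary_areas(mesh.nodes, tib_art, tib_nodes)
        pairs.append(ContactPair(
            name=f"fem_tib_{comp}", slave_nodes=tib_nodes, slave_areas=tib_areas,
            master=fem_art,
            friction_mu=friction_mu, penalty_normal=pn, search_radius=3.0))
        men_inf = mesh.facet_sets[f"meniscus_{side}/inferior"]
        men_nodes = np.unique(men_inf)
        men_areas = tributary_areas(mesh.nodes, men_inf, men_nodes)
        pairs.append(ContactPair(
            name=f"men_tib_{comp}", slave_nodes=men_nodes, slave_areas=men_areas,
            master=mesh.facet_sets[f"tibial_cartilage_{comp}/articular"],
            friction_mu=friction_mu, penalty_normal=pn, search_radius=3.0))
    if topo is not None and tear_face_contact:
        src = mesh.meta["sources"][f"meniscus_{tear.meniscus}"]
        pairs.append(tear_contact_pairs(src, topo, friction_mu=friction_mu,
                                        penalty_normal=pn, node_offset=tear_offset))

    fe = FEModel(mesh, C, fixed_nodes=fixed, rigid_bodies=[femur],
                 springs=springs, contact_pairs=pairs, body_loads=body_loads)
    return KneeModel(geometry=geometry, load_case=load_case, pose=seated_pose,
                     seat_shift=float(seat_shift), mesh=mesh, fe=fe,
                     resolution=resolution, tear=topo,
                     tear_node_offset=tear_offset, part_meshes=parts)
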