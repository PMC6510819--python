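"""Standard numerical verification experiments.

Each experiment exercises the FE machinery end to end on a problem with a
closed-form answer: single-element uniaxial and shear tests recover the
printed elastic constants, a ligament bundle at unit elongation recovers its
printed stiffness, a sliding block recovers the friction coefficient, a
displacement patch test recovers exact constant stress, and rigid-sphere
indentation of an elastic block is compared with the Hertz solution.
"""

from __future__ import annotations

import numpy as np

from .contact import ContactPair, RigidPlane, RigidSphere, tributary_areas
from .elements import element_stiffness_tet
from .fem import FEModel, SolverParams, SpringLigament
from .materials import (IsotropicElastic, TransverselyIsotropicElastic,
                        stiffness_isotropic, stiffness_transverse_isotropic)
from .meshing import boundary_faces, mesh_box

_AXES = {"x": 0, "y": 1, "z": 2}


def _material_matrix(material, fiber_dir) -> np.ndarray:
    if isinstance(material, IsotropicElastic):
        return stiffness_isotropic(material)
    if isinstance(material, TransverselyIsotropicElastic):
        if fiber_dir is None:
            fiber_dir = np.array([1.0, 0.0, 0.0])
        return stiffness_transverse_isotropic(material, np.asarray(fiber_dir, float))
    return np.asarray(material, dtype=float)


def uniaxial_test(material, load_axis: str = "x", fiber_dir=None,
                  n: int = 2) -> dict:
    """Uniaxial-stress FE experiment on a unit cube (template tet split).

    Symmetry supports on the three coordinate planes, unit tensile traction
    on the +``load_axis`` face, all other faces traction-free.  Returns the
    effective Young's modulus (axial stress / axial strain) and the two
    lateral Poisson's ratios (-lateral strain / axial strain).
    """
    C = _material_matrix(material, fiber_dir)
    mesh = mesh_box(n, n, n)
    gi = mesh.meta["grid_index"]
    d = _AXES[load_axis]
    fixed_dofs = np.concatenate([
        3 * np.flatnonzero(gi[:, ax] == 0) + ax for ax in range(3)])
    tri, _ = boundary_faces(mesh)
    loaded = tri[np.all(gi[tri][:, :, d] == n, axis=1)]
    area = tributary_areas(mesh.nodes, loaded, np.arange(mesh.n_nodes))
    f = np.zeros(3 * mesh.n_nodes)
    f[d::3] = area  # unit traction
    model = FEModel(mesh, C, fixed_dofs=fixed_dofs, nodal_loads=f)
    sol = model.solve(SolverParams(n_steps=1, step_max_disp=100.0))
    strains = {}
    for ax in range(3):
        face = np.flatnonzero(gi[:, ax] == n)
        strains[ax] = sol.u[face, ax].mean()  # edge length 1
    out = {"E": float(1.0 / strains[d])}
    lateral = [ax for ax in range(3) if ax != d]
    for ax in lateral:
        name = f"nu_{load_axis}{'xyz'[ax]}"
        out[name] = float(-strains[ax] / strains[d])
    return out


def effective_youngs_modulus(material, load_axis: str = "x",
                             fiber_dir=None, n: int = 2) -> float:
    """Effective Young's modulus from a uniaxial-stress FE experiment.

    A unit cube (template tet split) with symmetry supports on the three
    coordinate planes carries a unit tensile traction on the +``load_axis``
    face; all other faces are traction-free.  Returns axial stress over
    axial strain.
    """
    C = _material_matrix(material, fiber_dir)
    mesh = mesh_box(n, n, n)
    gi = mesh.meta["grid_index"]
    d = _AXES[load_axis]
    # symmetry: zero normal displacement on each coordinate plane
    fixed_dofs = np.concatenate([
        3 * np.flatnonzero(gi[:, ax] == 0) + ax for ax in range(3)])
    tri, _ = boundary_faces(mesh)
    loaded = tri[np.all(gi[tri][:, :, d] == n, axis=1)]
    area = tributary_areas(mesh.nodes, loaded, np.arange(mesh.n_nodes))
    f = np.zeros(3 * mesh.n_nodes)
    f[d::3] = area  # unit traction
    model = FEModel(mesh, C, fixed_dofs=fixed_dofs, nodal_loads=f)
    sol = model.solve(SolverParams(n_steps=1, step_max_disp=100.0))
    face_nodes = np.flatnonzero(gi[:, d] == n)
    strain = sol.u[face_nodes, d].mean()  # edge length 1
    return float(1.0 / strain)


def effective_shear_modulus(material, plane: str = "yz",
                            fiber_dir=None, n: int = 2,
                            gamma: float = 0.01) -> float:
    """Effective shear modulus from a simple-shear displacement experiment.

    All boundary nodes of a unit cube follow the affine field
    u_i = gamma * x_j for shear plane (i, j); interior nodes are solved for.
    Returns mean shear stress over the imposed engineering shear strain.
    """
    C = _material_matrix(material, fiber_dir)
    i, j = _AXES[plane[0]], _AXES[plane[1]]
    mesh = mesh_box(n, n, n)
    gi = mesh.meta["grid_index"]
    on_boundary = np.any((gi == 0) | (gi == n), axis=1)
    ids = np.flatnonzero(on_boundary)
    disp = np.zeros((len(ids), 3))
    disp[:, i] = gamma * mesh.nodes[ids, j]
    model = FEModel(mesh, C, prescribed=[(ids, disp)])
    sol = model.solve(SolverParams(n_steps=1, step_max_disp=100.0))
    voigt = {(1, 2): 3, (0, 2): 4, (0, 1): 5}[tuple(sorted((i, j)))]
    vols = mesh.volumes()
    tau = float((sol.stress[:, voigt] * vols).sum() / vols.sum())
    return tau / gamma


def patch_test(E: float = 1.0, nu: float = 0.0, strain: float = 0.05) -> dict:
    """Uniaxial displacement patch test on a unit cube of tets.

    The affine field u_x = strain * x is prescribed on the boundary; for a
    conforming linear element the interior solution and all element stresses
    are exact (constant sigma_xx = E * strain for nu = 0).
    """
    C = stiffness_isotropic(IsotropicElastic(E, nu))
    mesh = mesh_box(2, 2, 2)
    gi = mesh.meta["grid_index"]
    ids = np.flatnonzero(np.any((gi == 0) | (gi == 2), axis=1))
    disp = np.zeros((len(ids), 3))
    disp[:, 0] = strain * mesh.nodes[ids, 0]
    model = FEModel(mesh, C, prescribed=[(ids, disp)])
    sol = model.solve(SolverParams(n_steps=1, step_max_disp=100.0))
    exact = np.zeros(6)
    exact[0] = E * strain
    dev = np.abs(sol.stress - exact).max()
    return {"stress": sol.stress, "exact_sigma_xx": E * strain,
            "max_deviation": float(dev)}


def rigid_body_mode_count(C: np.ndarray | None = None, rel_tol: float = 1e-9) -> int:
    """Number of zero-energy modes of one tet element's stiffness."""
    if C is None:
        C = stiffness_isotropic(IsotropicElastic(1.0, 0.3))
    nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    K = element_stiffness_tet(nodes, C)
    w = np.linalg.eigvalsh(K)
    return int((np.abs(w) < rel_tol * np.abs(w).max()).sum())


def spring_unit_elongation_force(stiffness: float, n_nodes: int = 6) -> float:
    """Total axial force of a ligament bundle elongated by exactly 1 mm.

    The bundle's per-node springs act in parallel, so the measured total
    must equal the nominal stiffness in N (slack state carries zero force).
    """
    rng = np.random.default_rng(0)
    coords = rng.normal(size=(n_nodes, 3))
    axis = np.array([0.3, -0.5, 0.81])
    axis /= np.linalg.norm(axis)
    spring = SpringLigament("test", np.arange(n_nodes),
                            coords + 4.0 * axis, stiffness=stiffness)
    u = np.zeros((n_nodes, 3))
    _, _, f0 = spring.force_and_tangent(coords, u)
    assert np.all(f0 == 0.0), "springs must be slack in the reference state"
    u = -1.0 * axis * np.ones((n_nodes, 1))  # move 1 mm away from ground
    _, _, f1 = spring.force_and_tangent(coords, u)
    return float(f1.sum())


def friction_block_test(mu: float = 0.02, penalty: float = 5000.0) -> dict:
    """Elastic block dragged across a rigid plane while pressed onto it.

    The top face is driven with a prescribed tangential displacement large
    enough to put every contact node into the slip state; the ratio of
    tangential to normal contact reaction then recovers the Coulomb
    coefficient.
    """
    mesh = mesh_box(2, 2, 2, 2.0, 2.0, 1.0)
    gi = mesh.meta["grid_index"]
    C = stiffness_isotropic(IsotropicElastic(100.0, 0.3))
    tri, _ = boundary_faces(mesh)
    bot = tri[np.all(gi[tri][:, :, 2] == 0, axis=1)]
    bnodes = np.unique(bot)
    areas = tributary_areas(mesh.nodes, bot, bnodes)
    plane = RigidPlane(np.zeros(3), np.array([0.0, 0.0, 1.0]))
    pair = ContactPair("plane", bnodes, areas, plane,
                       friction_mu=mu, penalty_normal=penalty)
    top = np.flatnonzero(gi[:, 2] == 2)
    model = FEModel(mesh, C, contact_pairs=[pair],
                    prescribed=[(top, [0.5, 0.0, -0.02])])
    sol = model.solve(SolverParams(n_steps=4, step_max_disp=0.2, max_iter=100))
    st = sol.contact["plane"]
    N = float(st.fn.sum())
    T = float(np.linalg.norm(st.ft.sum(axis=0)))
    return {"normal": N, "tangential": T, "ratio": T / N,
            "statuses": set(st.status.tolist())}


def hertz_indentation_test(E: float = 10.0, nu: float = 0.3,
                           radius: float = 200.0, depth_of_indent: float = 0.5,
                           penalty: float = 500.0) -> dict:
    """Rigid sphere pressed into an elastic block versus the Hertz solution.

    The block (80 x 80 x 120 mm) uses a power-graded structured grid refined
    under the indenter; sizes were fixed by our own convergence study so the
    discretized half-space approximation stays well within the Hertz
    small-strain regime.
    """
    nxy, nz = 16, 10
    u = np.linspace(-1, 1, nxy + 1)
    gxy = 40.0 * np.sign(u) * np.abs(u) ** 1.7
    w = np.linspace(0, 1, nz + 1)
    gz = (-120.0 * w ** 1.8)[::-1]
    mesh = mesh_box(nxy, nxy, nz, gxy, gxy, gz)
    gi = mesh.meta["grid_index"]
    tri, _ = boundary_faces(mesh)
    topset = tri[np.all(gi[tri][:, :, 2] == nz, axis=1)]
    tn = np.unique(topset)
    ta = tributary_areas(mesh.nodes, topset, tn)
    sphere = RigidSphere(np.array([0.0, 0.0, radius - depth_of_indent]), radius)
    pair = ContactPair("sphere", tn, ta, sphere, friction_mu=0.0,
                       penalty_normal=penalty)
    bot = np.flatnonzero(gi[:, 2] == 0)
    model = FEModel(mesh, stiffness_isotropic(IsotropicElastic(E, nu)),
                    fixed_nodes=bot, contact_pairs=[pair])
    sol = model.solve(SolverParams(n_steps=2, step_max_disp=0.5, max_iter=80))
    F = float(sol.contact["sphere"].fn.sum())
    Fh = 4.0 / 3.0 * (E / (1 - nu**2)) * np.sqrt(radius) * depth_of_indent**1.5
    return {"force_fe": F, "force_hertz": Fh, "ratio": F / Fh}


def frame_indifference_test(seed: int = 9) -> dict:
    """Rotate a complete model (mesh, contact plane, spring, prescribed
    motion) by a random rigid rotation and compare the solutions.

    Returns the maximum displacement deviation relative to the solution
    scale; small-strain frame indifference requires it to vanish to solver
    precision.
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    mesh = mesh_box(2, 2, 2, 2.0, 2.0, 1.0)
    gi = mesh.meta["grid_index"]
    tri, _ = boundary_faces(mesh)
    bot = tri[np.all(gi[tri][:, :, 2] == 0, axis=1)]
    ids = np.unique(bot)
    areas = tributary_areas(mesh.nodes, bot, ids)
    top = np.flatnonzero(gi[:, 2] == 2)
    corner = np.array([int(np.argmax(mesh.nodes.sum(axis=1)))])

    def build(rot):
        m2 = mesh.copy()
        m2.nodes = mesh.nodes @ rot.T
        plane = RigidPlane(rot @ np.zeros(3), rot @ np.array([0.0, 0.0, 1.0]))
        pair = ContactPair("p", ids, areas, plane, friction_mu=0.0,
                           penalty_normal=200.0)
        spring = SpringLigament(
            "lig", corner, m2.nodes[corner] + (rot @ np.array([1.0, 0.0, 0.5])),
            stiffness=2.0, slack_lengths=np.array([0.9]))
        presc = rot @ np.array([0.05, 0.02, -0.06])
        C10 = stiffness_isotropic(IsotropicElastic(10.0, 0.3))
        return FEModel(m2, C10, contact_pairs=[pair], springs=[spring],
                       prescribed=[(top, presc)])

    params = SolverParams(n_steps=2, rtol=1e-9, max_iter=80)
    u_id = build(np.eye(3)).solve(params).u
    u_rot = build(R).solve(params).u
    scale = max(float(np.abs(u_id).max()), 1e-12)
    dev = float(np.max(np.abs(u_rot - u_id @ R.T))) / scale
    return {"max_relative_deviation": dev}
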