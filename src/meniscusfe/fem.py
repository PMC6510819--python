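"""Static, geometrically linear FE system with rigid-body ties, tension-only
springs and penalty frictional contact, solved by Newton iteration with
incremental load stepping.

The femur is a rigid body: nodes on bone-bonded cartilage surfaces move
rigidly with it.  Its free degrees of freedom (by default medial-lateral
translation, axial translation and varus-valgus rotation) are unknowns of
the reduced system; the compressive load acts on the axial translation.
The tibia is fully fixed, so tibial-side bone-bonded nodes are constrained
to zero displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .contact import ContactPair, ContactState, accumulate_contact, evaluate_contact
from .elements import assemble_stiffness, element_strains, element_stresses
from .meshing import FEMesh

# insertional ligament stiffnesses, N/mm
LIGAMENT_STIFFNESS = {
    "lateral_anterior": 216.0,
    "lateral_posterior": 130.0,
    "medial_anterior": 169.0,
    "medial_posterior": 207.0,
}


class SingularSystemError(RuntimeError):
    """The constrained system is structurally singular (insufficient support)."""


class ConvergenceError(RuntimeError):
    """Newton iteration failed to converge; carries the residual trace."""

    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


@dataclass
class SpringLigament:
    """Tension-only linear spring bundle anchoring a horn to the tibia.

    The total stiffness is distributed over the attached node set as
    parallel per-node springs to per-node ground points, so a unit axial
    elongation of the whole bundle produces a total force equal to the
    printed stiffness.  Springs carry zero force below their slack length
    (non-compressive).
    """

    name: str
    node_ids: np.ndarray        # (n,)
    ground_points: np.ndarray   # (n, 3)
    stiffness: float            # total N/mm
    slack_lengths: np.ndarray | None = None   # (n,), default = reference lengths

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        self.ground_points = np.asarray(self.ground_points, dtype=float)

    def init_slack(self, coords: np.ndarray) -> None:
        if self.slack_lengths is None:
            self.slack_lengths = np.linalg.norm(
                self.ground_points - coords[self.node_ids], axis=1)

    def force_and_tangent(self, coords: np.ndarray, u: np.ndarray):
        """Nodal forces (n, 3), tangent blocks (n, 3, 3) and axial forces (n,)."""
        self.init_slack(coords)
        k = self.stiffness / len(self.node_ids)
        pos = coords[self.node_ids] + u[self.node_ids]
        d = self.ground_points - pos
        length = np.linalg.norm(d, axis=1)
        axis = d / np.maximum(length, 1e-12)[:, None]
        stretch = length - self.slack_lengths
        taut = stretch > 0
        fmag = np.where(taut, k * stretch, 0.0)
        forces = fmag[:, None] * axis
        aaT = np.einsum("ai,aj->aij", axis, axis)
        geo = np.where(taut, fmag / np.maximum(length, 1e-12), 0.0)
        tang = (k * taut)[:, None, None] * aaT + geo[:, None, None] * (np.eye(3)[None] - aaT)
        return forces, tang, fmag


@dataclass
class RigidBodyConstraint:
    """Nodes moving rigidly with a rigid bone.

    Displacement of a tied node X:  u(X) = sum_i q_i d_i + sum_j q_j a_j x (X - X0)
    with unit translation directions d_i and small-rotation axes a_j; the q
    are unknowns of the reduced system (free bone DOFs).  An empty DOF set
    makes the tied nodes fully fixed to ground.
    """

    name: str
    node_ids: np.ndarray
    ref_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    trans_dirs: tuple = ()
    rot_axes: tuple = ()

    @property
    def n_dofs(self) -> int:
        return len(self.trans_dirs) + len(self.rot_axes)


@dataclass
class SolverParams:
    rtol: float = 1e-4
    max_iter: int = 60
    n_steps: int = 4
    penetration_tol: float = 0.02      # mm
    step_max_disp: float = 1.0         # mm, Newton increment cap
    regularization: float = 1e-8       # tangent diagonal, x max(diag K)
    max_substep_depth: int = 4
    friction_freeze_iter: int = 30     # freeze lagged friction after this many
                                       # iterations of a load step


@dataclass
class SolutionField:
    """Converged solution: displacements, stresses, contact and spring state."""

    u: np.ndarray                     # (N, 3)
    body_dofs: dict                   # body name -> (n_dofs,) values
    stress: np.ndarray                # (M, 6) Voigt, MPa
    strain: np.ndarray                # (M, 6)
    contact: dict                     # pair name -> ContactState
    springs: dict                     # ligament name -> dict(total_force, forces, ...)
    reactions: np.ndarray             # (3N,) support/internal force imbalance
    trace: list
    converged: bool
    max_penetration: float
    load_factor: float = 1.0

    def spring_total_force(self, name: str) -> float:
        return float(self.springs[name]["total_force"])


class FEModel:
    """Assembled model: mesh + materials + constraints + springs + contact."""

    def __init__(self, mesh: FEMesh, C_per_element: np.ndarray,
                 fixed_nodes: np.ndarray = (),
                 rigid_bodies: list | None = None,
                 springs: list | None = None,
                 contact_pairs: list | None = None,
                 nodal_loads: np.ndarray | None = None,
                 body_loads: dict | None = None,
                 prescribed: list | None = None,
                 fixed_dofs: np.ndarray = ()):
        self.mesh = mesh
        self.C = np.asarray(C_per_element, dtype=float)
        if self.C.ndim == 2:
            self.C = np.broadcast_to(self.C, (mesh.n_elements, 6, 6))
        self.fixed_nodes = np.asarray(fixed_nodes, dtype=int)
        self.fixed_dofs = np.asarray(fixed_dofs, dtype=int)
        self.rigid_bodies = list(rigid_bodies or [])
        self.springs = list(springs or [])
        self.contact_pairs = list(contact_pairs or [])
        self.f_nodal = (np.zeros(3 * mesh.n_nodes) if nodal_loads is None
                        else np.asarray(nodal_loads, dtype=float).reshape(-1))
        self.body_loads = dict(body_loads or {})   # body name -> (n_dofs,) loads
        # prescribed displacements: list of (node_ids, displacement) pairs,
        # ramped with the load factor
        self.u_presc = np.zeros(3 * mesh.n_nodes)
        self.prescribed_nodes = np.zeros(0, dtype=int)
        if prescribed:
            ids_all = []
            for ids, disp in prescribed:
                ids = np.asarray(ids, dtype=int)
                disp = np.broadcast_to(np.asarray(disp, float), (len(ids), 3))
                self.u_presc.reshape(-1, 3)[ids] = disp
                ids_all.append(ids)
            self.prescribed_nodes = np.unique(np.concatenate(ids_all))

        self.K, self.B, self.vols = assemble_stiffness(mesh.nodes, mesh.tets, self.C)
        self._build_reduction()

    # -- constraint handling -------------------------------------------------

    def _build_reduction(self) -> None:
        n = self.mesh.n_nodes
        constrained_nodes = set(self.fixed_nodes.tolist()) | set(self.prescribed_nodes.tolist())
        for body in self.rigid_bodies:
            overlap = constrained_nodes & set(np.asarray(body.node_ids).tolist())
            if overlap:
                raise ValueError(f"nodes {sorted(overlap)[:5]}... doubly constrained")
            constrained_nodes |= set(np.asarray(body.node_ids).tolist())
        cn = np.array(sorted(constrained_nodes), dtype=int)
        mask = np.zeros(3 * n, dtype=bool)
        if len(cn):
            mask[(3 * cn[:, None] + np.arange(3)).ravel()] = True
        mask[self.fixed_dofs] = True
        free_dofs = np.flatnonzero(~mask)
        self.free_dofs = free_dofs
        n_red = len(free_dofs) + sum(b.n_dofs for b in self.rigid_bodies)
        if n_red == 0:
            raise SingularSystemError("no unknowns: everything is constrained")

        rows, cols, vals = [], [], []
        rows.append(free_dofs)
        cols.append(np.arange(len(free_dofs)))
        vals.append(np.ones(len(free_dofs)))

        self.body_dof_index = {}
        off = len(free_dofs)
        for body in self.rigid_bodies:
            ids = np.asarray(body.node_ids, dtype=int)
            X = self.mesh.nodes[ids] - np.asarray(body.ref_point)
            dof_cols = []
            modes = [np.broadcast_to(np.asarray(d, float), (len(ids), 3))
                     for d in body.trans_dirs]
            modes += [np.cross(np.asarray(a, float)[None, :], X) for a in body.rot_axes]
            for m, mode in enumerate(modes):
                rows.append((3 * ids[:, None] + np.arange(3)).ravel())
                cols.append(np.full(3 * len(ids), off + m))
                vals.append(mode.ravel())
                dof_cols.append(off + m)
            self.body_dof_index[body.name] = np.array(dof_cols, dtype=int)
            off += body.n_dofs

        self.T = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(3 * n, n_red)).tocsr()
        self.K_red = (self.T.T @ self.K @ self.T).tocsc()

        self.f_ext_red = self.T.T @ self.f_nodal
        for name, load in self.body_loads.items():
            self.f_ext_red[self.body_dof_index[name]] += np.asarray(load, dtype=float)

    # -- force evaluation ----------------------------------------------------

    def _spring_contact_forces(self, u_flat: np.ndarray, u_ref_flat: np.ndarray,
                               friction_frozen: bool = False):
        """Forces on nodes from springs + contact, tangent triplets, states."""
        n = self.mesh.n_nodes
        u = u_flat.reshape(n, 3)
        u_ref = u_ref_flat.reshape(n, 3)
        f = np.zeros(3 * n)
        rows, cols, vals = [], [], []

        spring_states = {}
        for spring in self.springs:
            forces, tang, fmag = spring.force_and_tangent(self.mesh.nodes, u)
            idx = (3 * spring.node_ids[:, None] + np.arange(3)).ravel()
            np.add.at(f, idx, forces.ravel())
            r = (3 * spring.node_ids[:, None, None] + np.arange(3)[None, :, None])
            c = (3 * spring.node_ids[:, None, None] + np.arange(3)[None, None, :])
            rows.append(np.broadcast_to(r, tang.shape).ravel())
            cols.append(np.broadcast_to(c, tang.shape).ravel())
            vals.append(tang.ravel())
            spring_states[spring.name] = {
                "forces": fmag, "total_force": fmag.sum(),
                "nodal_forces": forces,
            }

        contact_states = {}
        if not hasattr(self, "_friction_memory"):
            self._friction_memory = {}
        for pair in self.contact_pairs:
            mem = None
            if pair.friction_mu > 0:
                mem = self._friction_memory.setdefault(
                    pair.name, np.zeros((len(pair.slave_nodes), 3)))
            state = evaluate_contact(pair, self.mesh.nodes, u, u_ref,
                                     friction_memory=mem,
                                     friction_frozen=friction_frozen)
            if state is not None:
                accumulate_contact(state, f, rows, cols, vals)
            contact_states[pair.name] = state

        if rows:
            Kc = sp.coo_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(3 * n, 3 * n)).tocsr()
        else:
            Kc = sp.csr_matrix((3 * n, 3 * n))
        return f, Kc, spring_states, contact_states

    # -- solve ---------------------------------------------------------------

    def solve(self, params: SolverParams | None = None,
              initial_guess: np.ndarray | None = None) -> SolutionField:
        params = params or SolverParams()
        n_red = self.K_red.shape[0]
        x = np.zeros(n_red)
        if initial_guess is not None:
            # map a full nodal displacement guess onto the free dofs
            u0 = np.asarray(initial_guess, dtype=float).reshape(-1)
            x[:len(self.free_dofs)] = u0[self.free_dofs]
        trace: list = []
        ref_load = max(np.linalg.norm(self.f_ext_red), 1.0)
        diag_scale = max(np.abs(self.K_red.diagonal()).max(), 1.0)
        reg = params.regularization * diag_scale

        lambdas = np.linspace(1.0 / params.n_steps, 1.0, params.n_steps)
        prev_lam = 0.0
        for lam in lambdas:
            x = self._solve_step(x, prev_lam, lam, params, trace, ref_load, reg,
                                 depth=0)
            prev_lam = lam

        return self._finalize(x, params, trace)

    def _solve_step(self, x0, lam0, lam, params, trace, ref_load, reg, depth):
        """One load increment: damped Newton with line search; bisect on failure.

        Sliding contact creates nearly neutral modes that must travel several
        mm to equilibrium; Newton increments are capped, residual-guarded by
        a backtracking line search, and secant-accelerated along coherent
        increment sequences.
        """
        x = x0.copy()
        u_ref = self.T @ x0 + lam0 * self.u_presc
        self._last_u_ref = u_ref
        tol = params.rtol * max(ref_load, 1.0)

        def residual(xv, frozen):
            u = self.T @ xv + lam * self.u_presc
            f_sc, Kc, _, _ = self._spring_contact_forces(u, u_ref,
                                                         friction_frozen=frozen)
            r = lam * self.f_ext_red + self.T.T @ (f_sc - self.K @ u)
            return r, Kc

        frozen = False
        r, Kc = residual(x, frozen)
        rn = np.linalg.norm(r)
        dx_prev = None
        for it in range(params.max_iter):
            trace.append((lam, it, rn))
            if rn < tol:
                self._friction_was_frozen = frozen
                return x
            frozen = it >= params.friction_freeze_iter
            J = self.K_red + self.T.T @ Kc @ self.T
            J = J + reg * sp.identity(J.shape[0], format="csr")
            try:
                lu = spla.splu(J.tocsc(), permc_spec="MMD_AT_PLUS_A")
            except RuntimeError as exc:  # pragma: no cover - singular factor
                raise SingularSystemError(str(exc)) from exc
            dx = lu.solve(r)
            if not np.all(np.isfinite(dx)):
                raise SingularSystemError(
                    "linear solve produced non-finite increments (insufficient "
                    "constraint or degenerate stiffness)")
            step = np.abs(dx).max()
            if step > params.step_max_disp:
                dx *= params.step_max_disp / step
            dx_newton = dx
            # secant acceleration along coherent contracting sequences
            if dx_prev is not None:
                na, nb = np.linalg.norm(dx), np.linalg.norm(dx_prev)
                if na > 0 and nb > 0:
                    cosang = float(dx @ dx_prev) / (na * nb)
                    rho = na / nb
                    if cosang > 0.99 and 0.3 < rho < 0.995:
                        dx = dx * min(1.0 / (1.0 - rho), 60.0)
                        step = np.abs(dx).max()
                        cap = 5.0 * params.step_max_disp
                        if step > cap:
                            dx *= cap / step
            # backtracking line search on the residual norm; when no trial
            # achieves a decrease (flat modes, contact-set changes) take the
            # best trial seen, so progress continues along soft directions
            accepted = False
            best = None
            for alpha in (1.0, 0.5, 0.25, 0.125):
                r_new, Kc_new = residual(x + alpha * dx, frozen)
                rn_new = np.linalg.norm(r_new)
                if best is None or rn_new < best[0]:
                    best = (rn_new, alpha, r_new, Kc_new)
                if rn_new < max((1.0 - 1e-4 * alpha) * rn, 0.5 * tol):
                    accepted = True
                    break
            if not accepted:
                rn_new, alpha, r_new, Kc_new = best
            x = x + alpha * dx
            r, Kc, rn = r_new, Kc_new, rn_new
            dx_prev = dx * alpha if accepted else None
        if depth < params.max_substep_depth:
            mid = 0.5 * (lam0 + lam)
            x = self._solve_step(x0, lam0, mid, params, trace, ref_load, reg, depth + 1)
            return self._solve_step(x, mid, lam, params, trace, ref_load, reg, depth + 1)
        raise ConvergenceError(
            f"no convergence at load factor {lam:.3f} after {params.max_iter} "
            f"iterations (residual {rn:.3g}, tol {tol:.3g})", trace)

    def _finalize(self, x, params, trace) -> SolutionField:
        u_flat = self.T @ x + self.u_presc
        u_ref = getattr(self, "_last_u_ref", u_flat)
        f_sc, _, spring_states, contact_states = self._spring_contact_forces(
            u_flat, u_ref, friction_frozen=self._friction_was_frozen)
        u = u_flat.reshape(-1, 3)
        stress = element_stresses(self.B, self.mesh.tets, self.C, u)
        strain = element_strains(self.B, self.mesh.tets, u)
        reactions = self.K @ u_flat - f_sc - self.f_nodal
        max_pen = 0.0
        for state in contact_states.values():
            if state is not None and state.gap is not None and len(state.gap):
                max_pen = max(max_pen, float(np.maximum(-state.gap, 0.0).max()))
        body_dofs = {name: x[idx] for name, idx in self.body_dof_index.items()}
        return SolutionField(
            u=u, body_dofs=body_dofs, stress=stress, strain=strain,
            contact=contact_states, springs=spring_states, reactions=reactions,
            trace=trace, converged=True, max_penetration=max_pen)


def rigid_bone_constraints(mesh: FEMesh, facet_set: str, kind: str = "bonded",
                           **body_kwargs) -> np.ndarray | RigidBodyConstraint:
    """Constraint set for a cartilage layer bonded to a rigid bone.

    ``kind='bonded'`` with no body DOFs returns the node-id array to fix
    (tibial side: the bone is fully constrained); passing translation
    directions / rotation axes returns a :class:`RigidBodyConstraint`
    (femoral side: nodes follow the rigid femur's free DOFs).
    """
    if facet_set not in mesh.facet_sets:
        raise KeyError(f"facet set {facet_set!r} not present in mesh")
    tri = mesh.facet_sets[facet_set]
    if len(tri) == 0:
        raise ValueError(f"facet set {facet_set!r} is empty")
    ids = np.unique(tri)
    if kind == "bonded" and not body_kwargs:
        return ids
    return RigidBodyConstraint(node_ids=ids, **body_kwargs)


def solve_static(model: FEModel, params: SolverParams | None = None) -> SolutionField:
    """Convenience wrapper: Newton-solve an assembled model."""
    return model.solve(params)
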