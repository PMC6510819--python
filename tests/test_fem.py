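"""FE core: elements, assembly, constraints, springs, contact, small solves."""

import numpy as np
import pytest

from conftest import box_mesh, random_rotation
from meniscusfe.contact import (ContactPair, RigidPlane, evaluate_contact,
                                tributary_areas)
from meniscusfe.elements import (InvertedElementError, element_stiffness_tet,
                                 element_stresses)
from meniscusfe.fem import (FEModel, SingularSystemError, SolverParams,
                            SpringLigament)
from meniscusfe.materials import IsotropicElastic, stiffness_isotropic
from meniscusfe.meshing import boundary_faces
from meniscusfe import verification as V

C_UNIT = stiffness_isotropic(IsotropicElastic(1.0, 0.3))
TET = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


class TestElement:
    def test_rigid_body_modes(self):
        assert V.rigid_body_mode_count() == 6

    def test_symmetric_positive_semidefinite(self):
        K = element_stiffness_tet(TET, C_UNIT)
        assert np.max(np.abs(K - K.T)) < 1e-12
        assert np.linalg.eigvalsh(K).min() > -1e-12 * np.linalg.eigvalsh(K).max()

    def test_inverted_element_rejected(self):
        bad = TET[[0, 2, 1, 3]]
        with pytest.raises(InvertedElementError):
            element_stiffness_tet(bad, C_UNIT)

    def test_patch_test_exact_constant_stress(self):
        res = V.patch_test(E=1.0, nu=0.0, strain=0.05)
        assert res["max_deviation"] < 1e-9


class TestSolveStatics:
    def test_bar_end_displacement_closed_form(self):
        """Uniaxial bar: end displacement equals FL/EA within 0.1%."""
        mesh = box_mesh(2, 2, 8, 1.0, 1.0, 4.0)
        gi = mesh.meta["grid_index"]
        E, F, L, A = 10.0, 5.0, 4.0, 1.0
        tri, _ = boundary_faces(mesh)
        top = tri[np.all(gi[tri][:, :, 2] == 8, axis=1)]
        ta = tributary_areas(mesh.nodes, top, np.arange(mesh.n_nodes))
        f = np.zeros(3 * mesh.n_nodes)
        f[2::3] = F * ta
        model = FEModel(mesh, stiffness_isotropic(IsotropicElastic(E, 0.0)),
                        fixed_nodes=np.flatnonzero(gi[:, 2] == 0), nodal_loads=f)
        sol = model.solve(SolverParams(n_steps=1, step_max_disp=100.0))
        uz = sol.u[np.flatnonzero(gi[:, 2] == 8), 2].mean()
        assert abs(uz - F * L / (E * A)) / (F * L / (E * A)) < 1e-3

    def test_zero_load_zero_residual_solution(self):
        mesh = box_mesh(1, 1, 1)
        model = FEModel(mesh, C_UNIT, fixed_nodes=np.array([0, 1, 2, 3]))
        sol = model.solve(SolverParams(n_steps=1))
        assert np.allclose(sol.u, 0.0)
        assert np.allclose(sol.stress, 0.0)

    def test_global_stiffness_symmetric(self):
        mesh = box_mesh(2, 2, 2)
        model = FEModel(mesh, C_UNIT, fixed_nodes=np.array([0]))
        d = (model.K - model.K.T)
        assert abs(d).max() < 1e-8 * abs(model.K).max()

    def test_unconstrained_model_reports_singularity(self):
        mesh = box_mesh(1, 1, 1)
        f = np.zeros(3 * mesh.n_nodes)
        f[2::3] = 1.0
        model = FEModel(mesh, C_UNIT, nodal_loads=f)
        with pytest.raises((SingularSystemError, RuntimeError)):
            model.solve(SolverParams(n_steps=1, max_iter=3,
                                     regularization=0.0))

    def test_fixed_nodes_stay_put_and_stresses_react(self):
        mesh = box_mesh(2, 2, 2)
        gi = mesh.meta["grid_index"]
        bottom = np.flatnonzero(gi[:, 2] == 0)
        top = np.flatnonzero(gi[:, 2] == 2)
        model = FEModel(mesh, C_UNIT, fixed_nodes=bottom,
                        prescribed=[(top, [0.0, 0.0, -0.1])])
        sol = model.solve(SolverParams(n_steps=1))
        assert np.allclose(sol.u[bottom], 0.0, atol=1e-12)
        assert sol.stress[:, 2].mean() < 0  # compression


class TestSprings:
    def test_slack_and_unit_elongation(self):
        for k in (216.0, 130.0, 169.0, 207.0):
            assert np.isclose(V.spring_unit_elongation_force(k), k)

    def test_never_compressive(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(5, 3))
        spring = SpringLigament("s", np.arange(5),
                                coords + np.array([0, 0, 2.0]), stiffness=100.0)
        for _ in range(50):
            u = rng.normal(size=(5, 3)) * 3.0
            _, _, fmag = spring.force_and_tangent(coords, u)
            assert fmag.min() >= 0.0


class TestContact:
    def _bottom_pair(self, mesh, mu=0.0, pn=1000.0, g0=1e-6):
        gi = mesh.meta["grid_index"]
        tri, _ = boundary_faces(mesh)
        bot = tri[np.all(gi[tri][:, :, 2] == 0, axis=1)]
        ids = np.unique(bot)
        areas = tributary_areas(mesh.nodes, bot, ids)
        plane = RigidPlane(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        return ContactPair("p", ids, areas, plane, friction_mu=mu,
                           penalty_normal=pn, smoothing_gap=g0), ids, areas

    def test_separated_surfaces_zero_force(self):
        mesh = box_mesh(1, 1, 1)
        mesh.nodes[:, 2] += 0.5
        pair, ids, _ = self._bottom_pair(mesh)
        u = np.zeros((mesh.n_nodes, 3))
        state = evaluate_contact(pair, mesh.nodes, u, u)
        assert state is None or state.fn is None or len(state.active) == 0

    def test_penalty_law_with_prescribed_penetration(self):
        mesh = box_mesh(1, 1, 1)
        pair, ids, areas = self._bottom_pair(mesh, pn=1000.0, g0=1e-6)
        delta = 0.01
        u = np.zeros((mesh.n_nodes, 3))
        u[ids, 2] = -delta
        state = evaluate_contact(pair, mesh.nodes, u, np.zeros_like(u))
        # deep in the linear branch: fn = pn * (delta - g0/2) * area
        expect = 1000.0 * (delta - 0.5e-6) * areas
        assert np.allclose(np.sort(state.fn), np.sort(expect), rtol=1e-9)

    def test_friction_coefficient_recovered_at_slip(self):
        res = V.friction_block_test(mu=0.02)
        assert res["statuses"] == {"slip"}
        assert abs(res["ratio"] - 0.02) / 0.02 < 0.05

    def test_load_linearity_in_closed_contact(self):
        """With contact fully closed, doubling the load doubles displacement."""
        mesh = box_mesh(2, 2, 2, 2.0, 2.0, 1.0)
        gi = mesh.meta["grid_index"]
        pair, ids, _ = self._bottom_pair(mesh, pn=5000.0)
        top = np.flatnonzero(gi[:, 2] == 2)
        sols = {}
        for P in (10.0, 20.0):
            f = np.zeros(3 * mesh.n_nodes)
            f[3 * top + 2] = -P / len(top)
            model = FEModel(mesh, stiffness_isotropic(IsotropicElastic(50.0, 0.3)),
                            contact_pairs=[pair], nodal_loads=f)
            sols[P] = model.solve(SolverParams(n_steps=1, rtol=1e-8))
        ratio = sols[20.0].u[top, 2].mean() / sols[10.0].u[top, 2].mean()
        assert abs(ratio - 2.0) < 0.02


class TestFrameIndifference:
    def test_rotated_model_yields_rotated_solution(self):
        """Rotating geometry, prescribed motion, springs and the contact
        plane by a rigid rotation rotates the displacement field."""
        res = V.frame_indifference_test(seed=9)
        assert res["max_relative_deviation"] < 1e-6


def test_element_stress_recovery_consistency():
    """Uniform strain applied to a meshed cube reproduces C @ eps exactly."""
    mesh = box_mesh(2, 2, 2)
    from meniscusfe.elements import b_matrices

    B, _ = b_matrices(mesh.nodes[mesh.tets])
    eps = np.array([0.01, -0.004, 0.002, 0.003, -0.001, 0.005])
    grad = np.array([[eps[0], eps[5] / 2, eps[4] / 2],
                     [eps[5] / 2, eps[1], eps[3] / 2],
                     [eps[4] / 2, eps[3] / 2, eps[2]]])
    u = mesh.nodes @ grad.T
    C = np.broadcast_to(C_UNIT, (mesh.n_elements, 6, 6))
    stress = element_stresses(B, mesh.tets, C, u)
    expect = C_UNIT @ eps
    assert np.max(np.abs(stress - expect)) < 1e-12
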