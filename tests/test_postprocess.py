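"""Outcome measures on manufactured stress fields (no solves needed)."""

from types import SimpleNamespace

import numpy as np
import pytest

from meniscusfe.geometry import generate_geometry
from meniscusfe.meshing import DEFAULT_RESOLUTION, mesh_meniscus
from meniscusfe.postprocess import (ReportError, SegmentDisplacement,
                                    apex_stress_delta, sample_transect,
                                    segment_displacements,
                                    tear_surface_difference)
from meniscusfe.tears import TearSpec, insert_tear


@pytest.fixture(scope="module")
def mm():
    return mesh_meniscus(generate_geometry(), "MM", DEFAULT_RESOLUTION)


def _solution(mesh, stress):
    return SimpleNamespace(stress=np.asarray(stress, float),
                           u=np.zeros((mesh.n_nodes, 3)))


def _uniform_solution(mesh, voigt):
    return _solution(mesh, np.tile(np.asarray(voigt, float), (mesh.n_elements, 1)))


class TestTransect:
    def test_uniform_field_gives_flat_profile(self, mm):
        sigma = [2.0, 1.0, 0.5, 0.0, 0.0, 0.0]
        sol = _uniform_solution(mm, sigma)
        prof = sample_transect(sol, mm, "MM", "middle", n_samples=9)
        assert np.allclose(prof.max_pcs, 2.0, atol=1e-9)
        assert prof.s[0] == 0.0 and prof.s[-1] == 1.0
        assert np.all(np.diff(prof.s) > 0)

    def test_linear_in_s_field_sampled_linearly(self, mm):
        shape = mm.meta["shape"]
        _, s_elem = shape.polar(mm.centroids())
        stress = np.zeros((mm.n_elements, 6))
        stress[:, 0] = 1.0 + 2.0 * s_elem  # sigma_xx linear in s
        prof = sample_transect(_solution(mm, stress), mm, "MM", "middle",
                               n_samples=9)
        expect = 1.0 + 2.0 * prof.s
        # piecewise-linear recovery of a linear field, O(h) at the rims
        assert np.max(np.abs(prof.max_pcs - expect)) < 0.35
        interior = slice(1, -1)
        assert np.max(np.abs(prof.max_pcs[interior] - expect[interior])) < 0.2

    def test_empty_region_rejected(self, mm):
        with pytest.raises(ReportError):
            sample_transect(_uniform_solution(mm, np.zeros(6)), mm, "LM",
                            "middle")


@pytest.fixture(scope="module")
def torn(mm):
    spec = TearSpec("longitudinal", "MM", "middle", "stable")
    return insert_tear(mm, spec)


@pytest.fixture(scope="module")
def radial(mm):
    return insert_tear(mm, TearSpec("radial", "MM", "posterior", "stable"))


class TestTearSurface:
    def _two_sided_solution(self, mesh, topo, inner_value, outer_value):
        shape = mesh.meta["shape"]
        _, s = shape.polar(mesh.centroids())
        stress = np.zeros((mesh.n_elements, 6))
        hoop = np.where(s > 5.0 / 6.0, outer_value, inner_value)
        # uniaxial stress along the local fiber direction
        f = mesh.fiber_dir
        stress[:, 0] = hoop * f[:, 0] ** 2
        stress[:, 1] = hoop * f[:, 1] ** 2
        stress[:, 2] = hoop * f[:, 2] ** 2
        stress[:, 3] = hoop * f[:, 1] * f[:, 2]
        stress[:, 4] = hoop * f[:, 0] * f[:, 2]
        stress[:, 5] = hoop * f[:, 0] * f[:, 1]
        return _solution(mesh, stress)

    def test_equal_faces_tie_is_unfavourable(self, torn):
        mesh, topo = torn
        sol = self._two_sided_solution(mesh, topo, 1.0, 1.0)
        rep = tear_surface_difference(sol, mesh, topo)
        assert abs(rep.difference) < 1e-9
        assert rep.favourable is False

    def test_outer_greater_is_favourable(self, torn):
        mesh, topo = torn
        rep = tear_surface_difference(
            self._two_sided_solution(mesh, topo, 1.0, 2.0), mesh, topo)
        assert rep.favourable is True
        assert np.isclose(rep.difference, 1.0, atol=0.05)

    def test_swapping_faces_flips_classification(self, torn):
        mesh, topo = torn
        rep = tear_surface_difference(
            self._two_sided_solution(mesh, topo, 2.0, 1.0), mesh, topo)
        assert rep.favourable is False
        assert rep.difference < 0

    def test_radial_tear_rejected(self, mm):
        spec = TearSpec("radial", "MM", "middle", "stable")
        mesh, topo = insert_tear(mm, spec)
        with pytest.raises(ReportError):
            tear_surface_difference(_uniform_solution(mesh, np.zeros(6)),
                                    mesh, topo)


class TestApex:
    def test_identical_runs_give_zero_delta(self, mm, radial):
        mesh, topo = radial
        sol = _uniform_solution(mesh, [1.0, 0.2, 0.0, 0, 0, 0])
        rep = apex_stress_delta(sol, sol, mesh, topo)
        assert rep.delta == 0.0

    def test_delta_invariant_to_rigid_rotation(self, mm, radial):
        from conftest import random_rotation

        mesh, topo = radial
        rng = np.random.default_rng(1)
        stress_t = rng.normal(size=(mesh.n_elements, 6))
        stress_i = rng.normal(size=(mesh.n_elements, 6))
        R = random_rotation(2)

        def rotate_voigt(stress):
            out = np.empty_like(stress)
            idx = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]
            for e, v in enumerate(stress):
                S = np.array([[v[0], v[5], v[4]], [v[5], v[1], v[3]],
                              [v[4], v[3], v[2]]])
                Sr = R @ S @ R.T
                out[e] = [Sr[i, j] for i, j in idx]
            return out

        rep0 = apex_stress_delta(_solution(mesh, stress_t),
                                 _solution(mesh, stress_i), mesh, topo)
        rep1 = apex_stress_delta(_solution(mesh, rotate_voigt(stress_t)),
                                 _solution(mesh, rotate_voigt(stress_i)),
                                 mesh, topo)
        assert np.isclose(rep0.delta, rep1.delta, atol=1e-9)

    def test_mismatched_meshes_rejected(self, mm, radial):
        mesh, topo = radial
        sol_t = _uniform_solution(mesh, np.zeros(6))
        sol_i = SimpleNamespace(stress=np.zeros((3, 6)), u=np.zeros((4, 3)))
        with pytest.raises(ReportError):
            apex_stress_delta(sol_t, sol_i, mesh, topo)


class TestSegments:
    def _merged(self):
        from meniscusfe.meshing import merge_meshes

        g = generate_geometry()
        return merge_meshes({
            "meniscus_MM": mesh_meniscus(g, "MM", DEFAULT_RESOLUTION),
            "meniscus_LM": mesh_meniscus(g, "LM", DEFAULT_RESOLUTION)})

    def test_identical_solutions_give_zeros(self):
        mesh = self._merged()
        sol = SimpleNamespace(u=np.zeros((mesh.n_nodes, 3)))
        reports = segment_displacements(sol, sol, mesh)
        assert all(r.ap_mm == 0.0 and r.ml_mm == 0.0 for r in reports)
        assert {r.segment for r in reports} == {"anterior", "posterior",
                                                "midsection"}

    def test_anterior_translation_sign_convention(self):
        mesh = self._merged()
        sol_a = SimpleNamespace(u=np.zeros((mesh.n_nodes, 3)))
        sol_b = SimpleNamespace(u=np.tile([0.0, 1.0, 0.0], (mesh.n_nodes, 1)))
        for rep in segment_displacements(sol_a, sol_b, mesh):
            assert np.isclose(rep.ap_mm, 1.0)

    def test_medial_translation_sign_convention(self):
        mesh = self._merged()
        sol_a = SimpleNamespace(u=np.zeros((mesh.n_nodes, 3)))
        sol_b = SimpleNamespace(u=np.tile([-1.0, 0.0, 0.0], (mesh.n_nodes, 1)))
        for rep in segment_displacements(sol_a, sol_b, mesh):
            assert np.isclose(rep.ml_mm, 1.0)  # -x is medial
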