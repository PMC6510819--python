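"""Rigid-transform utilities and least-squares landmark registration."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from meniscusfe.transforms import (DegenerateLandmarksError, RigidTransform,
                                   landmark_transform)


def _grid_search_rigid(src, dst, n=24, passes=4):
    """Brute-force oracle: nested Euler-angle grid search for the best
    proper rotation (translation handled by centering)."""
    c_src, c_dst = src.mean(axis=0), dst.mean(axis=0)
    a, b = src - c_src, dst - c_dst

    def rms_of(angles):
        R = Rotation.from_euler("xyz", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((a @ R.T - b) ** 2, axis=1)))

    center = np.zeros(3)
    half = np.array([np.pi, np.pi / 2, np.pi])
    best = (np.inf, center)
    for _ in range(passes):
        axs = [np.linspace(center[i] - half[i], center[i] + half[i], n)
               for i in range(3)]
        for ax in axs[0]:
            for ay in axs[1]:
                for az in axs[2]:
                    r = rms_of([ax, ay, az])
                    if r < best[0]:
                        best = (r, np.array([ax, ay, az]))
        center = best[1]
        half = half * (3.0 / n)
    return best


@pytest.fixture
def cloud():
    rng = np.random.default_rng(7)
    return rng.normal(size=(6, 3)) * 20.0


def test_identity_registration(cloud):
    xform, rms = landmark_transform(cloud, cloud)
    assert np.allclose(xform.R, np.eye(3), atol=1e-12)
    assert np.allclose(xform.t, 0.0, atol=1e-12)
    assert rms < 1e-12


def test_exact_rotation_translation_recovered(cloud):
    R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    t = np.array([5.0, -3.0, 11.0])
    xform, rms = landmark_transform(cloud, cloud @ R.T + t)
    assert np.allclose(xform.R, R, atol=1e-9)
    assert np.allclose(xform.t, t, atol=1e-9)
    assert rms < 1e-9


def test_perturbed_registration_matches_grid_search_oracle():
    rng = np.random.default_rng(3)
    src = rng.normal(size=(3, 3)) * 10.0
    R = Rotation.from_euler("xyz", [0.3, -0.5, 0.9]).as_matrix()
    dst = src @ R.T + np.array([1.0, 2.0, 3.0]) + rng.normal(size=(3, 3)) * 0.5
    _, rms = landmark_transform(src, dst)
    rms_grid, _ = _grid_search_rigid(src, dst)
    # closed-form optimum matches the refined brute-force search
    assert rms <= rms_grid + 1e-9
    assert np.isclose(rms, rms_grid, rtol=1e-3)


def test_left_invariance_of_residual(cloud):
    rng = np.random.default_rng(11)
    dst = cloud + rng.normal(size=cloud.shape) * 0.3
    _, rms0 = landmark_transform(cloud, dst)
    pre = RigidTransform(Rotation.from_euler("xyz", [0.4, 1.1, -0.2]).as_matrix(),
                         np.array([4.0, 5.0, 6.0]))
    _, rms1 = landmark_transform(pre.apply(cloud), pre.apply(dst))
    assert np.isclose(rms0, rms1, rtol=1e-9)


def test_collinear_landmarks_rejected():
    pts = np.outer(np.arange(4.0), np.array([1.0, 2.0, 3.0]))
    with pytest.raises(DegenerateLandmarksError):
        landmark_transform(pts, pts)
    with pytest.raises(DegenerateLandmarksError):
        landmark_transform(pts[:2], pts[:2])


def test_compose_inverse_roundtrip(cloud):
    x1 = RigidTransform.about_axis([0, 0, 1], 37.0, point=[1, 2, 3])
    x2 = RigidTransform.translation([4, 5, 6])
    comp = x2.compose(x1)
    assert np.allclose(comp.inverse().apply(comp.apply(cloud)), cloud, atol=1e-10)
    assert np.isclose(x1.rotation_angle_deg(), 37.0)
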