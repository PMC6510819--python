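"""Rigid transforms and least-squares landmark registration.

Coordinate convention used throughout the package: origin at the tibial
plateau center, +x lateral, +y anterior, +z proximal, lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


class DegenerateLandmarksError(ValueError):
    """Raised when landmark sets are too degenerate to define a rigid transform."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R @ x + t (rotation then translation)."""

    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("RigidTransform needs a 3x3 rotation and 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("R is not a proper rotation (R R^T = I, det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.R.T + self.t

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, from the axis-angle decomposition."""
        return float(np.degrees(np.linalg.norm(Rotation.from_matrix(self.R).as_rotvec())))

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()

    @staticmethod
    def about_axis(axis: np.ndarray, angle_deg: float, point: np.ndarray | None = None) -> "RigidTransform":
        """Rotation by ``angle_deg`` about ``axis`` through ``point`` (default origin)."""
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()
        if point is None:
            return RigidTransform(R, np.zeros(3))
        p = np.asarray(point, dtype=float)
        return RigidTransform(R, p - R @ p)

    @staticmethod
    def translation(t: np.ndarray) -> "RigidTransform":
        return RigidTransform(np.eye(3), np.asarray(t, dtype=float))


def landmark_transform(
    source_landmarks: np.ndarray, target_landmarks: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid registration (Kabsch) of corresponding landmarks.

    Finds the proper rigid transform minimizing the RMS distance between
    transformed source points and target points. Returns the transform and
    the residual RMS in mm.

    Raises
    ------
    DegenerateLandmarksError
        If fewer than 3 points are given or the points are (near) collinear,
        in which case the rotation is not uniquely determined.
    """
    src = np.asarray(source_landmarks, dtype=float)
    dst = np.asarray(target_landmarks, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("landmark sets must be matching (n, 3) arrays")
    if src.shape[0] < 3:
        raise DegenerateLandmarksError("need at least 3 landmarks")
    c_src = src.mean(axis=0)
    c_dst = dst.mean(axis=0)
    a = src - c_src
    # Collinearity check: second singular value of the centered cloud.
    s = np.linalg.svd(a, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateLandmarksError("landmarks are collinear; rotation is ambiguous")
    rot, _ = Rotation.align_vectors(dst - c_dst, a)
    R = rot.as_matrix()
    t = c_dst - R @ c_src
    xform = RigidTransform(R, t)
    resid = xform.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return xform, rms
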