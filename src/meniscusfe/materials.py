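"""Linear-elastic constitutive models and stress-tensor utilities.

Articular cartilage is isotropic (E = 13 MPa, nu = 0.42 by default).  The
meniscus is transversely isotropic with the fiber (symmetry) axis along the
local circumferential direction: in-plane constants E_p = 20 MPa, nu_p = 0.2,
G_p = 8.3 MPa and fiber-direction constants E_f = 150 MPa, nu_f = 0.3,
G_f = 57.7 MPa by default.

Voigt ordering is fixed throughout the package as (11, 22, 33, 23, 13, 12)
with engineering shear strains.  ``nu_f`` is interpreted as the major
Poisson's ratio nu_12 (fiber-driven contraction of the transverse plane);
see docs/methods.md for the convention discussion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IsotropicElastic",
    "TransverselyIsotropicElastic",
    "MaterialAdmissibilityError",
    "stiffness_isotropic",
    "stiffness_transverse_isotropic",
    "rotate_stiffness",
    "principal_stresses",
    "CARTILAGE_DEFAULT",
    "MENISCUS_DEFAULT",
]

# Voigt index pairs for order (11, 22, 33, 23, 13, 12)
_VOIGT_PAIRS = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]


class MaterialAdmissibilityError(ValueError):
    """Elastic constants yield a non-positive-definite stiffness."""


@dataclass(frozen=True)
class IsotropicElastic:
    """Isotropic linear elasticity: Young's modulus E (MPa), Poisson nu."""

    E: float
    nu: float

    def validate(self) -> None:
        if self.E <= 0:
            raise MaterialAdmissibilityError(f"E must be > 0 (got {self.E})")
        if not (-1.0 < self.nu < 0.5):
            raise MaterialAdmissibilityError(f"nu must lie in (-1, 0.5) (got {self.nu})")


@dataclass(frozen=True)
class TransverselyIsotropicElastic:
    """Transverse isotropy about a fiber axis (local axis 1).

    E_p, nu_p, G_p: Young's modulus, Poisson's ratio and shear modulus in
    the plane of isotropy (transverse plane).  E_f, nu_f, G_f: the same for
    the fiber (circumferential) direction; nu_f is the major ratio nu_12 and
    G_f the fiber-plane shear modulus.  Units MPa.
    """

    E_p: float
    nu_p: float
    G_p: float
    E_f: float
    nu_f: float
    G_f: float

    def compliance_local(self) -> np.ndarray:
        """6x6 compliance in the local frame with axis 1 along the fiber."""
        Ep, nup, Gp = self.E_p, self.nu_p, self.G_p
        Ef, nuf, Gf = self.E_f, self.nu_f, self.G_f
        S = np.zeros((6, 6))
        S[0, 0] = 1 / Ef
        S[1, 1] = S[2, 2] = 1 / Ep
        S[0, 1] = S[1, 0] = S[0, 2] = S[2, 0] = -nuf / Ef
        S[1, 2] = S[2, 1] = -nup / Ep
        S[3, 3] = 1 / Gp          # shear in the plane of isotropy (23)
        S[4, 4] = S[5, 5] = 1 / Gf  # fiber-plane shear (13, 12)
        return S


def _check_spd(C: np.ndarray, what: str) -> None:
    w = np.linalg.eigvalsh(0.5 * (C + C.T))
    if w.min() <= 0:
        raise MaterialAdmissibilityError(
            f"{what}: stiffness not positive definite "
            f"(minimum eigenvalue {w.min():.4g} MPa <= 0); the elastic "
            "constants are thermodynamically inadmissible"
        )


def stiffness_isotropic(mat: IsotropicElastic) -> np.ndarray:
    """Standard isotropic 6x6 stiffness in Voigt (engineering-shear) notation."""
    mat.validate()
    E, nu = mat.E, mat.nu
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.diag_indices(3)] = lam + 2 * mu
    C[3, 3] = C[4, 4] = C[5, 5] = mu
    _check_spd(C, "isotropic material")
    return C


def _voigt_to_tensor(C: np.ndarray) -> np.ndarray:
    """Voigt stiffness (engineering shear) -> full 4th-order tensor."""
    T = np.zeros((3, 3, 3, 3))
    for a, (i, j) in enumerate(_VOIGT_PAIRS):
        for b, (k, l) in enumerate(_VOIGT_PAIRS):
            c = C[a, b]
            for ii, jj in ((i, j), (j, i)):
                for kk, ll in ((k, l), (l, k)):
                    T[ii, jj, kk, ll] = c
    return T


def _tensor_to_voigt(T: np.ndarray) -> np.ndarray:
    C = np.zeros((6, 6))
    for a, (i, j) in enumerate(_VOIGT_PAIRS):
        for b, (k, l) in enumerate(_VOIGT_PAIRS):
            C[a, b] = T[i, j, k, l]
    return C


def rotate_stiffness(C: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotate a Voigt stiffness by rotation Q (local -> global directions)."""
    T = _voigt_to_tensor(C)
    Tg = np.einsum("pi,qj,rk,sl,ijkl->pqrs", Q, Q, Q, Q, T, optimize=True)
    return _tensor_to_voigt(Tg)


def _fiber_frame(fiber_dir: np.ndarray) -> np.ndarray:
    """Orthonormal frame with local axis 1 along the fiber (columns of Q)."""
    a = np.asarray(fiber_dir, dtype=float)
    n = np.linalg.norm(a)
    if not np.isclose(n, 1.0, atol=1e-8):
        raise ValueError(f"fiber_dir must be a unit vector (|f| = {n:.6g})")
    a = a / n
    helper = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    b = np.cross(helper, a)
    b /= np.linalg.norm(b)
    c = np.cross(a, b)
    return np.stack([a, b, c], axis=1)


def stiffness_transverse_isotropic(
    mat: TransverselyIsotropicElastic, fiber_dir: np.ndarray
) -> np.ndarray:
    """6x6 global-frame stiffness for a transversely isotropic material.

    The compliance is assembled in the local fiber frame, inverted, and
    rotated to the global frame by the fourth-order tensor transformation.
    The in-plane response is invariant to the choice of transverse axes, so
    only the fiber direction matters; flipping the fiber sign leaves the
    stiffness unchanged.
    """
    S = mat.compliance_local()
    C_local = np.linalg.inv(S)
    _check_spd(C_local, "transversely isotropic material")
    Q = _fiber_frame(fiber_dir)
    return rotate_stiffness(C_local, Q)


def fiber_frames(fiber_dirs: np.ndarray) -> np.ndarray:
    """Batched orthonormal frames (E, 3, 3) with local axis 1 along each fiber."""
    a = np.asarray(fiber_dirs, dtype=float)
    a = a / np.linalg.norm(a, axis=1, keepdims=True)
    helper = np.where(np.abs(a[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    b = np.cross(helper, a)
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    c = np.cross(a, b)
    return np.stack([a, b, c], axis=2)


def stiffness_transverse_isotropic_batch(
    mat: TransverselyIsotropicElastic, fiber_dirs: np.ndarray
) -> np.ndarray:
    """Per-element global stiffnesses (E, 6, 6) for varying fiber directions."""
    C_local = np.linalg.inv(mat.compliance_local())
    _check_spd(C_local, "transversely isotropic material")
    T0 = _voigt_to_tensor(C_local)
    Q = fiber_frames(fiber_dirs)
    Tg = np.einsum("epi,eqj,erk,esl,ijkl->epqrs", Q, Q, Q, Q, T0, optimize=True)
    idx = np.array(_VOIGT_PAIRS)
    i, j = idx[:, 0], idx[:, 1]
    return Tg[:, i[:, None], j[:, None], i[None, :], j[None, :]]


def principal_stresses(sigma: np.ndarray) -> np.ndarray:
    """Sorted principal stresses (sigma1 >= sigma2 >= sigma3) of a symmetric
    stress tensor given either as a 3x3 matrix or a Voigt 6-vector.

    sigma1 is the maximum principal stress (the hoop-stress indicator in the
    meniscus); sigma3 the minimum (compressive contact indicator).
    Supports batched input: (..., 3, 3) or (..., 6).
    """
    s = np.asarray(sigma, dtype=float)
    if s.shape[-1] == 6 and (s.ndim == 1 or s.shape[-2:] != (3, 3)):
        m = np.zeros(s.shape[:-1] + (3, 3))
        m[..., 0, 0] = s[..., 0]
        m[..., 1, 1] = s[..., 1]
        m[..., 2, 2] = s[..., 2]
        m[..., 1, 2] = m[..., 2, 1] = s[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = s[..., 4]
        m[..., 0, 1] = m[..., 1, 0] = s[..., 5]
        s = m
    w = np.linalg.eigvalsh(0.5 * (s + np.swapaxes(s, -1, -2)))
    return w[..., ::-1]


CARTILAGE_DEFAULT = IsotropicElastic(E=13.0, nu=0.42)
MENISCUS_DEFAULT = TransverselyIsotropicElastic(
    E_p=20.0, nu_p=0.2, G_p=8.3, E_f=150.0, nu_f=0.3, G_f=57.7
)
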