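"""Constant-strain linear tetrahedron: B-matrices, stiffness, stress recovery.

Voigt ordering (11, 22, 33, 23, 13, 12) with engineering shear strains, as
documented in :mod:`meniscusfe.materials`.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


class InvertedElementError(ValueError):
    """A tetrahedron has non-positive signed volume."""


def shape_gradients(nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients and volumes for a batch of tets.

    Parameters
    ----------
    nodes : (M, 4, 3) array of element node coordinates.

    Returns
    -------
    grads : (M, 4, 3) array, grads[e, a] = grad N_a (constant per element).
    vols : (M,) signed volumes.
    """
    p = np.asarray(nodes, dtype=float)
    single = p.ndim == 2
    if single:
        p = p[None]
    M = np.concatenate([np.ones((len(p), 4, 1)), p], axis=2)  # (M,4,4)
    det = np.linalg.det(M)
    vols = det / 6.0
    if np.any(np.abs(vols) < 1e-14):
        raise InvertedElementError("degenerate tetrahedron (zero volume)")
    inv = np.linalg.inv(M)
    grads = np.transpose(inv[:, 1:, :], (0, 2, 1))  # (M, 4 nodes, 3 dims)
    return (grads[0], vols[0]) if single else (grads, vols)


def b_matrices(nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strain-displacement matrices B (M, 6, 12) and signed volumes (M,)."""
    grads, vols = shape_gradients(nodes)
    single = grads.ndim == 2
    if single:
        grads, vols = grads[None], np.atleast_1d(vols)
    m = len(grads)
    B = np.zeros((m, 6, 12))
    gx, gy, gz = grads[..., 0], grads[..., 1], grads[..., 2]
    cols = np.arange(4) * 3
    B[:, 0, cols + 0] = gx
    B[:, 1, cols + 1] = gy
    B[:, 2, cols + 2] = gz
    B[:, 3, cols + 1] = gz
    B[:, 3, cols + 2] = gy
    B[:, 4, cols + 0] = gz
    B[:, 4, cols + 2] = gx
    B[:, 5, cols + 0] = gy
    B[:, 5, cols + 1] = gx
    return (B[0], vols[0]) if single else (B, vols)


def element_stiffness_tet(nodes: np.ndarray, C: np.ndarray) -> np.ndarray:
    """12x12 stiffness K = V * B^T C B of one constant-strain tet.

    Raises :class:`InvertedElementError` for non-positive volume.
    """
    B, vol = b_matrices(np.asarray(nodes, dtype=float))
    if vol <= 0:
        raise InvertedElementError(f"element volume {vol:.3g} <= 0 (inverted element)")
    return vol * B.T @ C @ B


def assemble_stiffness(nodes: np.ndarray, tets: np.ndarray,
                       C_per_element: np.ndarray) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Global stiffness (3N x 3N CSR) plus per-element B and volumes."""
    B, vols = b_matrices(nodes[tets])
    if vols.min() <= 0:
        raise InvertedElementError("mesh contains inverted elements")
    Ke = np.einsum("e,eia,eij,ejb->eab", vols, B, C_per_element, B, optimize=True)
    dof = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(len(tets), 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                      shape=(3 * len(nodes), 3 * len(nodes))).tocsr()
    return K, B, vols


def element_strains(B: np.ndarray, tets: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Voigt strains (M, 6) from nodal displacements u (N, 3)."""
    ue = u[tets].reshape(len(tets), 12)
    return np.einsum("eij,ej->ei", B, ue)


def element_stresses(B: np.ndarray, tets: np.ndarray,
                     C_per_element: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Voigt stresses (M, 6) from nodal displacements."""
    eps = element_strains(B, tets, u)
    return np.einsum("eij,ej->ei", C_per_element, eps)
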