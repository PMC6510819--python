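"""Node-to-surface penalty contact with regularized Coulomb friction.

Each contact pair couples follower (slave) nodes to either a deformable
master facet set (triangles of the model mesh) or an analytic rigid surface.
The normal response is a tension-free penalty on the penetration gap; the
tangential response is a penalty on slip accumulated within the current load
step, capped at mu times the normal force (regularized stick-slip).
Projections and normals are recomputed from current coordinates each Newton
iteration, so sliding kinematics are updated between iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

DEFAULT_FRICTION = 0.02


class RigidSurface:
    """Analytic rigid master surface: signed gap and outward normal."""

    def gap_and_normal(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError


@dataclass(frozen=True)
class RigidPlane(RigidSurface):
    """Half-space master: material lies on the -normal side; gap = n.(p - p0)."""

    point: np.ndarray
    normal: np.ndarray

    def gap_and_normal(self, points):
        n = np.asarray(self.normal, float)
        n = n / np.linalg.norm(n)
        g = (np.asarray(points) - np.asarray(self.point, float)) @ n
        return g, np.broadcast_to(n, (len(points), 3))


@dataclass(frozen=True)
class RigidSphere(RigidSurface):
    """Rigid spherical indenter; gap measured outward from the sphere surface."""

    center: np.ndarray
    radius: float

    def gap_and_normal(self, points):
        d = np.asarray(points) - np.asarray(self.center, float)
        r = np.linalg.norm(d, axis=1)
        r = np.maximum(r, 1e-12)
        return r - self.radius, d / r[:, None]


@dataclass
class ContactPair:
    """One follower-node set against one master surface.

    master is either an (F, 3) triangle index array into the model mesh
    (outward-oriented winding) or a :class:`RigidSurface`.
    """

    name: str
    slave_nodes: np.ndarray          # (S,) node ids
    slave_areas: np.ndarray          # (S,) tributary areas, mm^2
    master: object                   # (F, 3) int array or RigidSurface
    friction_mu: float = DEFAULT_FRICTION
    penalty_normal: float = 650.0    # N/mm^3
    penalty_tangent: float | None = None  # defaults to penalty_normal
    kind: str = "deformable-deformable"
    search_radius: float = 5.0       # mm; projections beyond this are ignored
    smoothing_gap: float = 0.01      # mm; C1 quadratic blend of the penalty law
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.friction_mu < 0:
            raise ValueError("friction_mu must be >= 0")
        if self.penalty_normal <= 0:
            raise ValueError("penalty_normal must be > 0")
        if self.penalty_tangent is None:
            self.penalty_tangent = self.penalty_normal

    @property
    def is_rigid(self) -> bool:
        return isinstance(self.master, RigidSurface)


def tributary_areas(nodes: np.ndarray, tris: np.ndarray, node_ids: np.ndarray) -> np.ndarray:
    """Per-node tributary area: one third of adjacent facet areas."""
    p = nodes[tris]
    a = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
    acc = np.zeros(len(nodes))
    np.add.at(acc, tris.ravel(), np.repeat(a / 3.0, 3))
    return acc[node_ids]


def _closest_point_triangles(p: np.ndarray, tri_pts: np.ndarray):
    """Closest points of query points on candidate triangles.

    p : (S, 3); tri_pts : (S, K, 3, 3).  Returns (S, K, 3) closest points and
    (S, K, 3) barycentric weights.  Vectorized Ericson-style clamp.
    """
    a, b, c = tri_pts[..., 0, :], tri_pts[..., 1, :], tri_pts[..., 2, :]
    q = p[:, None, :]
    ab, ac, ap = b - a, c - a, q - a

    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = q - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp = q - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    shape = d1.shape
    u = np.zeros(shape)
    v = np.zeros(shape)
    w = np.zeros(shape)

    # region masks, applied in priority order
    m_a = (d1 <= 0) & (d2 <= 0)
    m_b = (d3 >= 0) & (d4 <= d3)
    m_c = (d6 >= 0) & (d5 <= d6)
    denom_ab = d1 - d3
    m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    m_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    done = np.zeros(shape, bool)

    def setbar(mask, uu, vv, ww):
        nonlocal done
        m = mask & ~done
        u[m], v[m], w[m] = (uu[m] if isinstance(uu, np.ndarray) else uu,
                            vv[m] if isinstance(vv, np.ndarray) else vv,
                            ww[m] if isinstance(ww, np.ndarray) else ww)
        done = done | m

    with np.errstate(divide="ignore", invalid="ignore"):
        setbar(m_a, 1.0, 0.0, 0.0)
        setbar(m_b, 0.0, 1.0, 0.0)
        setbar(m_c, 0.0, 0.0, 1.0)
        t_ab = np.where(np.abs(denom_ab) > 0, d1 / np.where(denom_ab != 0, denom_ab, 1.0), 0.0)
        setbar(m_ab, 1.0 - t_ab, t_ab, 0.0)
        t_ac = np.where(np.abs(d2 - d6) > 0, d2 / np.where((d2 - d6) != 0, d2 - d6, 1.0), 0.0)
        setbar(m_ac, 1.0 - t_ac, 0.0, t_ac)
        den_bc = (d4 - d3) + (d5 - d6)
        t_bc = np.where(den_bc != 0, (d4 - d3) / np.where(den_bc != 0, den_bc, 1.0), 0.0)
        setbar(m_bc, 0.0, 1.0 - t_bc, t_bc)
        denom = va + vb + vc
        vv = np.where(denom != 0, vb / np.where(denom != 0, denom, 1.0), 0.0)
        ww = np.where(denom != 0, vc / np.where(denom != 0, denom, 1.0), 0.0)
        setbar(~done, 1.0 - vv - ww, vv, ww)

    bary = np.stack([u, v, w], axis=-1)
    closest = np.einsum("...k,...ki->...i", bary, tri_pts)
    return closest, bary


@dataclass
class ContactState:
    """Per-iteration evaluation of one pair: geometry, forces, status."""

    pair: ContactPair
    active: np.ndarray            # (A,) indices into pair.slave_nodes
    gap: np.ndarray               # (A,) signed gaps (negative = penetration)
    normal: np.ndarray            # (A, 3)
    facet: np.ndarray | None      # (A,) master facet index, None for rigid
    bary: np.ndarray | None       # (A, 3)
    fn: np.ndarray = field(default=None)  # (A,) normal force magnitudes
    ft: np.ndarray = field(default=None)  # (A, 3) tangential force vectors
    status: np.ndarray = field(default=None)  # (A,) 'stick'/'slip'
    all_gap: np.ndarray = field(default=None)  # (S,) gap per slave node
    kn_scale: np.ndarray = field(default=None)  # (A,) smoothed-stiffness factor


def evaluate_contact(pair: ContactPair, coords: np.ndarray, u: np.ndarray,
                     u_ref: np.ndarray, k_candidates: int = 8,
                     friction_memory: np.ndarray | None = None,
                     friction_frozen: bool = False) -> ContactState | None:
    """Evaluate gaps, penalty forces and friction for one pair.

    coords are reference coordinates (N, 3), u current displacements,
    u_ref the displacements at the start of the load step (slip reference).
    Returns None when the pair is disabled or nothing is near contact.
    """
    if not pair.enabled:
        return None
    pos = coords + u
    ps = pos[pair.slave_nodes]

    if pair.is_rigid:
        gap, normal = pair.master.gap_and_normal(ps)
        near = gap < pair.search_radius
        if not np.any(near):
            return None
        idx = np.flatnonzero(near)
        state = ContactState(pair, idx, gap[idx], normal[idx], None, None)
        all_gap = gap
    else:
        tris = pair.master
        pm = pos[tris]
        centroids = pm.mean(axis=1)
        tree = cKDTree(centroids)
        k = min(k_candidates, len(tris))
        _, cand = tree.query(ps, k=k)
        cand = np.atleast_2d(cand.T).T if cand.ndim == 1 else cand
        tri_pts = pos[tris[cand]]                      # (S, K, 3, 3)
        closest, bary = _closest_point_triangles(ps, tri_pts)
        dvec = ps[:, None, :] - closest
        dist = np.linalg.norm(dvec, axis=2)
        best = np.argmin(dist, axis=1)
        rows = np.arange(len(ps))
        facet = cand[rows, best]
        bary = bary[rows, best]
        proj = closest[rows, best]
        tp = pos[tris[facet]]
        nrm = np.cross(tp[:, 1] - tp[:, 0], tp[:, 2] - tp[:, 0])
        nn = np.linalg.norm(nrm, axis=1)
        nrm = nrm / np.maximum(nn, 1e-14)[:, None]
        gap = np.einsum("ij,ij->i", ps - proj, nrm)
        near = np.abs(gap) < pair.search_radius
        if not np.any(near):
            return None
        idx = np.flatnonzero(near)
        state = ContactState(pair, idx, gap[idx], nrm[idx], facet[idx], bary[idx])
        all_gap = gap

    pen = state.gap < 0.0
    idx = state.active[pen]
    gap = state.gap[pen]
    normal = state.normal[pen]
    facet = None if state.facet is None else state.facet[pen]
    bary = None if state.bary is None else state.bary[pen]

    areas = pair.slave_areas[idx]
    # C1-regularized penalty: quadratic ramp over the first ``smoothing_gap``
    # of penetration, linear beyond; removes active-set chatter at grazing
    # contacts (the equilibrium forces are set by the load, the extra
    # penetration offset is g0/2 at most)
    g0 = max(pair.smoothing_gap, 1e-9)
    depth = -gap
    fn = pair.penalty_normal * areas * np.where(
        depth < g0, depth**2 / (2 * g0), depth - g0 / 2)
    kn_scale = np.minimum(depth / g0, 1.0)

    # friction: penalty on slip accumulated within the load step, relative to
    # the master surface, capped at mu * fn
    s_ids = pair.slave_nodes[idx]
    du = u[s_ids] - u_ref[s_ids]
    if facet is not None:
        tris = pair.master
        dm = np.einsum("ak,aki->ai", bary, (u - u_ref)[tris[facet]])
        du = du - dm
    dt = du - np.einsum("ij,ij->i", du, normal)[:, None] * normal
    ft = -pair.penalty_tangent * areas[:, None] * dt
    ftn = np.linalg.norm(ft, axis=1)
    cap = pair.friction_mu * fn
    slip = ftn > cap
    scale = np.ones(len(ft))
    nonzero = ftn > 1e-14
    scale[slip & nonzero] = (cap[slip & nonzero] / ftn[slip & nonzero])
    ft = ft * scale[:, None]

    if friction_frozen and friction_memory is not None:
        # late-iteration treatment: hold the lagged friction forces constant
        # (rescaled to the current Coulomb cap) so the Newton loop closes on
        # the remaining smooth problem; the frozen state is within the
        # regularization error of the Coulomb model
        ft = friction_memory[idx].copy()
        ftn3 = np.linalg.norm(ft, axis=1)
        over = ftn3 > cap
        nz = ftn3 > 1e-14
        sc = np.ones(len(ft))
        sc[over & nz] = cap[over & nz] / ftn3[over & nz]
        ft = ft * sc[:, None]
        status = np.full(len(ft), "slip")
        out = ContactState(pair, idx, gap, normal, facet, bary, fn, ft, status, all_gap)
        out.kn_scale = kn_scale
        return out

    # under-relax against the previous iterate (lagged friction): near the
    # slip cap the trial direction flips for vanishing slip increments, so
    # the raw fixed point chatters; averaging restores convergence while the
    # converged force still satisfies the Coulomb cap
    if friction_memory is not None:
        ft = 0.5 * (ft + friction_memory[idx])
        ftn2 = np.linalg.norm(ft, axis=1)
        over = ftn2 > cap
        nz = ftn2 > 1e-14
        sc = np.ones(len(ft))
        sc[over & nz] = cap[over & nz] / ftn2[over & nz]
        ft = ft * sc[:, None]
        friction_memory[:] *= 0.5
        friction_memory[idx] = ft

    status = np.where(slip, "slip", "stick")
    out = ContactState(pair, idx, gap, normal, facet, bary, fn, ft, status, all_gap)
    out.kn_scale = kn_scale
    return out


def accumulate_contact(state: ContactState, f: np.ndarray,
                       rows: list, cols: list, vals: list) -> None:
    """Add contact nodal forces to f (3N,) and tangent triplets to COO lists.

    The tangent is the penalty gap stiffness p A n n^T (plus the stick
    tangential penalty) distributed over slave and master-facet nodes with
    coefficients (+1, -w_i); friction in the slip state contributes force
    only (secant treatment).
    """
    if state is None or state.fn is None or len(state.active) == 0:
        return
    pair = state.pair
    s_ids = pair.slave_nodes[state.active]
    areas = pair.slave_areas[state.active]
    n = state.normal
    force = state.fn[:, None] * n + state.ft

    np.add.at(f, (3 * s_ids[:, None] + np.arange(3)).ravel(), force.ravel())

    stick = state.status == "stick"
    kt = pair.penalty_tangent * areas * stick
    kn = pair.penalty_normal * areas * getattr(state, "kn_scale", 1.0)
    # per-contact 3x3 block: kn n n^T + kt (I - n n^T)
    nnT = np.einsum("ai,aj->aij", n, n)
    blocks = kn[:, None, None] * nnT + kt[:, None, None] * (np.eye(3)[None] - nnT)

    if state.facet is None:
        _add_blocks(rows, cols, vals, s_ids, s_ids, blocks)
    else:
        tris = pair.master[state.facet]  # (A, 3)
        mforce = -force[:, None, :] * state.bary[:, :, None]
        np.add.at(f, (3 * tris[:, :, None] + np.arange(3)).ravel(), mforce.ravel())
        coeff_nodes = np.concatenate([s_ids[:, None], tris], axis=1)      # (A, 4)
        coeff = np.concatenate([np.ones((len(s_ids), 1)), -state.bary], axis=1)
        for a in range(4):
            for b in range(4):
                cab = coeff[:, a] * coeff[:, b]
                _add_blocks(rows, cols, vals, coeff_nodes[:, a], coeff_nodes[:, b],
                            cab[:, None, None] * blocks)


def _add_blocks(rows, cols, vals, ni, nj, blocks) -> None:
    r = (3 * ni[:, None, None] + np.arange(3)[None, :, None])
    c = (3 * nj[:, None, None] + np.arange(3)[None, None, :])
    rows.append(np.broadcast_to(r, blocks.shape).ravel())
    cols.append(np.broadcast_to(c, blocks.shape).ravel())
    vals.append(np.asarray(blocks).ravel())
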