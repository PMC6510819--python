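"""Parametric synthetic tibiofemoral geometry.

A stand-in for subject-specific segmented imaging: rigid bones represented by
analytic articular surfaces (femoral condyles as spheres, tibial plateau as
shallow elliptic dishes), cartilage layers of uniform thickness, and two
C-shaped menisci with a wedge cross-section swept along a circular arc. The
meniscal inferior surface is congruent with the tibial cartilage surface, and
the anterior/posterior ends terminate in flat faces where the insertional
(horn) ligaments attach.

Coordinates: origin at the tibial plateau center, +x lateral, +y anterior,
+z proximal; all lengths in mm.  The medial compartment is at x < 0.

Each meniscus is parameterized by an arc coordinate ``phi`` (degrees, running
anterior -> posterior), a normalized radial coordinate ``s`` in [0, 1] from
the inner to the outer rim, and a height fraction ``v`` in [0, 1] from the
inferior to the superior surface.  The medial meniscus uses counterclockwise
chirality (+1), the lateral clockwise (-1), so that equal parameter sets
produce exact sagittal mirror images.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .transforms import RigidTransform, landmark_transform

SIDES = ("MM", "LM")


class GeometryParameterError(ValueError):
    """A knee-geometry parameter violates a validity invariant."""


def _default_ligament_offsets() -> dict:
    # Offset from the horn terminal-face centroid to the tibial insertion,
    # expressed in the horn's local frame: (along the outgoing arc tangent,
    # horizontal normal, vertical).  Continues the arc and dips into the bone.
    return {
        "lateral_anterior": (6.0, 0.0, -1.5),
        "lateral_posterior": (6.0, 0.0, -1.5),
        "medial_anterior": (6.0, 0.0, -1.5),
        "medial_posterior": (6.0, 0.0, -1.5),
    }


@dataclass
class KneeGeometryParams:
    """Free parameters of the synthetic knee (units mm / degrees).

    Defaults approximate an adult knee sized to the reported subject. The
    femoral condyles are spheres (per compartment) whose radii reflect the
    relatively flat distal articular profile; meniscal radii/heights are
    chosen so the condyle nests on the wedge and load is shared between
    meniscus and central cartilage.
    """

    condyle_radius_medial: float = 26.0
    condyle_radius_lateral: float = 25.0
    condyle_separation: float = 46.0
    plateau_halfwidth: float = 38.0
    cartilage_thickness_femoral: float = 2.0
    cartilage_thickness_tibial: float = 2.0

    meniscus_outer_radius_MM: float = 20.0
    meniscus_outer_radius_LM: float = 19.0
    meniscus_inner_radius_MM: float = 10.0
    meniscus_inner_radius_LM: float = 9.5
    meniscus_peripheral_height_MM: float = 6.0
    meniscus_peripheral_height_LM: float = 5.5
    arc_start_deg_MM: float = 55.0
    arc_end_deg_MM: float = 295.0
    arc_start_deg_LM: float = -120.0
    arc_end_deg_LM: float = 110.0

    ligament_insertion_offsets: dict = field(default_factory=_default_ligament_offsets)
    random_seed: int = 0

    # Shape details not taken from imaging (see docs/methods.md).
    inner_height_fraction: float = 0.15
    dish_depth: float = 2.0
    dish_semiaxis_ml: float = 25.0
    dish_semiaxis_ap: float = 27.0
    condyle_cap_angle_ml_deg: float = 55.0
    condyle_cap_angle_ap_deg: float = 80.0
    seating_clearance: float = 0.0
    surface_roughness_mm: float = 0.0

    def arc_span(self, side: str) -> float:
        return getattr(self, f"arc_end_deg_{side}") - getattr(self, f"arc_start_deg_{side}")

    def validate(self) -> None:
        for side in SIDES:
            ro = getattr(self, f"meniscus_outer_radius_{side}")
            ri = getattr(self, f"meniscus_inner_radius_{side}")
            hp = getattr(self, f"meniscus_peripheral_height_{side}")
            if not (ro > ri > 0):
                raise GeometryParameterError(
                    f"meniscus {side}: requires outer_radius > inner_radius > 0 "
                    f"(got outer={ro}, inner={ri})"
                )
            if hp <= 0:
                raise GeometryParameterError(f"meniscus {side}: peripheral_height must be > 0")
            if self.arc_span(side) <= 0:
                raise GeometryParameterError(f"meniscus {side}: requires arc_end > arc_start")
        if self.arc_span("MM") < self.arc_span("LM"):
            raise GeometryParameterError(
                "medial meniscus arc span must be >= lateral (more open C-shape)"
            )
        if not (0.0 < self.inner_height_fraction < 0.25):
            raise GeometryParameterError(
                "inner_height_fraction must lie in (0, 0.25): the wedge tapers "
                "to a near-zero inner edge"
            )
        for name in ("condyle_radius_medial", "condyle_radius_lateral",
                     "cartilage_thickness_femoral", "cartilage_thickness_tibial",
                     "condyle_separation", "plateau_halfwidth"):
            if getattr(self, name) <= 0:
                raise GeometryParameterError(f"{name} must be > 0")


@dataclass(frozen=True)
class TibialDish:
    """Shallow elliptic-paraboloid articular dish of one tibial compartment.

    z(x, y) = depth * (((x - cx)/a)^2 + (y/b)^2), minimum 0 at the
    compartment center; the tibial cartilage top surface follows this dish.
    """

    center_x: float
    depth: float
    semiaxis_ml: float
    semiaxis_ap: float

    def z(self, x, y):
        return self.depth * (((np.asarray(x) - self.center_x) / self.semiaxis_ml) ** 2
                             + (np.asarray(y) / self.semiaxis_ap) ** 2)


@dataclass(frozen=True)
class FemoralCondyle:
    """Spherical condylar bone surface plus a uniform cartilage layer."""

    center: np.ndarray  # (3,)
    bone_radius: float
    cartilage_thickness: float

    @property
    def articular_radius(self) -> float:
        return self.bone_radius + self.cartilage_thickness

    def lowest_surface_z(self, x, y) -> np.ndarray:
        """z of the (lower) articular sphere surface above (x, y); NaN outside."""
        d2 = (np.asarray(x) - self.center[0]) ** 2 + (np.asarray(y) - self.center[1]) ** 2
        r2 = self.articular_radius**2
        with np.errstate(invalid="ignore"):
            return np.where(d2 < r2, self.center[2] - np.sqrt(np.maximum(r2 - d2, 0.0)), np.nan)


@dataclass(frozen=True)
class MeniscusShape:
    """Analytic swept-wedge meniscus of one compartment.

    The cross-section is a right-triangle wedge: flat inferior face on the
    tibial dish, vertical peripheral wall of height ``h_peri`` at the outer
    rim, sloped superior face tapering to a small inner-edge height.
    """

    side: str
    center_x: float
    chirality: int  # +1 medial, -1 lateral
    r_inner: float
    r_outer: float
    h_inner: float
    h_peri: float
    arc_start_deg: float
    arc_end_deg: float
    dish: TibialDish

    @property
    def rim_width(self) -> float:
        return self.r_outer - self.r_inner

    @property
    def arc_span_rad(self) -> float:
        return np.radians(self.arc_end_deg - self.arc_start_deg)

    def height(self, s):
        return self.h_inner + np.asarray(s) * (self.h_peri - self.h_inner)

    def _angle(self, phi_deg):
        return self.chirality * np.radians(np.asarray(phi_deg))

    def point(self, phi_deg, s, v):
        """Map (arc deg, radial fraction, height fraction) to xyz."""
        ang = self._angle(phi_deg)
        r = self.r_inner + np.asarray(s) * self.rim_width
        x = self.center_x + r * np.cos(ang)
        y = r * np.sin(ang)
        z = self.dish.z(x, y) + np.asarray(v) * self.height(s)
        return np.stack(np.broadcast_arrays(x, y, z), axis=-1)

    def polar(self, points):
        """Inverse horizontal map: xyz (or xy) -> (phi_deg, s)."""
        p = np.asarray(points, dtype=float)
        dx = p[..., 0] - self.center_x
        dy = p[..., 1]
        ang = np.arctan2(dy, dx) * self.chirality
        phi = np.degrees(ang)
        # unwrap into the arc range
        lo = self.arc_start_deg
        phi = (phi - lo) % 360.0 + lo
        r = np.hypot(dx, dy)
        s = (r - self.r_inner) / self.rim_width
        return phi, s

    def fiber_direction(self, phi_deg):
        """Unit circumferential tangent, oriented anterior->posterior."""
        ang = self._angle(phi_deg)
        t = np.stack(np.broadcast_arrays(
            -np.sin(ang) * self.chirality, np.cos(ang) * self.chirality,
            np.zeros_like(ang)), axis=-1)
        return t

    def analytic_volume(self) -> float:
        """Exact volume of the vertically extruded wedge over the arc sector."""
        ri, w = self.r_inner, self.rim_width
        hi, hp = self.h_inner, self.h_peri
        # V = span * int_{r_i}^{r_o} h(s(r)) r dr,  h linear in s = (r-ri)/w
        a = hi
        b = (hp - hi) / w
        ro = self.r_outer
        integral = a * (ro**2 - ri**2) / 2 + b * ((ro**3 - ri**3) / 3 - ri * (ro**2 - ri**2) / 2)
        return float(self.arc_span_rad * integral)


@dataclass
class KneeGeometry:
    """Assembled analytic knee: bones, cartilage layers, menisci, attachments."""

    params: KneeGeometryParams
    condyles: dict            # side name 'medial'/'lateral' -> FemoralCondyle
    dishes: dict              # 'medial'/'lateral' -> TibialDish
    menisci: dict             # 'MM'/'LM' -> MeniscusShape
    ligament_attachments: dict  # ligament name -> (horn_point, tibial_insertion)
    landmarks: dict           # name -> (3,) point

    @property
    def condyle_center_z(self) -> float:
        return float(self.condyles["medial"].center[2])

    def compartment_of(self, side: str) -> str:
        return "medial" if side == "MM" else "lateral"


@dataclass(frozen=True)
class BonePose:
    """Rigid femur pose for one flexion angle."""

    flexion_angle: float
    transform: RigidTransform
    source: str = "parametric"  # or "landmark_registered"


def _meniscus_shape(params: KneeGeometryParams, side: str, dish: TibialDish) -> MeniscusShape:
    comp_sign = -1.0 if side == "MM" else 1.0
    hp = getattr(params, f"meniscus_peripheral_height_{side}")
    return MeniscusShape(
        side=side,
        center_x=comp_sign * params.condyle_separation / 2,
        chirality=+1 if side == "MM" else -1,
        r_inner=getattr(params, f"meniscus_inner_radius_{side}"),
        r_outer=getattr(params, f"meniscus_outer_radius_{side}"),
        h_inner=params.inner_height_fraction * hp,
        h_peri=hp,
        arc_start_deg=getattr(params, f"arc_start_deg_{side}"),
        arc_end_deg=getattr(params, f"arc_end_deg_{side}"),
        dish=dish,
    )


def seat_femur_height(
    dishes: dict, menisci: dict, condyle_centers_xy: dict,
    radii: dict, clearance: float = 0.0, n_samples: int = 48,
) -> float:
    """Vertical condyle-center height at which the femoral cartilage first
    touches the tibial side (cartilage top or meniscus superior surface).

    ``condyle_centers_xy``/``radii`` map compartment name -> horizontal center /
    articular (cartilage outer) radius.  Returns the common center z giving a
    minimum surface gap equal to ``clearance``.
    """
    z_req = -np.inf
    for comp in ("medial", "lateral"):
        cx, cy = condyle_centers_xy[comp]
        R = radii[comp]
        dish = dishes[comp]
        side = "MM" if comp == "medial" else "LM"
        men = menisci[side]
        # candidate target points: tibial cartilage top over the dish domain
        g = np.linspace(-0.9, 0.9, n_samples)
        gx, gy = np.meshgrid(dish.center_x + g * dish.semiaxis_ml, g * dish.semiaxis_ap)
        pts = [np.stack([gx.ravel(), gy.ravel(), dish.z(gx, gy).ravel()], axis=-1)]
        # and the meniscus superior surface
        phi = np.linspace(men.arc_start_deg, men.arc_end_deg, 3 * n_samples)
        s = np.linspace(0.0, 1.0, n_samples // 2)
        P, S = np.meshgrid(phi, s)
        pts.append(men.point(P, S, 1.0).reshape(-1, 3))
        p = np.concatenate(pts, axis=0)
        d2 = (p[:, 0] - cx) ** 2 + (p[:, 1] - cy) ** 2
        ok = d2 < (0.98 * R) ** 2
        if not np.any(ok):
            continue
        z_req = max(z_req, np.max(p[ok, 2] + np.sqrt(R**2 - d2[ok])))
    if not np.isfinite(z_req):
        raise GeometryParameterError("condyles do not overhang any tibial surface")
    return float(z_req + clearance)


def generate_geometry(params: KneeGeometryParams | None = None) -> KneeGeometry:
    """Build the analytic knee geometry from parameters.

    Deterministic for a given parameter set (``random_seed`` only perturbs
    optional surface roughness, which defaults to zero).
    """
    params = params if params is not None else KneeGeometryParams()
    params.validate()

    dishes = {
        "medial": TibialDish(-params.condyle_separation / 2, params.dish_depth,
                             params.dish_semiaxis_ml, params.dish_semiaxis_ap),
        "lateral": TibialDish(params.condyle_separation / 2, params.dish_depth,
                              params.dish_semiaxis_ml, params.dish_semiaxis_ap),
    }
    menisci = {side: _meniscus_shape(params, side, dishes["medial" if side == "MM" else "lateral"])
               for side in SIDES}

    centers_xy = {"medial": (-params.condyle_separation / 2, 0.0),
                  "lateral": (params.condyle_separation / 2, 0.0)}
    radii = {"medial": params.condyle_radius_medial + params.cartilage_thickness_femoral,
             "lateral": params.condyle_radius_lateral + params.cartilage_thickness_femoral}
    zc = seat_femur_height(dishes, menisci, centers_xy, radii,
                           clearance=params.seating_clearance)

    condyles = {
        "medial": FemoralCondyle(np.array([centers_xy["medial"][0], 0.0, zc]),
                                 params.condyle_radius_medial,
                                 params.cartilage_thickness_femoral),
        "lateral": FemoralCondyle(np.array([centers_xy["lateral"][0], 0.0, zc]),
                                  params.condyle_radius_lateral,
                                  params.cartilage_thickness_femoral),
    }

    attachments = {}
    for side, prefix in (("LM", "lateral"), ("MM", "medial")):
        men = menisci[side]
        for horn, phi in (("anterior", men.arc_start_deg), ("posterior", men.arc_end_deg)):
            name = f"{prefix}_{horn}"
            s_mid = 0.5
            horn_pt = men.point(phi, s_mid, 0.5)
            tangent = men.fiber_direction(phi)
            outgoing = -tangent if horn == "anterior" else tangent
            off = np.asarray(params.ligament_insertion_offsets[name], dtype=float)
            radial = np.array([np.cos(men._angle(phi)), np.sin(men._angle(phi)), 0.0])
            insertion = horn_pt + off[0] * outgoing + off[1] * radial + off[2] * np.array([0, 0, 1.0])
            attachments[name] = (horn_pt, insertion)

    half_sep = params.condyle_separation / 2
    landmarks = {
        "medial_epicondyle": np.array([-(half_sep + 12.0), 0.0, zc]),
        "lateral_epicondyle": np.array([half_sep + 12.0, 0.0, zc]),
        "adductor_tubercle": np.array([-(half_sep + 9.0), 2.0, zc + 18.0]),
    }

    return KneeGeometry(params=params, condyles=condyles, dishes=dishes,
                        menisci=menisci, ligament_attachments=attachments,
                        landmarks=landmarks)


def pose_femur(
    geometry: KneeGeometry,
    flexion_angle: float,
    screw_home_coupling_deg: float = 5.0,
    rollback_mm_per_deg: float = 0.1,
) -> BonePose:
    """Parametric femur pose at a flexion angle in [0, 30] degrees.

    Flexion rotates the femur about the fixed axis through the condylar
    centers (the +x direction at the condylar center height).  A prescribed
    internal-rotation component (default 5 degrees, accrued linearly over
    0 -> 20 degrees of flexion and held thereafter) emulates screw-home
    coupling, and a small posterior translation emulates femoral rollback.
    """
    if not (0.0 <= flexion_angle <= 30.0):
        raise ValueError(f"flexion angle {flexion_angle} outside supported range [0, 30]")
    zc = geometry.condyle_center_z
    flex = RigidTransform.about_axis([1.0, 0, 0], flexion_angle, point=[0, 0, zc])
    # internal rotation of the femur: lateral condyle translates posteriorly
    psi = -screw_home_coupling_deg * min(flexion_angle, 20.0) / 20.0
    twist = RigidTransform.about_axis([0, 0, 1.0], psi)
    rollback = RigidTransform.translation([0.0, -rollback_mm_per_deg * flexion_angle, 0.0])
    return BonePose(flexion_angle=flexion_angle,
                    transform=rollback.compose(twist.compose(flex)),
                    source="parametric")


def pose_femur_from_landmarks(
    geometry: KneeGeometry, flexion_angle: float, target_landmarks: dict
) -> BonePose:
    """Femur pose registered from observed landmark positions (per-pose
    bone landmark sets), via least-squares rigid registration."""
    names = sorted(set(geometry.landmarks) & set(target_landmarks))
    src = np.array([geometry.landmarks[n] for n in names])
    dst = np.array([target_landmarks[n] for n in names])
    xform, _ = landmark_transform(src, dst)
    return BonePose(flexion_angle=flexion_angle, transform=xform,
                    source="landmark_registered")


def mirror_params(params: KneeGeometryParams) -> KneeGeometryParams:
    """Parameters of the sagittally mirrored knee (MM <-> LM roles swapped).

    A point of the medial meniscus at arc angle phi maps to arc angle
    phi - 180 in the lateral chirality convention, and vice versa.
    """
    p = dataclasses.replace(
        params,
        condyle_radius_medial=params.condyle_radius_lateral,
        condyle_radius_lateral=params.condyle_radius_medial,
        meniscus_outer_radius_MM=params.meniscus_outer_radius_LM,
        meniscus_outer_radius_LM=params.meniscus_outer_radius_MM,
        meniscus_inner_radius_MM=params.meniscus_inner_radius_LM,
        meniscus_inner_radius_LM=params.meniscus_inner_radius_MM,
        meniscus_peripheral_height_MM=params.meniscus_peripheral_height_LM,
        meniscus_peripheral_height_LM=params.meniscus_peripheral_height_MM,
        arc_start_deg_MM=params.arc_start_deg_LM + 180.0,
        arc_end_deg_MM=params.arc_end_deg_LM + 180.0,
        arc_start_deg_LM=params.arc_start_deg_MM - 180.0,
        arc_end_deg_LM=params.arc_end_deg_MM - 180.0,
        ligament_insertion_offsets={
            "lateral_anterior": params.ligament_insertion_offsets["medial_anterior"],
            "lateral_posterior": params.ligament_insertion_offsets["medial_posterior"],
            "medial_anterior": params.ligament_insertion_offsets["lateral_anterior"],
            "medial_posterior": params.ligament_insertion_offsets["lateral_posterior"],
        },
    )
    return p
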