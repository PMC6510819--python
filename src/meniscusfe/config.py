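"""Experiment configuration: schema validation with defaults matching the
study protocol (printed material constants, ligament stiffnesses, friction
coefficient, loads and flexion angles, full tear matrix at one body weight).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .geometry import KneeGeometryParams
from .materials import IsotropicElastic, TransverselyIsotropicElastic
from .meshing import MeshResolution
from .tears import TearSpec


class ConfigError(ValueError):
    """Schema violation, reporting the path to the offending key."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="allow")


class GeometryConfig(_Model):
    condyle_radius_medial: float = Field(26.0, gt=0)
    condyle_radius_lateral: float = Field(25.0, gt=0)
    condyle_separation: float = Field(46.0, gt=0)
    plateau_halfwidth: float = Field(38.0, gt=0)
    cartilage_thickness_femoral: float = Field(2.0, gt=0)
    cartilage_thickness_tibial: float = Field(2.0, gt=0)
    meniscus_outer_radius_MM: float = Field(20.0, gt=0)
    meniscus_outer_radius_LM: float = Field(19.0, gt=0)
    meniscus_inner_radius_MM: float = Field(10.0, gt=0)
    meniscus_inner_radius_LM: float = Field(9.5, gt=0)
    meniscus_peripheral_height_MM: float = Field(6.0, gt=0)
    meniscus_peripheral_height_LM: float = Field(5.5, gt=0)
    arc_start_deg_MM: float = 55.0
    arc_end_deg_MM: float = 295.0
    arc_start_deg_LM: float = -120.0
    arc_end_deg_LM: float = 110.0
    random_seed: int = 0

    def to_params(self) -> KneeGeometryParams:
        known = {k: getattr(self, k) for k in type(self).model_fields}
        return KneeGeometryParams(**known)


class CartilageMaterialConfig(_Model):
    E: float = Field(13.0, gt=0)
    nu: float = Field(0.42, gt=-1, lt=0.5)


class MeniscusMaterialConfig(_Model):
    E_p: float = Field(20.0, gt=0)
    nu_p: float = 0.2
    G_p: float = Field(8.3, gt=0)
    E_f: float = Field(150.0, gt=0)
    nu_f: float = 0.3
    G_f: float = Field(57.7, gt=0)


class MaterialsConfig(_Model):
    cartilage: CartilageMaterialConfig = CartilageMaterialConfig()
    meniscus: MeniscusMaterialConfig = MeniscusMaterialConfig()


class LigamentsConfig(_Model):
    lateral_anterior: float = Field(216.0, gt=0)
    lateral_posterior: float = Field(130.0, gt=0)
    medial_anterior: float = Field(169.0, gt=0)
    medial_posterior: float = Field(207.0, gt=0)


class MeshConfig(_Model):
    circumferential_divisions: int = Field(22, ge=2)
    radial_divisions: int = Field(6, ge=3)
    vertical_divisions: int = Field(2, ge=2)
    cartilage_divisions: int = Field(9, ge=2)
    cartilage_layers: int = Field(2, ge=2)

    def to_resolution(self) -> MeshResolution:
        return MeshResolution(self.circumferential_divisions, self.radial_divisions,
                              self.vertical_divisions, self.cartilage_divisions,
                              self.cartilage_layers)


class SolverConfig(_Model):
    rtol: float = Field(1e-4, gt=0)
    n_steps: int = Field(4, ge=1)
    max_iter: int = Field(100, ge=1)
    step_max_disp: float = Field(2.0, gt=0)
    penetration_tol: float = Field(0.02, gt=0)
    friction_mu: float = Field(0.02, ge=0)
    penalty_scale: float = Field(50.0, gt=0)
    tear_face_contact: bool = True


class LoadsConfig(_Model):
    body_weight_n: float = Field(750.0, gt=0)   # "approximately full body weight"
    validation_loads_n: tuple = (375.0, 750.0)
    flexion_angles_deg: tuple = (0.0, 20.0, 30.0)
    screw_home_coupling_deg: float = 5.0
    rollback_mm_per_deg: float = 0.1


class TearConfig(_Model):
    tear_type: str
    meniscus: str
    region: str
    stability: str

    def to_spec(self) -> TearSpec:
        return TearSpec(self.tear_type, self.meniscus, self.region, self.stability)


class ExperimentConfig(_Model):
    geometry: GeometryConfig = GeometryConfig()
    materials: MaterialsConfig = MaterialsConfig()
    ligaments: LigamentsConfig = LigamentsConfig()
    mesh: MeshConfig = MeshConfig()
    solver: SolverConfig = SolverConfig()
    loads: LoadsConfig = LoadsConfig()
    tears: list[TearConfig] | None = None    # None = the full 2x3x2x2 matrix
    intact_only: bool = False
    output_dir: str = "results"
    seed: int = 0

    def tear_specs(self) -> tuple:
        from .experiment import TEAR_MATRIX
        if self.intact_only:
            return ()
        if self.tears is None:
            return TEAR_MATRIX
        return tuple(t.to_spec() for t in self.tears)

    def cartilage(self) -> IsotropicElastic:
        return IsotropicElastic(self.materials.cartilage.E, self.materials.cartilage.nu)

    def meniscus(self) -> TransverselyIsotropicElastic:
        m = self.materials.meniscus
        return TransverselyIsotropicElastic(m.E_p, m.nu_p, m.G_p, m.E_f, m.nu_f, m.G_f)

    def ligament_stiffness(self) -> dict:
        return {k: getattr(self.ligaments, k) for k in
                ("lateral_anterior", "lateral_posterior",
                 "medial_anterior", "medial_posterior")}


def _warn_unknown(model: BaseModel, path: str = "") -> None:
    extra = getattr(model, "model_extra", None) or {}
    for key in extra:
        warnings.warn(f"unknown config key {path}{key!r} ignored", stacklevel=3)
    for name in type(model).model_fields:
        value = getattr(model, name)
        if isinstance(value, BaseModel):
            _warn_unknown(value, f"{path}{name}.")


def validate_config(path_or_dict) -> ExperimentConfig:
    """Load + schema-validate a YAML config; missing keys take the protocol
    defaults, unknown keys warn (forward compatibility), invalid values
    raise :class:`ConfigError` naming the offending key path."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        text = Path(path_or_dict).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a YAML mapping")
    try:
        cfg = ExperimentConfig(**raw)
    except ValidationError as exc:
        err = exc.errors()[0]
        loc = ".".join(str(p) for p in err["loc"])
        raise ConfigError(f"config error at {loc!r}: {err['msg']}") from exc
    _warn_unknown(cfg)
    return cfg
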