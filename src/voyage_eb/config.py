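"""Run configuration: one object wiring every stage, loadable from YAML.

The ``demo`` profile is sized to complete end-to-end in minutes on one CPU
(coarse grid, one simulated year); ``full`` runs three ENSO-phase years at
finer resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import yaml

from .body_model import (DEFAULT_B1_SCF_M, DEFAULT_BASE_BODIES,
                         DEFAULT_SCF_RELATIONS, BodyType, ScfBmiRelation,
                         build_body_types)
from .calendar365 import HOURS_PER_DAY
from .energy_balance import DEFAULT_EXPOSURES, ExposureParams
from .errors import ConfigurationError
from .interpretation import DEFAULT_HEAT_FRACTION, EnergyDensityTable
from .synthetic_env import ClimateConfig, GridSpec
from .voyage_sim import SimConfig, VesselPolar

#: days of field coverage beyond the last departure of a year (50-day cap + margin)
FIELD_BUFFER_DAYS = 60

_PROFILES = {
    "demo": dict(resolution=2.5, atmos_step=3.0, years=("neutral",)),
    "full": dict(resolution=1.0, atmos_step=3.0, years=("nino", "neutral", "nina")),
}


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    profile: str = "demo"
    grid_resolution: float = 2.5
    atmos_step_hours: float = 3.0
    lat_min: float = -50.0
    lat_max: float = 28.0
    lon_min: float = 165.0
    lon_max: float = 235.0
    years: Sequence[str] = ("neutral",)
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    polar: VesselPolar = field(default_factory=VesselPolar)
    base_bodies: Mapping[str, dict] = field(default_factory=lambda: dict(DEFAULT_BASE_BODIES))
    scf_relations: Mapping[tuple, ScfBmiRelation] = field(
        default_factory=lambda: dict(DEFAULT_SCF_RELATIONS))
    b1_scf_m: float = DEFAULT_B1_SCF_M
    bmi_increment: float = 2.0
    exposures: Mapping[str, ExposureParams] = field(
        default_factory=lambda: dict(DEFAULT_EXPOSURES))
    densities: EnergyDensityTable = field(default_factory=EnergyDensityTable)
    heat_fraction: float = DEFAULT_HEAT_FRACTION
    trip_days: float = 25.0   # average trip length used by worked-example conversions

    def __post_init__(self) -> None:
        if self.profile not in _PROFILES:
            raise ConfigurationError(f"unknown profile {self.profile!r}")
        if not self.years:
            raise ConfigurationError("at least one simulated year is required")
        if not self.exposures:
            raise ConfigurationError("at least one exposure parameterization is required")

    @classmethod
    def for_profile(cls, profile: str, seed: int = 0, **overrides) -> "RunConfig":
        if profile not in _PROFILES:
            raise ConfigurationError(f"unknown profile {profile!r}")
        p = _PROFILES[profile]
        kw = dict(
            seed=seed,
            profile=profile,
            grid_resolution=p["resolution"],
            atmos_step_hours=p["atmos_step"],
            years=p["years"],
            climate=ClimateConfig(seed=seed),
            sim=SimConfig(seed=seed),
        )
        kw.update(overrides)
        return cls(**kw)

    def grid_for_year(self, year_index: int) -> GridSpec:
        start = year_index * 365 * HOURS_PER_DAY
        return GridSpec(
            lat_min=self.lat_min, lat_max=self.lat_max,
            lon_min=self.lon_min, lon_max=self.lon_max,
            resolution=self.grid_resolution,
            time_start=start,
            time_end=start + (365 + FIELD_BUFFER_DAYS) * HOURS_PER_DAY,
            atmos_step=self.atmos_step_hours,
            ocean_step=24.0,
        )

    def climate_for_year(self, year_index: int) -> ClimateConfig:
        phase = self.years[year_index]
        return replace(self.climate, enso_phase=phase,
                       seed=self.climate.seed + 7919 * year_index)

    def body_types(self) -> list[BodyType]:
        return build_body_types(base=dict(self.base_bodies),
                                relations=dict(self.scf_relations),
                                b1_scf_m=self.b1_scf_m,
                                bmi_increment=self.bmi_increment)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "profile": self.profile,
            "grid": {
                "resolution": self.grid_resolution,
                "atmos_step_hours": self.atmos_step_hours,
                "lat": [self.lat_min, self.lat_max],
                "lon": [self.lon_min, self.lon_max],
            },
            "years": list(self.years),
            "sim": self.sim.__dict__,
            "polar": {
                "angles_deg": list(self.polar.angles_deg),
                "ratios": list(self.polar.ratios),
                "max_speed": self.polar.max_speed,
                "no_go_angle": self.polar.no_go_angle,
            },
            "bodies": {
                "base": dict(self.base_bodies),
                "b1_scf_m": self.b1_scf_m,
                "bmi_increment": self.bmi_increment,
                "relations": {
                    f"{sex}.{variant}": {"slope": r.slope, "intercept": r.intercept}
                    for (sex, variant), r in self.scf_relations.items()
                },
            },
            "exposures": {
                name: {k: getattr(e, k) for k in
                       ("wfr", "ifr", "cfr", "alpha", "tc_k",
                        "clothing_s_m", "clothing_k", "scf_k")}
                for name, e in self.exposures.items()
            },
            "densities": {"fat": self.densities.fat, "muscle": self.densities.muscle,
                          "foods": dict(self.densities.foods)},
            "heat_fraction": self.heat_fraction,
            "trip_days": self.trip_days,
        }


def load_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file of overrides.

    Recognized top-level keys: ``profile``, ``seed``, ``grid`` (resolution,
    atmos_step_hours, lat, lon), ``years``, ``sim``, ``polar``, ``bodies``,
    ``exposures``, ``densities``, ``heat_fraction``, ``trip_days``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping")

    profile = raw.get("profile", "demo")
    seed = int(raw.get("seed", 0))
    overrides: dict = {}

    grid = raw.get("grid", {})
    if "resolution" in grid:
        overrides["grid_resolution"] = float(grid["resolution"])
    if "atmos_step_hours" in grid:
        overrides["atmos_step_hours"] = float(grid["atmos_step_hours"])
    if "lat" in grid:
        overrides["lat_min"], overrides["lat_max"] = map(float, grid["lat"])
    if "lon" in grid:
        overrides["lon_min"], overrides["lon_max"] = map(float, grid["lon"])
    if "years" in raw:
        overrides["years"] = tuple(raw["years"])
    if "climate" in raw:
        overrides["climate"] = ClimateConfig(seed=seed, **raw["climate"])
    if "sim" in raw:
        overrides["sim"] = SimConfig(seed=seed, **raw["sim"])
    if "polar" in raw:
        p = raw["polar"]
        overrides["polar"] = VesselPolar(
            angles_deg=tuple(p.get("angles_deg", VesselPolar().angles_deg)),
            ratios=tuple(p.get("ratios", VesselPolar().ratios)),
            max_speed=float(p.get("max_speed", VesselPolar().max_speed)),
            no_go_angle=float(p.get("no_go_angle", VesselPolar().no_go_angle)),
        )
    if "bodies" in raw:
        b = raw["bodies"]
        if "base" in b:
            overrides["base_bodies"] = {
                sex: {"h_cm": float(v["h_cm"]), "bm_kg": float(v["bm_kg"])}
                for sex, v in b["base"].items()
            }
        if "b1_scf_m" in b:
            overrides["b1_scf_m"] = float(b["b1_scf_m"])
        if "bmi_increment" in b:
            overrides["bmi_increment"] = float(b["bmi_increment"])
        if "relations" in b:
            rels = dict(DEFAULT_SCF_RELATIONS)
            for key, v in b["relations"].items():
                sex, variant = key.split(".")
                rels[(sex, variant)] = ScfBmiRelation(
                    sex, variant, slope=float(v["slope"]), intercept=float(v["intercept"]))
            overrides["scf_relations"] = rels
    if "exposures" in raw:
        overrides["exposures"] = {
            name: ExposureParams(label=name, **params)
            for name, params in raw["exposures"].items()
        }
    if "densities" in raw:
        d = raw["densities"]
        overrides["densities"] = EnergyDensityTable(
            fat=float(d.get("fat", 9.0)),
            muscle=float(d.get("muscle", 4.0)),
            foods=d.get("foods", dict(EnergyDensityTable().foods)),
        )
    if "heat_fraction" in raw:
        overrides["heat_fraction"] = float(raw["heat_fraction"])
    if "trip_days" in raw:
        overrides["trip_days"] = float(raw["trip_days"])

    return RunConfig.for_profile(profile, seed=seed, **overrides)
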