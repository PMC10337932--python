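"""Resting energy balance: EB = BMR - L.

Net heat loss L = Ld + Lw - Sa combines losses over the dry and wet body
fractions with shortwave absorption. The shared dry-loss kernel is
BSA * (Tc - Ta) / (R + 1/C): thermal resistance R of insulating layers
(subcutaneous fat, clothing) in series with a wind-dependent convective
transfer coefficient C. Loss over the wet body fraction is increased by 50%.

All functions here expect wind speed already adjusted to person height
(1.5 m); use :func:`adjust_wind` on 10-m winds first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .body_model import BodyType
from .errors import ConfigurationError
from .synthetic_env import EnvSample

KELVIN_OFFSET = 273.15
WET_LOSS_FACTOR = 1.5

# bark-cloth clothing layer
DEFAULT_CLOTHING_S_M = 0.0012
DEFAULT_CLOTHING_K = 0.0357   # W/mK
DEFAULT_SCF_K = 0.2           # W/mK


@dataclass(frozen=True)
class InsulationLayer:
    s_m: float       # thickness
    k: float         # conductivity W/mK
    cfr: float = 1.0  # covered body fraction

    def __post_init__(self) -> None:
        if self.s_m <= 0 or self.k <= 0:
            raise ConfigurationError("layer thickness and conductivity must be positive")
        if not 0.0 <= self.cfr <= 1.0:
            raise ConfigurationError("covered fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ExposureParams:
    """Exposure level: wet/illuminated/clothed fractions, skin albedo, core temp.

    The shipped ``Hhl``/``Lhl`` presets put every parameter at its
    loss-maximizing (respectively minimizing) end of the evaluated ranges.
    """

    wfr: float
    ifr: float
    cfr: float
    alpha: float
    tc_k: float = 310.15
    clothing_s_m: float = DEFAULT_CLOTHING_S_M
    clothing_k: float = DEFAULT_CLOTHING_K
    scf_k: float = DEFAULT_SCF_K
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("wfr", "ifr", "cfr", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.tc_k <= KELVIN_OFFSET:
            raise ConfigurationError("core temperature must exceed 273.15 K")
        if min(self.clothing_s_m, self.clothing_k, self.scf_k) <= 0:
            raise ConfigurationError("thicknesses and conductivities must be positive")

    def layers(self, scf_m: float) -> list[InsulationLayer]:
        return [
            InsulationLayer(s_m=scf_m, k=self.scf_k, cfr=1.0),
            InsulationLayer(s_m=self.clothing_s_m, k=self.clothing_k, cfr=self.cfr),
        ]


HHL = ExposureParams(wfr=0.20, ifr=0.3, cfr=0.25, alpha=0.30, label="Hhl")
LHL = ExposureParams(wfr=0.10, ifr=0.4, cfr=0.50, alpha=0.25, label="Lhl")
DEFAULT_EXPOSURES = {"Hhl": HHL, "Lhl": LHL}


@dataclass(frozen=True)
class EBResult:
    bmr: float
    ld: float
    lw: float
    sa: float
    l: float
    eb: float


def adjust_wind(ws_z, z: float = 10.0, z1: float = 1.5, p: float = 0.11):
    """Power-law height adjustment of wind speed from ``z`` to ``z1`` meters."""
    if z <= 0 or z1 <= 0:
        raise ConfigurationError("elevations must be positive")
    return np.asarray(ws_z) * (z1 / z) ** p


def convection(ws):
    """Convective transfer coefficient C = 5 + 3.95 * WS^0.6 (WS at 1.5 m)."""
    ws = np.asarray(ws, dtype=float)
    if np.any(ws < 0):
        raise ConfigurationError("wind speed must be non-negative")
    return 5.0 + 3.95 * ws**0.6


def thermal_resistance(layers: Iterable[InsulationLayer]) -> float:
    """Series resistance of insulating layers: sum of (s/k) * covered fraction."""
    layers = list(layers)
    if not layers:
        raise ConfigurationError("at least one insulating layer is required")
    return float(sum((lay.s_m / lay.k) * lay.cfr for lay in layers))


def solar_absorption(bsa_m2, ifr, s_wm2, alpha):
    """Absorbed shortwave power in W: BSA * ifr * S * (1 - alpha)."""
    return np.asarray(bsa_m2) * ifr * np.asarray(s_wm2) * (1.0 - alpha)


def eb_components(body: BodyType, exp: ExposureParams, ta_c, ws, solar_wm2):
    """Vectorized EB decomposition over arrays of (Ta degC, WS at 1.5 m, solar).

    Returns a dict of arrays: bmr, ld, lw, sa, l, eb. Negative (Tc - Ta) is
    allowed and propagates sign (net radiative/convective gain in hot air).
    """
    ta_k = np.asarray(ta_c, dtype=float) + KELVIN_OFFSET
    r = thermal_resistance(exp.layers(body.scf_m))
    c = convection(ws)
    base = body.bsa * (exp.tc_k - ta_k) / (r + 1.0 / c)
    ld = (1.0 - exp.wfr) * base
    lw = WET_LOSS_FACTOR * exp.wfr * base
    sa = solar_absorption(body.bsa, exp.ifr, solar_wm2, exp.alpha)
    l = ld + lw - sa
    b = body.bmr_w
    return {"bmr": np.broadcast_to(b, l.shape).copy() if hasattr(l, "shape") else b,
            "ld": ld, "lw": lw, "sa": sa, "l": l, "eb": b - l}


def heat_loss(body: BodyType, exp: ExposureParams, env: EnvSample) -> EBResult:
    """Loss decomposition for one sample; env wind is taken as already at 1.5 m."""
    comp = eb_components(body, exp, env.ta_c, env.ws10, env.solar_wm2)
    return EBResult(bmr=float(comp["bmr"]), ld=float(comp["ld"]), lw=float(comp["lw"]),
                    sa=float(comp["sa"]), l=float(comp["l"]), eb=float(comp["eb"]))


def eb(body: BodyType, exp: ExposureParams, env: EnvSample) -> EBResult:
    """Resting energy balance EB = BMR - L for one environmental sample."""
    return heat_loss(body, exp, env)
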