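"""Anthropometry: body types, BMI, body surface area, subcutaneous fat, BMR.

BMR uses the sex-specific linear "Oxford" equations in body mass, converted
from kcal/day to watts; BSA uses a height/mass power law. Subcutaneous-fat
thickness (SCF) for derived body types comes from configurable linear
BMI->SCF relations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ConfigurationError, ModelRangeError

#: kcal/day -> W: 4184 J/kcal / 86400 s/day, rounded to 4 significant figures
KCAL_PER_DAY_TO_W = 0.04843

_BMR_COEFS = {"female": (13.1, 558.0), "male": (16.0, 545.0)}


def bmi(bm_kg: float, h_cm: float) -> float:
    """Body mass index, kg/m^2."""
    if bm_kg <= 0 or h_cm <= 0:
        raise ConfigurationError("body mass and height must be positive")
    return bm_kg / (h_cm / 100.0) ** 2


def bsa(h_cm: float, bm_kg: float) -> float:
    """Body surface area in m^2: 0.024265 * H^0.3964 * BM^0.5378 (H in cm)."""
    if bm_kg <= 0 or h_cm <= 0:
        raise ConfigurationError("body mass and height must be positive")
    return 0.024265 * h_cm**0.3964 * bm_kg**0.5378


def bmr(sex: str, bm_kg: float) -> float:
    """Basal metabolic rate in W from the sex-specific Oxford linear equations."""
    if sex not in _BMR_COEFS:
        raise ConfigurationError(f"unknown sex {sex!r}")
    if bm_kg <= 0:
        raise ConfigurationError("body mass must be positive")
    slope, intercept = _BMR_COEFS[sex]
    return KCAL_PER_DAY_TO_W * (slope * bm_kg + intercept)


@dataclass(frozen=True)
class ScfBmiRelation:
    """Linear BMI -> subcutaneous-fat-thickness relation (SCF in mm)."""

    sex: str
    variant: str          # "standard" (B2) or "robustness" (B3)
    slope: float          # mm per (kg/m^2)
    intercept: float      # mm

    def scf_m(self, bmi_value: float) -> float:
        """Predicted SCF in meters; rejects non-positive predictions."""
        scf_mm = self.slope * bmi_value + self.intercept
        if scf_mm <= 0:
            raise ModelRangeError(
                f"SCF-BMI relation predicts non-positive SCF ({scf_mm:.2f} mm) "
                f"at BMI {bmi_value:.2f}"
            )
        return scf_mm / 1000.0


def scf_from_bmi(rel: ScfBmiRelation, bmi_value: float) -> float:
    return rel.scf_m(bmi_value)


# Default relations are documented stand-ins satisfying the qualitative
# constraints of the source analysis: female standard slope exceeds male
# standard slope; the robustness variant flattens the female relation below
# every standard slope and steepens the male relation above them.
DEFAULT_SCF_RELATIONS = {
    ("female", "standard"): ScfBmiRelation("female", "standard", slope=0.85, intercept=-10.0),
    ("male", "standard"): ScfBmiRelation("male", "standard", slope=0.55, intercept=-7.0),
    ("female", "robustness"): ScfBmiRelation("female", "robustness", slope=0.20, intercept=0.0),
    ("male", "robustness"): ScfBmiRelation("male", "robustness", slope=0.90, intercept=-12.0),
}


@dataclass(frozen=True)
class BodyType:
    """One evaluated body: sex, height (cm), mass (kg), SCF (m) and a label."""

    sex: str
    h_cm: float
    bm_kg: float
    scf_m: float
    label: str = "B1"

    def __post_init__(self) -> None:
        if self.h_cm <= 0 or self.bm_kg <= 0 or self.scf_m <= 0:
            raise ConfigurationError("height, mass and SCF must be positive")

    @property
    def bmi(self) -> float:
        return bmi(self.bm_kg, self.h_cm)

    @property
    def bsa(self) -> float:
        return bsa(self.h_cm, self.bm_kg)

    @property
    def bmr_w(self) -> float:
        return bmr(self.sex, self.bm_kg)

    @property
    def key(self) -> str:
        return f"{self.label}_{'F' if self.sex == 'female' else 'M'}"


def derive_body(base: BodyType, bmi_increment: float, rel: ScfBmiRelation,
                label: str) -> BodyType:
    """Same height/sex as ``base`` with BMI raised by ``bmi_increment``.

    Mass follows from the new BMI; SCF is re-estimated from the BMI relation.
    """
    new_bmi = base.bmi + bmi_increment
    new_bm = new_bmi * (base.h_cm / 100.0) ** 2
    return replace(base, bm_kg=new_bm, scf_m=rel.scf_m(new_bmi), label=label)


# Representative default base anthropometry (config-overridable stand-ins).
DEFAULT_BASE_BODIES = {
    "female": dict(h_cm=166.0, bm_kg=70.0),
    "male": dict(h_cm=175.0, bm_kg=80.0),
}

DEFAULT_B1_SCF_M = 0.005  # evaluated range 0.005-0.0075 m


def build_body_types(base: dict | None = None,
                     relations: dict | None = None,
                     b1_scf_m: float = DEFAULT_B1_SCF_M,
                     bmi_increment: float = 2.0) -> list[BodyType]:
    """The six evaluated bodies: B1 from config, B2/B3 via +2 BMI and SCF relations."""
    base = base or DEFAULT_BASE_BODIES
    relations = relations or DEFAULT_SCF_RELATIONS
    bodies: list[BodyType] = []
    for sex in ("female", "male"):
        b1 = BodyType(sex=sex, label="B1", scf_m=b1_scf_m, **base[sex])
        b2 = derive_body(b1, bmi_increment, relations[(sex, "standard")], "B2")
        b3 = derive_body(b1, bmi_increment, relations[(sex, "robustness")], "B3")
        bodies.extend([b1, b2, b3])
    return bodies
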