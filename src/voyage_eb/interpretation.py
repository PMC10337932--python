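"""Worked-example conversions of a daily EB deficit into tangible equivalents.

These are linear "translations" only: fat or muscle mass consumed, extra food
required, or physical activity whose heat by-product would cover the deficit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import ConfigurationError

#: fraction of physical-activity calories released as body heat (~12 degC air)
DEFAULT_HEAT_FRACTION = 0.116

DEFAULT_FOOD_DENSITIES: Mapping[str, float] = {
    "fish": 1.00,
    "cooked_taro": 1.42,
    "boiled_breadfruit_seeds": 1.68,
}


@dataclass(frozen=True)
class EnergyDensityTable:
    """Energy densities in kcal/g (USDA-consistent defaults, overridable)."""

    fat: float = 9.0
    muscle: float = 4.0
    foods: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FOOD_DENSITIES))

    def __post_init__(self) -> None:
        if self.fat <= 0 or self.muscle <= 0 or any(v <= 0 for v in self.foods.values()):
            raise ConfigurationError("energy densities must be positive")


def fat_equivalent(deficit_kcal_day: float, days: float,
                   table: EnergyDensityTable = EnergyDensityTable()) -> tuple[float, float]:
    """(g fat per day to 1 d.p., kg fat over the whole trip to 2 d.p.)."""
    if deficit_kcal_day < 0:
        raise ConfigurationError("deficit must be non-negative")
    g_day = round(deficit_kcal_day / table.fat, 1)
    kg_total = round(g_day * days / 1000.0, 2)
    return g_day, kg_total


def muscle_equivalent(deficit_kcal_day: float, days: float,
                      table: EnergyDensityTable = EnergyDensityTable()) -> float:
    """kg of muscle mass consumed over the whole trip, to 2 d.p."""
    if deficit_kcal_day < 0:
        raise ConfigurationError("deficit must be non-negative")
    return round(deficit_kcal_day * days / table.muscle / 1000.0, 2)


def food_equivalent(deficit_kcal_day: float, food: str,
                    table: EnergyDensityTable = EnergyDensityTable()) -> int:
    """Extra grams per day of a named food, rounded to the nearest gram."""
    if food not in table.foods:
        raise KeyError(f"unknown food {food!r}; known: {sorted(table.foods)}")
    return round(deficit_kcal_day / table.foods[food])


def activity_equivalent(deficit_kcal_day: float,
                        heat_fraction: float = DEFAULT_HEAT_FRACTION) -> float:
    """kcal/day of physical activity whose heat by-product covers the deficit."""
    if not 0.0 < heat_fraction <= 1.0:
        raise ConfigurationError("heat_fraction must lie in (0, 1]")
    return deficit_kcal_day / heat_fraction


def report(deficit_kcal_day: float, days: float,
           table: EnergyDensityTable = EnergyDensityTable(),
           heat_fraction: float = DEFAULT_HEAT_FRACTION) -> dict:
    """All conversions for a deficit, as a JSON-serializable dict."""
    g_day, kg_total = fat_equivalent(deficit_kcal_day, days, table)
    return {
        "deficit_kcal_per_day": deficit_kcal_day,
        "days": days,
        "fat_g_per_day": g_day,
        "fat_kg_total": kg_total,
        "muscle_kg_total": muscle_equivalent(deficit_kcal_day, days, table),
        "food_g_per_day": {
            name: food_equivalent(deficit_kcal_day, name, table) for name in table.foods
        },
        "activity_kcal_per_day": activity_equivalent(deficit_kcal_day, heat_fraction),
    }
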