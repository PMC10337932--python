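"""Idealized 365-day calendar helpers.

All simulation time is measured in hours since 00:00 on day 0 of year 0 of an
idealized no-leap calendar. Month lengths follow the Gregorian pattern without
leap days, which keeps meteorological season boundaries in their usual places.
"""

from __future__ import annotations

import numpy as np

HOURS_PER_DAY = 24.0
DAYS_PER_YEAR = 365
HOURS_PER_YEAR = HOURS_PER_DAY * DAYS_PER_YEAR

_MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MONTH_STARTS = np.concatenate([[0], np.cumsum(_MONTH_LENGTHS)])  # day-of-year

#: meteorological seasons, Southern-Hemisphere naming convention
SEASON_OF_MONTH = {
    12: "DJF", 1: "DJF", 2: "DJF",
    3: "MAM", 4: "MAM", 5: "MAM",
    6: "JJA", 7: "JJA", 8: "JJA",
    9: "SON", 10: "SON", 11: "SON",
}

SEASONS = ("DJF", "MAM", "JJA", "SON")


def day_of_year(t_hours: float) -> float:
    """Fractional day-of-year in [0, 365) for an hour offset."""
    return (np.asarray(t_hours) / HOURS_PER_DAY) % DAYS_PER_YEAR


def month_of_day(doy: int) -> int:
    """1-based month containing integer day-of-year ``doy`` (0-based)."""
    d = int(doy) % DAYS_PER_YEAR
    return int(np.searchsorted(_MONTH_STARTS, d, side="right"))


def season_of_day(doy: int) -> str:
    """Meteorological season label for an integer day-of-year."""
    return SEASON_OF_MONTH[month_of_day(doy)]


def local_solar_hour(t_hours, lon_deg):
    """Local solar time in hours, from UTC-like model time plus longitude offset."""
    return (np.asarray(t_hours) + np.asarray(lon_deg) / 15.0) % 24.0
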