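"""Departure-day aggregation of trips into energy-balance series and contrasts.

Environmental forcing for a departure day is the hourly mean over the vessels
of that departure/destination; EB series are integrated to aggregate EB (aEB,
kcal) and summarized as per-day means with t-based confidence intervals,
seasonal means, and Welch contrasts between destinations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calendar365 import HOURS_PER_DAY, season_of_day
from .body_model import BodyType
from .energy_balance import ExposureParams, adjust_wind, eb_components
from .errors import ConfigurationError
from .synthetic_env import EnvFieldSet
from .voyage_sim import Trip

JOULES_PER_KCAL = 4184.0
SECONDS_PER_HOUR = 3600.0
#: kcal per day delivered by a constant 1 W
W_TO_KCAL_PER_DAY = 86400.0 / JOULES_PER_KCAL


@dataclass
class DepartureEnvSeries:
    """Hourly environment averaged across the vessels of one departure/destination."""

    departure_day: int
    destination: str
    hours: np.ndarray        # hours since departure
    ta_c: np.ndarray
    ws15: np.ndarray         # wind speed adjusted to 1.5 m
    solar_wm2: np.ndarray
    n_vessels: int
    truncation_time: float   # duration (h) of the shortest member trip


def trip_hourly_env(trip: Trip, fieldset: EnvFieldSet,
                    step_hours: float = 1.0) -> dict[str, np.ndarray]:
    """Hourly along-track environment for one trip.

    Positions are interpolated linearly between trajectory points, then the
    fields are sampled at each hour.
    """
    if len(trip.points) < 2:
        p = trip.points[0]
        return {"hours": np.array([0.0]),
                "ta_c": np.array([p.env.ta_c]),
                "ws10": np.array([p.env.ws10]),
                "solar_wm2": np.array([p.env.solar_wm2])}
    ts = np.array([p.t for p in trip.points])
    lats = np.array([p.lat for p in trip.points])
    lons = np.array([p.lon for p in trip.points])
    # unwrap longitudes so linear interpolation is dateline-safe
    lons_unwrapped = np.degrees(np.unwrap(np.radians(lons)))
    t_hourly = np.arange(ts[0], ts[-1] + 1e-9, step_hours)
    lat_h = np.interp(t_hourly, ts, lats)
    lon_h = np.interp(t_hourly, ts, lons_unwrapped) % 360.0
    tr = fieldset.sample_track(lat_h, lon_h, t_hourly)
    ws10 = np.hypot(tr["wind_u"], tr["wind_v"])
    return {"hours": t_hourly - ts[0], "ta_c": tr["ta_c"], "ws10": ws10,
            "solar_wm2": tr["solar_wm2"]}


def departure_env(trips: Sequence[Trip], fieldset: EnvFieldSet,
                  truncate_at_shortest: bool = False) -> DepartureEnvSeries:
    """Hourly vessel-mean environment for one departure day and destination.

    By default the mean at each hour runs over the vessels still en route; with
    ``truncate_at_shortest`` the series stops at the earliest member endpoint.
    """
    trips = list(trips)
    if not trips:
        raise ConfigurationError("departure_env requires at least one trip")
    day0, dest0 = trips[0].departure_day, trips[0].destination
    if any(t.departure_day != day0 or t.destination != dest0 for t in trips):
        raise ConfigurationError("trips must share departure day and destination")

    members = [trip_hourly_env(t, fieldset) for t in trips]
    lengths = np.array([m["hours"].size for m in members])
    truncation = float(min(m["hours"][-1] for m in members))
    n = int(lengths.min()) if truncate_at_shortest else int(lengths.max())

    def masked_mean(key: str) -> np.ndarray:
        stacked = np.full((len(members), n), np.nan)
        for i, m in enumerate(members):
            k = min(m[key].size, n)
            stacked[i, :k] = m[key][:k]
        return np.nanmean(stacked, axis=0)

    ta = masked_mean("ta_c")
    ws10 = masked_mean("ws10")
    solar = masked_mean("solar_wm2")
    return DepartureEnvSeries(
        departure_day=day0,
        destination=dest0,
        hours=np.arange(n, dtype=float),
        ta_c=ta,
        ws15=np.asarray(adjust_wind(ws10), dtype=float),
        solar_wm2=solar,
        n_vessels=len(trips),
        truncation_time=truncation,
    )


@dataclass
class EBSeries:
    """Hourly EB (W) for one departure-day forcing under one body x exposure."""

    departure_day: int
    destination: str
    body_label: str
    sex: str
    exposure_label: str
    eb_w: np.ndarray

    @property
    def duration_days(self) -> float:
        return self.eb_w.size / HOURS_PER_DAY

    @property
    def aeb_kcal(self) -> float:
        """Aggregate EB: hourly rates summed over the voyage, in kcal."""
        return float(self.eb_w.sum() * SECONDS_PER_HOUR / JOULES_PER_KCAL)

    @property
    def mean_daily_eb(self) -> float:
        """kcal per day averaged over the voyage."""
        return self.aeb_kcal / self.duration_days


def eb_series(env: DepartureEnvSeries, body: BodyType,
              exposure: ExposureParams) -> EBSeries:
    """Apply the EB model hour by hour to a departure-day environment series."""
    comp = eb_components(body, exposure, env.ta_c, env.ws15, env.solar_wm2)
    return EBSeries(
        departure_day=env.departure_day,
        destination=env.destination,
        body_label=body.label,
        sex=body.sex,
        exposure_label=exposure.label,
        eb_w=np.asarray(comp["eb"], dtype=float),
    )


@dataclass(frozen=True)
class GroupStats:
    mean: float
    ci_half_width: float
    n: int


def mean_ci(values: Iterable[float], confidence: float = 0.95) -> GroupStats:
    """Mean with Student-t confidence interval (half-width 0 for n == 1)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ConfigurationError("cannot summarize an empty group")
    m = float(v.mean())
    if v.size < 2:
        return GroupStats(mean=m, ci_half_width=0.0, n=1)
    sem = v.std(ddof=1) / np.sqrt(v.size)
    t = stats.t.ppf(0.5 + confidence / 2.0, v.size - 1)
    return GroupStats(mean=m, ci_half_width=float(t * sem), n=int(v.size))


def departure_day_stats(series: Iterable[EBSeries]) -> pd.DataFrame:
    """Per (departure day-of-year, destination, body, exposure) mean daily EB with 95% CI.

    Pools whatever replicates exist per key (years of the same departure
    day-of-year, multiple configurations when requested upstream).
    """
    rows = [
        {
            "departure_doy": s.departure_day % 365,
            "destination": s.destination,
            "body": s.body_label,
            "sex": s.sex,
            "exposure": s.exposure_label,
            "mean_daily_eb": s.mean_daily_eb,
            "aeb_kcal": s.aeb_kcal,
            "duration_days": s.duration_days,
        }
        for s in series
    ]
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby(["departure_doy", "destination", "body", "sex", "exposure"])
        .agg(values=("mean_daily_eb", list), aeb_kcal=("aeb_kcal", "mean"),
             duration_days=("duration_days", "mean"))
        .reset_index()
    )
    st = grouped["values"].map(mean_ci)
    grouped["mean_daily_eb"] = [s.mean for s in st]
    grouped["ci_half_width"] = [s.ci_half_width for s in st]
    grouped["n"] = [s.n for s in st]
    grouped["season"] = grouped["departure_doy"].map(season_of_day)
    return grouped.drop(columns=["values"])


def seasonal_means(day_stats: pd.DataFrame,
                   value: str = "mean_daily_eb") -> pd.DataFrame:
    """Mean of a per-day statistic over departure days within each season."""
    return (
        day_stats.groupby(["destination", "season"])[value]
        .mean()
        .reset_index()
    )


@dataclass(frozen=True)
class ContrastResult:
    departure_doy: int
    mean_difference: float   # NZ - HW, kcal/day
    ci_half_width: float
    significant: bool
    season: str


def welch_contrast(a: Sequence[float], b: Sequence[float],
                   confidence: float = 0.95) -> tuple[float, float]:
    """Welch difference of means (a - b) with CI half-width.

    Zero-variance groups degenerate to an exact difference (half-width 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    diff = float(a.mean() - b.mean())
    va = a.var(ddof=1) if a.size > 1 else 0.0
    vb = b.var(ddof=1) if b.size > 1 else 0.0
    se2 = va / a.size + vb / b.size
    if se2 == 0.0:
        return diff, 0.0
    nu = se2**2 / (
        (va / a.size) ** 2 / max(a.size - 1, 1)
        + (vb / b.size) ** 2 / max(b.size - 1, 1)
    )
    t = stats.t.ppf(0.5 + confidence / 2.0, nu)
    return diff, float(t * np.sqrt(se2))


def destination_contrast(nz_values_by_day: dict[int, Sequence[float]],
                         hw_values_by_day: dict[int, Sequence[float]]) -> list[ContrastResult]:
    """Per-departure-day NZ - HW mean daily EB difference with Welch 95% CI."""
    out = []
    for doy in sorted(set(nz_values_by_day) & set(hw_values_by_day)):
        diff, hw_ci = welch_contrast(nz_values_by_day[doy], hw_values_by_day[doy])
        out.append(ContrastResult(
            departure_doy=doy,
            mean_difference=diff,
            ci_half_width=hw_ci,
            significant=bool(abs(diff) > hw_ci),
            season=season_of_day(doy),
        ))
    return out


def aeb_ratio(nz_aeb: Sequence[float], hw_aeb: Sequence[float]) -> float:
    """|mean aEB(NZ)| / |mean aEB(HW)| for one matched grouping."""
    nz = float(np.mean(np.asarray(nz_aeb, dtype=float)))
    hw = float(np.mean(np.asarray(hw_aeb, dtype=float)))
    if nz == 0.0 or hw == 0.0:
        raise ConfigurationError("aEB aggregates must be non-zero for a ratio")
    return abs(nz) / abs(hw)


def aeb_ratio_table(day_stats: pd.DataFrame) -> pd.DataFrame:
    """aEB ratio per (body, exposure) grouping plus the min-max across groupings."""
    rows = []
    for (body, sex, exposure), g in day_stats.groupby(["body", "sex", "exposure"]):
        nz = g[g.destination == "new_zealand"]["aeb_kcal"]
        hw = g[g.destination == "hawaii"]["aeb_kcal"]
        if len(nz) and len(hw) and nz.mean() != 0 and hw.mean() != 0:
            rows.append({"body": body, "sex": sex, "exposure": exposure,
                         "ratio": abs(nz.mean()) / abs(hw.mean())})
    return pd.DataFrame(rows)
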