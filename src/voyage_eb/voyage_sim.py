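"""Vessel advection: current drift plus polar-based sailing on a departure schedule.

Vessel displacement is the sum of the sampled surface-current velocity and a
sailing velocity derived from a speed-polar table; positions advance along
great circles on a spherical Earth every 6 hours until arrival, domain exit,
or a 50-day cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calendar365 import DAYS_PER_YEAR, HOURS_PER_DAY
from .errors import ConfigurationError
from .synthetic_env import EnvFieldSet, EnvSample

EARTH_RADIUS_M = 6_371_000.0

#: departure point (southern Tahiti) and destination target points, (lat, lon 0-360)
TAHITI = (-17.53, 210.42)
TARGETS = {
    "hawaii": (19.0, 204.4),        # southern coast of Hawai'i
    "new_zealand": (-37.7, 178.6),  # NE coast of Te Ika-a-Maui
}

DESTINATIONS = ("hawaii", "new_zealand")


@dataclass(frozen=True)
class VesselPolar:
    """Boat-speed fraction of wind speed as a function of true-wind angle off heading.

    The default table is a documented parametric stand-in for an unavailable
    replica-canoe polar: no way upwind of 45 degrees, rising to 0.35 at beam
    reach, 0.45 at broad reach, 0.40 dead downwind, hull-speed cap 5 m/s.
    """

    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0, 180.0)
    ratios: tuple[float, ...] = (0.0, 0.0, 0.35, 0.45, 0.40)
    max_speed: float = 5.0
    no_go_angle: float = 45.0

    def __post_init__(self) -> None:
        if len(self.angles_deg) != len(self.ratios):
            raise ConfigurationError("polar table angles and ratios differ in length")
        if any(r < 0 for r in self.ratios):
            raise ConfigurationError("polar ratios must be non-negative")
        if self.angles_deg[0] != 0.0 or self.angles_deg[-1] != 180.0:
            raise ConfigurationError("polar table must cover 0-180 degrees")

    def ratio(self, twa_deg) -> np.ndarray:
        """Interpolated speed ratio at true-wind angle(s) folded to [0, 180]."""
        twa = np.abs(np.asarray(twa_deg, dtype=float))
        twa = np.where(twa > 180.0, 360.0 - twa, twa)
        r = np.interp(twa, self.angles_deg, self.ratios)
        return np.where(twa < self.no_go_angle, 0.0, r)


@dataclass(frozen=True)
class SimConfig:
    step_hours: float = 6.0
    max_duration_days: float = 50.0
    arrival_radius_km: float = 50.0
    departure_interval_days: int = 5
    vessels_per_departure: int = 8
    heading_fan_deg: float = 60.0
    heading_step_deg: float = 5.0
    heading_noise_deg: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if HOURS_PER_DAY % self.step_hours != 0:
            raise ConfigurationError("step_hours must divide 24")
        if self.max_duration_days <= 0 or self.arrival_radius_km <= 0:
            raise ConfigurationError("max_duration and arrival_radius must be positive")


@dataclass(frozen=True)
class TrajectoryPoint:
    t: float                 # hours since epoch
    lat: float
    lon: float
    env: EnvSample
    sail_vec: tuple[float, float]
    drift_vec: tuple[float, float]


@dataclass
class Trip:
    departure_day: int       # day index since epoch (spans years)
    destination: str
    vessel_index: int
    points: list[TrajectoryPoint] = field(default_factory=list)
    outcome: str = "timed_out"

    @property
    def duration_days(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return (self.points[-1].t - self.points[0].t) / HOURS_PER_DAY

    @property
    def departure_doy(self) -> int:
        return self.departure_day % DAYS_PER_YEAR


# -- spherical geometry -------------------------------------------------------

def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (haversine, R = 6371 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2.0 * EARTH_RADIUS_M / 1000.0 * math.asin(min(1.0, math.sqrt(a)))


def initial_bearing(lat1, lon1, lat2, lon2) -> float:
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dlmb = math.radians(lon2 - lon1)
    y = math.sin(dlmb) * math.cos(p2)
    x = math.cos(p1) * math.sin(p2) - math.sin(p1) * math.cos(p2) * math.cos(dlmb)
    return math.degrees(math.atan2(y, x)) % 360.0


def step_position(lat: float, lon: float, velocity_uv: tuple[float, float],
                  dt_hours: float) -> tuple[float, float]:
    """Advance a position along the great circle set by an (east, north) velocity.

    Longitude is wrapped to [0, 360).
    """
    u, v = velocity_uv
    speed = math.hypot(u, v)
    if speed == 0.0:
        return lat, lon
    azimuth = math.atan2(u, v)
    delta = speed * dt_hours * 3600.0 / EARTH_RADIUS_M
    p1 = math.radians(lat)
    l1 = math.radians(lon)
    sin_p2 = math.sin(p1) * math.cos(delta) + math.cos(p1) * math.sin(delta) * math.cos(azimuth)
    p2 = math.asin(max(-1.0, min(1.0, sin_p2)))
    l2 = l1 + math.atan2(
        math.sin(azimuth) * math.sin(delta) * math.cos(p1),
        math.cos(delta) - math.sin(p1) * sin_p2,
    )
    return math.degrees(p2), math.degrees(l2) % 360.0


# -- sailing ------------------------------------------------------------------

def wind_from_bearing(wind_u: float, wind_v: float) -> float:
    """Compass bearing the wind blows FROM, degrees in [0, 360)."""
    return math.degrees(math.atan2(-wind_u, -wind_v)) % 360.0


def true_wind_angle(wind_u: float, wind_v: float, heading_deg) -> np.ndarray:
    """Angle between heading and wind origin, folded to [0, 180]."""
    wfb = wind_from_bearing(wind_u, wind_v)
    d = np.abs((np.asarray(heading_deg, dtype=float) - wfb + 180.0) % 360.0 - 180.0)
    return d


def sailing_velocity(polar: VesselPolar, wind: tuple[float, float],
                     heading_deg: float) -> tuple[float, float]:
    """Sailing velocity (east, north) m/s along ``heading_deg`` for a given wind."""
    wu, wv = wind
    ws = math.hypot(wu, wv)
    if ws == 0.0:
        return (0.0, 0.0)
    twa = float(true_wind_angle(wu, wv, heading_deg))
    speed = min(ws * float(polar.ratio(twa)), polar.max_speed)
    h = math.radians(heading_deg)
    return (speed * math.sin(h), speed * math.cos(h))


def choose_heading(pos: tuple[float, float], target: tuple[float, float],
                   polar: VesselPolar, wind: tuple[float, float],
                   fan_deg: float = 60.0, step_deg: float = 5.0) -> float:
    """Heading maximizing velocity made good toward the great-circle bearing.

    Candidates span ``bearing +/- fan_deg`` at ``step_deg`` increments; ties go
    to the candidate closest to the direct bearing, then to the smaller
    compass angle.
    """
    bearing = initial_bearing(pos[0], pos[1], target[0], target[1])
    offsets = np.arange(-fan_deg, fan_deg + 0.5 * step_deg, step_deg)
    headings = (bearing + offsets) % 360.0
    wu, wv = wind
    ws = math.hypot(wu, wv)
    if ws == 0.0:
        return bearing
    twa = true_wind_angle(wu, wv, headings)
    speeds = np.minimum(ws * polar.ratio(twa), polar.max_speed)
    vmg = speeds * np.cos(np.deg2rad(offsets))
    best = vmg.max()
    tied = np.flatnonzero(vmg >= best - 1e-12)
    # closest to direct bearing, then smaller compass angle
    order = sorted(tied, key=lambda i: (abs(offsets[i]), headings[i]))
    return float(headings[order[0]])


# -- trip integration ---------------------------------------------------------

def _vessel_rng(seed: int, departure_day: int, destination: str, vessel: int):
    dest_code = DESTINATIONS.index(destination)
    return np.random.default_rng((seed, departure_day, dest_code, vessel))


def simulate_trip(departure_day: int, destination: str, fieldset: EnvFieldSet,
                  polar: VesselPolar, config: SimConfig,
                  vessel_index: int = 0,
                  start: tuple[float, float] = TAHITI,
                  target: Optional[tuple[float, float]] = None) -> Trip:
    """Integrate one vessel from ``start`` toward the destination target.

    Vessels with the same departure and destination are differentiated by
    seeded heading noise (standard deviation ``heading_noise_deg``).
    """
    if target is None:
        target = TARGETS[destination]
    lat, lon = start
    if not fieldset.contains(lat, lon):
        raise ConfigurationError("departure point lies outside the field domain")
    t = departure_day * HOURS_PER_DAY
    if t < fieldset.t_atmos[0] or t > fieldset.t_atmos[-1]:
        raise ConfigurationError("departure time lies outside the field time range")
    rng = _vessel_rng(config.seed, departure_day, destination, vessel_index)
    trip = Trip(departure_day=departure_day, destination=destination,
                vessel_index=vessel_index)
    n_steps = int(config.max_duration_days * HOURS_PER_DAY / config.step_hours)
    t_max_field = fieldset.t_atmos[-1]

    for _ in range(n_steps + 1):
        env = fieldset.sample(lat, lon, t)
        heading = choose_heading((lat, lon), target, polar, (env.wind_u, env.wind_v),
                                 config.heading_fan_deg, config.heading_step_deg)
        if config.heading_noise_deg > 0:
            heading = (heading + rng.normal(0.0, config.heading_noise_deg)) % 360.0
        sail = sailing_velocity(polar, (env.wind_u, env.wind_v), heading)
        drift = (env.cur_u, env.cur_v)
        trip.points.append(TrajectoryPoint(t=t, lat=lat, lon=lon, env=env,
                                           sail_vec=sail, drift_vec=drift))
        if great_circle_km(lat, lon, target[0], target[1]) <= config.arrival_radius_km:
            trip.outcome = "arrived"
            break
        if t - departure_day * HOURS_PER_DAY >= config.max_duration_days * HOURS_PER_DAY:
            trip.outcome = "timed_out"
            break
        total = (sail[0] + drift[0], sail[1] + drift[1])
        new_lat, new_lon = step_position(lat, lon, total, config.step_hours)
        new_t = t + config.step_hours
        if not fieldset.contains(new_lat, new_lon) or new_t > t_max_field:
            trip.outcome = "exited_domain" if not fieldset.contains(new_lat, new_lon) \
                else "timed_out"
            break
        lat, lon, t = new_lat, new_lon, new_t
    return trip


def schedule_departures(config: SimConfig, years: int) -> list[tuple[int, str, int]]:
    """All (departure_day, destination, vessel_index) triples for ``years`` years.

    73 departure days per 365-day year at a 5-day interval, with
    ``vessels_per_departure`` vessels per destination per day.
    """
    out: list[tuple[int, str, int]] = []
    per_year = DAYS_PER_YEAR // config.departure_interval_days
    for y in range(years):
        for k in range(per_year):
            day = y * DAYS_PER_YEAR + k * config.departure_interval_days
            for destination in DESTINATIONS:
                for vessel in range(config.vessels_per_departure):
                    out.append((day, destination, vessel))
    return out
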