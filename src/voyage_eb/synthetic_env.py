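"""Synthetic gridded Pacific environment fields.

Generates surface air temperature, 10-m wind, downward shortwave flux and
surface currents on a regular lat/lon grid with the climatological structure
the downstream analysis relies on: a latitudinal temperature gradient,
hemispherically opposed seasonal cycles, trade-wind and westerly belts,
solar-geometry insolation with cloud attenuation, zonal current bands and an
ENSO-like interannual perturbation. Everything is a deterministic function of
the configuration seed.

Time is measured in hours on an idealized 365-day calendar (see
:mod:`voyage_eb.calendar365`). Longitudes use the 0-360 convention so that
tracks crossing the dateline stay monotone inside the domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .calendar365 import HOURS_PER_DAY, day_of_year, local_solar_hour
from .errors import ConfigurationError, FieldFormatError, OutOfDomainError

SOLAR_CONSTANT = 1361.0  # W/m2 top-of-atmosphere
CLEAR_SKY_TRANSMITTANCE = 0.75


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid with separate atmosphere and ocean time axes.

    Times are hours since the idealized epoch; ``atmos_step`` defaults to
    hourly (6 h is acceptable for sailing-only runs) and ``ocean_step`` to
    daily.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float = 0.25
    time_start: float = 0.0
    time_end: float = 365.0 * HOURS_PER_DAY
    atmos_step: float = 1.0
    ocean_step: float = 24.0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ConfigurationError("grid resolution must be positive")
        if not (-90.0 <= self.lat_min < self.lat_max <= 90.0):
            raise ConfigurationError("latitude bounds must satisfy -90 <= min < max <= 90")
        if self.lon_min >= self.lon_max:
            raise ConfigurationError("lon_min must be < lon_max")
        if self.time_end <= self.time_start:
            raise ConfigurationError("time_end must be after time_start")
        if self.atmos_step <= 0 or self.ocean_step <= 0:
            raise ConfigurationError("time steps must be positive")

    @property
    def lats(self) -> np.ndarray:
        n = int(np.floor((self.lat_max - self.lat_min) / self.resolution + 1e-9)) + 1
        return self.lat_min + self.resolution * np.arange(n)

    @property
    def lons(self) -> np.ndarray:
        n = int(np.floor((self.lon_max - self.lon_min) / self.resolution + 1e-9)) + 1
        return self.lon_min + self.resolution * np.arange(n)

    @property
    def atmos_times(self) -> np.ndarray:
        n = int(np.floor((self.time_end - self.time_start) / self.atmos_step)) + 1
        return self.time_start + self.atmos_step * np.arange(n)

    @property
    def ocean_times(self) -> np.ndarray:
        n = int(np.floor((self.time_end - self.time_start) / self.ocean_step)) + 1
        return self.time_start + self.ocean_step * np.arange(n)


#: (center latitude deg, gaussian half-width deg, zonal speed m/s)
DEFAULT_WIND_BELTS: tuple[tuple[float, float, float], ...] = (
    (-52.0, 13.0, 10.0),   # SH westerlies
    (-15.0, 13.0, -8.0),   # SH trades (easterly)
    (15.0, 13.0, -8.0),    # NH trades
    (52.0, 13.0, 10.0),    # NH westerlies
)

DEFAULT_CURRENT_BANDS: tuple[tuple[float, float, float], ...] = (
    (-8.0, 8.0, -0.25),    # south equatorial current (westward)
    (25.0, 8.0, 0.12),     # subtropical return flow
    (-45.0, 8.0, 0.30),    # circumpolar eastward flow
)

DEFAULT_NOISE_SCALES: Mapping[str, float] = {
    "sat": 0.6,      # degC
    "wind": 3.0,     # m/s per component (synoptic variability)
    "solar": 25.0,   # W/m2 (daytime only, clipped at 0)
    "current": 0.03, # m/s per component
}

_ENSO_TRADE_FACTOR = {"nino": 0.75, "neutral": 1.0, "nina": 1.15}


@dataclass(frozen=True)
class ClimateConfig:
    """Parameters of the synthetic climatology; ``seed`` fixes every field bit-for-bit."""

    seed: int = 0
    equator_sat: float = 28.0
    polar_gradient: float = 0.42   # degC per degree latitude
    seasonal_amplitude: float = 6.0
    diurnal_amplitude: float = 0.0
    enso_phase: str = "neutral"
    enso_sat_anomaly: float = 1.5
    wind_belt_params: Sequence[tuple[float, float, float]] = DEFAULT_WIND_BELTS
    cloud_attenuation: float = 0.35
    current_band_params: Sequence[tuple[float, float, float]] = DEFAULT_CURRENT_BANDS
    noise_scales: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SCALES)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.cloud_attenuation <= 1.0:
            raise ConfigurationError("cloud_attenuation must lie in [0, 1]")
        if self.enso_phase not in _ENSO_TRADE_FACTOR:
            raise ConfigurationError(f"unknown enso_phase {self.enso_phase!r}")
        if self.seasonal_amplitude < 0 or self.enso_sat_anomaly < 0:
            raise ConfigurationError("amplitudes must be non-negative")
        if any(v < 0 for v in self.noise_scales.values()):
            raise ConfigurationError("noise scales must be non-negative")

    def with_phase(self, phase: str) -> "ClimateConfig":
        return replace(self, enso_phase=phase)


@dataclass(frozen=True)
class EnvSample:
    """Point sample of the environment: Ta (degC), 10-m wind, shortwave, current."""

    ta_c: float
    wind_u: float
    wind_v: float
    solar_wm2: float
    cur_u: float
    cur_v: float

    @property
    def ws10(self) -> float:
        return float(np.hypot(self.wind_u, self.wind_v))

    @property
    def cur(self) -> tuple[float, float]:
        return (self.cur_u, self.cur_v)


def _enso_sign(phase: str) -> float:
    return {"nino": 1.0, "neutral": 0.0, "nina": -1.0}[phase]


def _sat_deterministic(cfg: ClimateConfig, t_hours, lat, lon):
    """Closed-form SAT (degC); broadcastable over (time, lat, lon)."""
    doy = day_of_year(t_hours)
    base = cfg.equator_sat - cfg.polar_gradient * np.abs(lat)
    lat_weight = np.clip(np.abs(lat), 0.0, 60.0) / 60.0
    # NH maximum near doy 196 (mid-July); sign(lat) opposes the hemispheres.
    seasonal = (
        cfg.seasonal_amplitude
        * lat_weight
        * np.sign(lat)
        * np.cos(2.0 * np.pi * (doy - 196.0) / 365.0)
    )
    diurnal = 0.0
    if cfg.diurnal_amplitude > 0:
        lsh = local_solar_hour(t_hours, lon)
        diurnal = cfg.diurnal_amplitude * np.cos(2.0 * np.pi * (lsh - 14.0) / 24.0)
    enso = (
        _enso_sign(cfg.enso_phase)
        * cfg.enso_sat_anomaly
        * np.exp(-((lat / 12.0) ** 2))
    )
    return base + seasonal + diurnal + enso


def _wind_deterministic(cfg: ClimateConfig, lat):
    """Zonal belt structure; trades are modulated by the ENSO phase."""
    factor = _ENSO_TRADE_FACTOR[cfg.enso_phase]
    u = np.zeros_like(np.asarray(lat, dtype=float))
    for center, width, speed in cfg.wind_belt_params:
        f = factor if abs(center) <= 30.0 else 1.0
        u = u + f * speed * np.exp(-(((lat - center) / width) ** 2))
    # weak equatorward flow inside the trade belts
    v = 1.0 * np.sign(-np.asarray(lat, dtype=float)) * np.exp(
        -(((np.abs(lat) - 15.0) / 10.0) ** 2)
    )
    return u, v


def toa_cos_zenith(t_hours, lat, lon):
    """Cosine of the solar zenith angle (clipped at 0) for the idealized calendar."""
    doy = day_of_year(t_hours)
    decl = np.deg2rad(23.44) * np.sin(2.0 * np.pi * (doy - 81.0) / 365.0)
    hour_angle = np.deg2rad((local_solar_hour(t_hours, lon) - 12.0) * 15.0)
    rlat = np.deg2rad(lat)
    cosz = np.sin(rlat) * np.sin(decl) + np.cos(rlat) * np.cos(decl) * np.cos(hour_angle)
    return np.maximum(cosz, 0.0)


def _solar_deterministic(cfg: ClimateConfig, t_hours, lat, lon):
    cosz = toa_cos_zenith(t_hours, lat, lon)
    lat_weight = np.clip(np.abs(lat), 0.0, 60.0) / 60.0
    cloud = np.clip(cfg.cloud_attenuation * (0.7 + 0.6 * lat_weight), 0.0, 0.95)
    return SOLAR_CONSTANT * CLEAR_SKY_TRANSMITTANCE * cosz * (1.0 - cloud)


def _current_deterministic(cfg: ClimateConfig, lat):
    u = np.zeros_like(np.asarray(lat, dtype=float))
    for center, width, speed in cfg.current_band_params:
        u = u + speed * np.exp(-(((lat - center) / width) ** 2))
    return u, np.zeros_like(u)


def _smooth_noise(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Seeded spatially/temporally correlated noise with standard deviation ``scale``."""
    if scale == 0.0:
        return np.zeros(shape, dtype=np.float32)
    raw = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(raw, sigma=(4.0, 1.0, 1.0), mode="nearest")
    sd = smooth.std()
    if sd > 0:
        smooth *= scale / sd
    return smooth.astype(np.float32)


@dataclass
class EnvFieldSet:
    """Gridded time-varying fields with fast sampling accessors.

    Atmospheric fields (``sat``, ``wind_u``, ``wind_v``, ``solar``) live on the
    atmosphere time axis and are interpolated linearly in time; current fields
    live on the ocean time axis and are held constant within each step.
    All fields are bilinear in space.
    """

    grid: GridSpec
    lats: np.ndarray
    lons: np.ndarray
    t_atmos: np.ndarray
    t_ocean: np.ndarray
    sat: np.ndarray
    wind_u: np.ndarray
    wind_v: np.ndarray
    solar: np.ndarray
    cur_u: np.ndarray
    cur_v: np.ndarray

    # -- interpolation helpers -------------------------------------------------

    def _frac_index(self, coords: np.ndarray, value, name: str):
        lo, hi = coords[0], coords[-1]
        value = np.asarray(value, dtype=float)
        if np.any(value < lo - 1e-9) or np.any(value > hi + 1e-9):
            raise OutOfDomainError(
                f"{name} value outside domain [{lo}, {hi}]"
            )
        step = coords[1] - coords[0] if coords.size > 1 else 1.0
        x = np.clip((value - lo) / step, 0.0, coords.size - 1.0)
        i0 = np.minimum(x.astype(int), coords.size - 2) if coords.size > 1 else np.zeros_like(x, int)
        return i0, x - i0

    def _trilinear(self, arr, k0, fk, i0, fi, j0, fj):
        k1, i1, j1 = k0 + 1, i0 + 1, j0 + 1
        c00 = arr[k0, i0, j0] * (1 - fj) + arr[k0, i0, j1] * fj
        c01 = arr[k0, i1, j0] * (1 - fj) + arr[k0, i1, j1] * fj
        c10 = arr[k1, i0, j0] * (1 - fj) + arr[k1, i0, j1] * fj
        c11 = arr[k1, i1, j0] * (1 - fj) + arr[k1, i1, j1] * fj
        c0 = c00 * (1 - fi) + c01 * fi
        c1 = c10 * (1 - fi) + c11 * fi
        return c0 * (1 - fk) + c1 * fk

    def _bilinear_at(self, arr, k, i0, fi, j0, fj):
        i1, j1 = i0 + 1, j0 + 1
        c0 = arr[k, i0, j0] * (1 - fj) + arr[k, i0, j1] * fj
        c1 = arr[k, i1, j0] * (1 - fj) + arr[k, i1, j1] * fj
        return c0 * (1 - fi) + c1 * fi

    def contains(self, lat: float, lon: float) -> bool:
        return (
            self.lats[0] - 1e-9 <= lat <= self.lats[-1] + 1e-9
            and self.lons[0] - 1e-9 <= lon <= self.lons[-1] + 1e-9
        )

    def sample_track(self, lats, lons, ts) -> dict[str, np.ndarray]:
        """Vectorized sampling along a track; returns arrays per field."""
        lats = np.atleast_1d(np.asarray(lats, dtype=float))
        lons = np.atleast_1d(np.asarray(lons, dtype=float))
        ts = np.atleast_1d(np.asarray(ts, dtype=float))
        i0, fi = self._frac_index(self.lats, lats, "latitude")
        j0, fj = self._frac_index(self.lons, lons, "longitude")
        k0, fk = self._frac_index(self.t_atmos, ts, "time")
        # time axis may end exactly on a node
        k0 = np.minimum(k0, self.sat.shape[0] - 2)
        fk = np.clip((ts - self.t_atmos[0]) / self.grid.atmos_step - k0, 0.0, 1.0)
        out = {}
        for name, arr in (
            ("ta_c", self.sat),
            ("wind_u", self.wind_u),
            ("wind_v", self.wind_v),
            ("solar_wm2", self.solar),
        ):
            out[name] = np.asarray(
                self._trilinear(arr, k0, fk, i0, fi, j0, fj), dtype=float
            )
        # currents: constant within each ocean step
        ko = np.clip(
            ((ts - self.t_ocean[0]) / self.grid.ocean_step).astype(int),
            0,
            self.t_ocean.size - 1,
        )
        out["cur_u"] = np.asarray(self._bilinear_at(self.cur_u, ko, i0, fi, j0, fj), float)
        out["cur_v"] = np.asarray(self._bilinear_at(self.cur_v, ko, i0, fi, j0, fj), float)
        out["solar_wm2"] = np.maximum(out["solar_wm2"], 0.0)
        return out

    def sample(self, lat: float, lon: float, t: float) -> EnvSample:
        """Point sample: bilinear in space, linear in time (currents step-constant)."""
        tr = self.sample_track([lat], [lon], [t])
        return EnvSample(
            ta_c=float(tr["ta_c"][0]),
            wind_u=float(tr["wind_u"][0]),
            wind_v=float(tr["wind_v"][0]),
            solar_wm2=float(tr["solar_wm2"][0]),
            cur_u=float(tr["cur_u"][0]),
            cur_v=float(tr["cur_v"][0]),
        )


def generate_fields(config: ClimateConfig, grid: GridSpec) -> EnvFieldSet:
    """Generate the full synthetic field set for ``grid`` under ``config``.

    Raises :class:`ConfigurationError` when no configured wind-belt center
    falls inside the latitude span of the domain.
    """
    lats, lons = grid.lats, grid.lons
    if not any(grid.lat_min <= c <= grid.lat_max for c, _, _ in config.wind_belt_params):
        raise ConfigurationError(
            "domain latitude span contains none of the configured wind belts"
        )

    ta = grid.atmos_times[:, None, None]
    la = lats[None, :, None]
    lo = lons[None, None, :]

    rng = np.random.default_rng(config.seed)
    shape = (grid.atmos_times.size, lats.size, lons.size)
    ns = config.noise_scales

    sat = (_sat_deterministic(config, ta, la, lo)
           + _smooth_noise(rng, shape, ns.get("sat", 0.0))).astype(np.float32)

    u_det, v_det = _wind_deterministic(config, la)
    wind_u = (np.broadcast_to(u_det, shape)
              + _smooth_noise(rng, shape, ns.get("wind", 0.0))).astype(np.float32)
    wind_v = (np.broadcast_to(v_det, shape)
              + _smooth_noise(rng, shape, ns.get("wind", 0.0))).astype(np.float32)

    solar_det = _solar_deterministic(config, ta, la, lo)
    solar = solar_det + _smooth_noise(rng, shape, ns.get("solar", 0.0))
    solar = np.where(solar_det > 0.0, np.maximum(solar, 0.0), 0.0).astype(np.float32)

    oshape = (grid.ocean_times.size, lats.size, lons.size)
    cu_det, cv_det = _current_deterministic(config, la)
    cur_u = (np.broadcast_to(cu_det, oshape)
             + _smooth_noise(rng, oshape, ns.get("current", 0.0))).astype(np.float32)
    cur_v = (np.broadcast_to(cv_det, oshape)
             + _smooth_noise(rng, oshape, ns.get("current", 0.0))).astype(np.float32)

    return EnvFieldSet(
        grid=grid,
        lats=lats,
        lons=lons,
        t_atmos=grid.atmos_times,
        t_ocean=grid.ocean_times,
        sat=sat,
        wind_u=wind_u,
        wind_v=wind_v,
        solar=solar,
        cur_u=cur_u,
        cur_v=cur_v,
    )


# -- NetCDF IO ----------------------------------------------------------------

_ATMOS_VARS = {"sat": "sat", "u10": "wind_u", "v10": "wind_v", "ssrd": "solar"}
_OCEAN_VARS = {"uo": "cur_u", "vo": "cur_v"}


def to_dataset(fs: EnvFieldSet):
    """CF-style :class:`xarray.Dataset` view of a field set."""
    import xarray as xr

    ds = xr.Dataset(
        {
            "sat": (("time", "lat", "lon"), fs.sat, {"units": "degC", "long_name": "surface air temperature"}),
            "u10": (("time", "lat", "lon"), fs.wind_u, {"units": "m s-1"}),
            "v10": (("time", "lat", "lon"), fs.wind_v, {"units": "m s-1"}),
            "ssrd": (("time", "lat", "lon"), fs.solar, {"units": "W m-2", "long_name": "surface downward shortwave flux"}),
            "uo": (("time_ocean", "lat", "lon"), fs.cur_u, {"units": "m s-1"}),
            "vo": (("time_ocean", "lat", "lon"), fs.cur_v, {"units": "m s-1"}),
        },
        coords={
            "time": ("time", fs.t_atmos, {"units": "hours"}),
            "time_ocean": ("time_ocean", fs.t_ocean, {"units": "hours"}),
            "lat": ("lat", fs.lats, {"units": "degrees_north"}),
            "lon": ("lon", fs.lons, {"units": "degrees_east"}),
        },
        attrs={"Conventions": "CF-1.8"},
    )
    return ds


def write_fields(fs: EnvFieldSet, path) -> None:
    """Write a field set as NetCDF (scipy backend, NetCDF3)."""
    to_dataset(fs).to_netcdf(path, engine="scipy")


def from_dataset(ds) -> EnvFieldSet:
    for name in list(_ATMOS_VARS) + list(_OCEAN_VARS):
        if name not in ds:
            raise FieldFormatError(f"environment file is missing variable {name!r}")
    for dim in ("time", "lat", "lon", "time_ocean"):
        if dim not in ds.dims:
            raise FieldFormatError(f"environment file is missing dimension {dim!r}")
    lats = np.asarray(ds["lat"].values, dtype=float)
    lons = np.asarray(ds["lon"].values, dtype=float)
    t_atmos = np.asarray(ds["time"].values, dtype=float)
    t_ocean = np.asarray(ds["time_ocean"].values, dtype=float)
    sat = np.asarray(ds["sat"].values, dtype=np.float32)
    if str(ds["sat"].attrs.get("units", "degC")).lower() in ("k", "kelvin"):
        sat = sat - np.float32(273.15)
    grid = GridSpec(
        lat_min=float(lats[0]),
        lat_max=float(lats[-1]),
        lon_min=float(lons[0]),
        lon_max=float(lons[-1]),
        resolution=float(lats[1] - lats[0]) if lats.size > 1 else 0.25,
        time_start=float(t_atmos[0]),
        time_end=float(t_atmos[-1]),
        atmos_step=float(t_atmos[1] - t_atmos[0]) if t_atmos.size > 1 else 1.0,
        ocean_step=float(t_ocean[1] - t_ocean[0]) if t_ocean.size > 1 else 24.0,
    )
    return EnvFieldSet(
        grid=grid,
        lats=lats,
        lons=lons,
        t_atmos=t_atmos,
        t_ocean=t_ocean,
        sat=sat,
        wind_u=np.asarray(ds["u10"].values, np.float32),
        wind_v=np.asarray(ds["v10"].values, np.float32),
        solar=np.asarray(ds["ssrd"].values, np.float32),
        cur_u=np.asarray(ds["uo"].values, np.float32),
        cur_v=np.asarray(ds["vo"].values, np.float32),
    )


def read_fields(path) -> EnvFieldSet:
    """Read a field set written by :func:`write_fields` (SAT in K is converted)."""
    import xarray as xr

    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        ds.load()
        return from_dataset(ds)
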