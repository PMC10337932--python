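"""End-to-end orchestration: env generation -> voyages -> EB -> aggregation.

``run_analysis`` keeps everything in memory and is the programmatic entry
point; ``run_pipeline`` adds file output plus a provenance manifest. Every
stage is a pure function of (config, seed), so re-running an identical config
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calendar365 import DAYS_PER_YEAR, SEASONS
from .config import RunConfig
from .errors import VoyageEBError
from . import interpretation
from .synthetic_env import generate_fields, write_fields
from .trip_energetics import (aeb_ratio_table, departure_day_stats,
                              departure_env, destination_contrast, eb_series,
                              seasonal_means)
from .voyage_sim import DESTINATIONS, Trip, simulate_trip

log = logging.getLogger("voyage_eb")


@dataclass
class AnalysisResult:
    config: RunConfig
    trips: list[Trip]
    day_stats: pd.DataFrame        # per (doy, destination, body, exposure)
    seasonal: pd.DataFrame
    contrasts: list                # ContrastResult per departure day
    gap_by_day: pd.DataFrame       # config-mean NZ - HW daily EB gap
    ratios: pd.DataFrame
    interpret_report: dict
    counts: dict = field(default_factory=dict)


def _gap_by_day(day_stats: pd.DataFrame) -> pd.DataFrame:
    """Config-mean NZ - HW mean daily EB per departure day-of-year."""
    pooled = (
        day_stats.groupby(["departure_doy", "destination"])["mean_daily_eb"]
        .mean()
        .unstack("destination")
    )
    out = pd.DataFrame({
        "departure_doy": pooled.index,
        "gap_kcal_day": pooled["new_zealand"] - pooled["hawaii"],
    }).reset_index(drop=True)
    from .calendar365 import season_of_day
    out["season"] = out["departure_doy"].map(season_of_day)
    return out


def run_analysis(config: RunConfig, progress: bool = False) -> AnalysisResult:
    """Execute every stage in memory and return the aggregated results."""
    bodies = config.body_types()
    exposures = dict(config.exposures)
    all_series = []
    trips_all: list[Trip] = []
    departures_per_year = DAYS_PER_YEAR // config.sim.departure_interval_days

    for year_index in range(len(config.years)):
        t0 = time.time()
        grid = config.grid_for_year(year_index)
        fieldset = generate_fields(config.climate_for_year(year_index), grid)
        log.info("year %d (%s): fields generated in %.1fs", year_index,
                 config.years[year_index], time.time() - t0)
        for k in range(departures_per_year):
            day = year_index * DAYS_PER_YEAR + k * config.sim.departure_interval_days
            for destination in DESTINATIONS:
                vessels = [
                    simulate_trip(day, destination, fieldset, config.polar,
                                  config.sim, vessel_index=v)
                    for v in range(config.sim.vessels_per_departure)
                ]
                trips_all.extend(vessels)
                env = departure_env(vessels, fieldset)
                for body in bodies:
                    for exp in exposures.values():
                        all_series.append(eb_series(env, body, exp))
        del fieldset

    day_stats = departure_day_stats(all_series)
    seasonal = seasonal_means(day_stats)
    gap = _gap_by_day(day_stats)

    # per-day contrast of config-pooled values across matched body x exposure cells
    nz_by_day: dict[int, list[float]] = {}
    hw_by_day: dict[int, list[float]] = {}
    for _, row in day_stats.iterrows():
        bucket = nz_by_day if row["destination"] == "new_zealand" else hw_by_day
        bucket.setdefault(int(row["departure_doy"]), []).append(row["mean_daily_eb"])
    contrasts = destination_contrast(nz_by_day, hw_by_day)

    ratios = aeb_ratio_table(day_stats)

    # worked-example conversions from the SH-summer (DJF) mean gap magnitude
    djf_gap = float(gap[gap.season == "DJF"]["gap_kcal_day"].mean())
    deficit = abs(djf_gap)
    report = interpretation.report(deficit, config.trip_days,
                                   table=config.densities,
                                   heat_fraction=config.heat_fraction)
    report["sh_summer_gap_kcal_day"] = djf_gap

    counts = {
        "n_trips": len(trips_all),
        "n_trips_per_destination": len(trips_all) // len(DESTINATIONS),
        "n_eb_series": len(all_series),
        "n_departure_days": int(day_stats["departure_doy"].nunique()),
        "outcomes": pd.Series([t.outcome for t in trips_all]).value_counts().to_dict(),
    }
    return AnalysisResult(config=config, trips=trips_all, day_stats=day_stats,
                          seasonal=seasonal, contrasts=contrasts, gap_by_day=gap,
                          ratios=ratios, interpret_report=report, counts=counts)


def trips_index_frame(trips: list[Trip]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "trip_id": f"{t.destination}_d{t.departure_day:04d}_v{t.vessel_index}",
            "departure_day": t.departure_day,
            "departure_doy": t.departure_doy,
            "destination": t.destination,
            "vessel_index": t.vessel_index,
            "outcome": t.outcome,
            "duration_days": t.duration_days,
            "final_lat": t.points[-1].lat,
            "final_lon": t.points[-1].lon,
        }
        for t in trips
    ])


def trip_points_frame(trip: Trip) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "t_hours": p.t, "lat": p.lat, "lon": p.lon,
            "ta_c": p.env.ta_c, "ws10_ms": p.env.ws10,
            "solar_wm2": p.env.solar_wm2,
            "cur_u": p.env.cur_u, "cur_v": p.env.cur_v,
            "sail_u": p.sail_vec[0], "sail_v": p.sail_vec[1],
        }
        for p in trip.points
    ])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir, write_env: bool = False,
                 write_trajectories: bool = False) -> dict:
    """Run all stages, write outputs under ``out_dir`` and return the manifest.

    A stage failure raises with the stage name; partial outputs written before
    the failure are recorded in ``manifest.json`` alongside the error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    try:
        import voyage_eb
        manifest["version"] = voyage_eb.__version__
    except Exception:  # pragma: no cover
        manifest["version"] = "unknown"

    def finish_stage(name: str, t0: float, **info):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 2), **info}

    try:
        if write_env:
            t0 = time.time()
            for year_index in range(len(config.years)):
                fs = generate_fields(config.climate_for_year(year_index),
                                     config.grid_for_year(year_index))
                write_fields(fs, out / f"env_year{year_index}.nc")
            finish_stage("generate-env", t0, years=len(config.years))

        t0 = time.time()
        result = run_analysis(config)
        finish_stage("simulate+energy+aggregate", t0, **result.counts)

        t0 = time.time()
        trips_index_frame(result.trips).to_csv(out / "trips_index.csv", index=False)
        if write_trajectories:
            traj_dir = out / "trajectories"
            traj_dir.mkdir(exist_ok=True)
            for t in result.trips:
                tid = f"{t.destination}_d{t.departure_day:04d}_v{t.vessel_index}"
                trip_points_frame(t).to_csv(traj_dir / f"{tid}.csv", index=False)
        result.day_stats.to_csv(out / "departure_day_stats.csv", index=False)
        result.seasonal.to_csv(out / "seasonal_means.csv", index=False)
        result.gap_by_day.to_csv(out / "gap_by_day.csv", index=False)
        result.ratios.to_csv(out / "aeb_ratios.csv", index=False)
        pd.DataFrame([c.__dict__ for c in result.contrasts]).to_csv(
            out / "contrasts.csv", index=False)
        (out / "interpretation.json").write_text(
            json.dumps(result.interpret_report, indent=2, sort_keys=True))
        finish_stage("write-outputs", t0)
    except VoyageEBError as exc:
        manifest["error"] = {"stage": "pipeline", "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
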