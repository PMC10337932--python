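# voyage-eb

Coupled canoe-voyage simulation and resting energy-balance (EB) analysis on
synthetic Pacific environmental fields.

The package simulates sailing passages from Tahiti toward Hawaii and New
Zealand across seeded synthetic climate fields (surface air temperature,
10-m winds, cloud-attenuated shortwave flux, surface currents), computes an
along-track resting energy balance `EB = BMR - L` for configurable body types
and exposure levels, and aggregates results by departure day: means with 95%
confidence intervals, seasonal averages, destination contrasts, aggregate EB
(aEB) ratios, and worked-example conversions of daily deficits into fat,
muscle, food and physical-activity equivalents.

## Layout

| module | role |
|---|---|
| `voyage_eb.synthetic_env` | seeded gridded fields + bilinear/linear sampling, NetCDF IO |
| `voyage_eb.voyage_sim` | current drift + polar sailing, VMG steering, departure schedule |
| `voyage_eb.body_model` | body types, BMI, BSA, SCF-from-BMI relations, Oxford BMR |
| `voyage_eb.energy_balance` | the EB model (convection, layered insulation, solar gain) |
| `voyage_eb.trip_energetics` | departure-day aggregation, CIs, Welch contrasts, aEB |
| `voyage_eb.interpretation` | deficit-to-fat/muscle/food/activity conversions |
| `voyage_eb.pipeline` / `voyage_eb.cli` | end-to-end orchestration, manifest, CLI |

## CLI

```bash
voyage-eb interpret --deficit 965 --days 25          # worked-example conversions
voyage-eb bodies                                     # resolved six body types (CSV)
voyage-eb schedule --years 3                         # departure-schedule arithmetic
voyage-eb generate-env --profile demo --seed 1 --out env.nc
voyage-eb run --profile demo --seed 1 --out out/     # full pipeline + manifest
```

All stages are pure functions of `(config, seed)`; a YAML config file
(`--config`) can override the grid, climate, polar, bodies, exposures and
densities (see `voyage_eb.config.load_config`).

## Notes

- Time uses an idealized 365-day no-leap calendar measured in hours;
  longitudes use the 0-360 convention (dateline-safe).
- The sailing polar is a documented parametric stand-in (no published numeric
  polar exists for the replica canoe); results are comparative, not absolute.
- The synthetic climatology reproduces structure (gradients, seasonal phase,
  wind/current belts, ENSO-like anomalies), not any reanalysis product.
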