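"""Build a fused space-time PM2.5 field from a synthetic annual raster and
nine hourly station series, and probe it.

The fused field is additive: C(p, t) = C_base(t) + (annual(p) - annual(base)),
where "base" is the representative station — the one whose hourly series
deviates least (minimum difference-series variance) from the annual map.
"""

import numpy as np

import dynexposure as dx

cfg = dx.ScenarioConfig(seed=1)
grid = dx.gen_annual_grid(cfg)
stations = dx.gen_station_series(cfg, grid)

field, ranked = dx.build_field(grid, stations)

print(f"annual raster: {grid.n_rows}x{grid.n_cols} cells of "
      f"{grid.cell_size} deg, mean {grid.mean():.1f} ug/m3")
print("station ranking (difference variance, ascending):")
for fit in ranked:
    mark = " <- representative" if fit.station_id == field.base_station.station_id else ""
    print(f"  {fit.station_id}: variance {fit.variance:8.2f} "
          f"(annual at site {fit.annual_value:.1f}){mark}")

# probe the field at one location across the pollution episode
lon, lat = 114.30, 30.60  # the scenario's main urban hotspot
times = field.base_station.timestamps[::12]
values = field.evaluate(np.full(times.size, lon), np.full(times.size, lat),
                        times)
print(f"\nfused concentration at ({lon}, {lat}), every 12 h:")
for t, v in zip(times, values):
    print(f"  {t}  {v:7.1f} ug/m3  ({dx.classify_air_quality(float(v))})")
print("\nThe hotspot cell tracks the station's hours shifted up by its "
      "annual spatial anomaly; mid-scenario values spike with the "
      "multi-day pollution episode.")
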