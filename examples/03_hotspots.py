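"""Activity hotspots of the highest- and lowest-exposure drivers.

Eligible drivers are ranked by mean daily time-weighted exposure; the top
and bottom fractions form the high/low groups, whose trip origins and
destinations are turned into quartic-kernel density surfaces (0.001-deg
cells).  The surface argmax marks each group's main activity hotspot.
"""

import dynexposure as dx

cfg = dx.ScenarioConfig(n_taxis=10, n_days=2, seed=3)
grid = dx.gen_annual_grid(cfg)
stations = dx.gen_station_series(cfg, grid)
network = dx.gen_road_network(cfg)
field, _ = dx.build_field(grid, stations)
fixes, _ = dx.gen_trajectories(cfg, network, field)
matched = dx.match_trips(dx.extract_trips(dx.clean_fixes(fixes, cfg.extent)),
                         network)
exposures = dx.compute_trip_exposures(matched, field)

driver_days, _, _, _ = dx.daily_summaries(exposures)
# the 2-day scenario scales the study's >=10-weekday / >=4-weekend rule down
eligible = dx.filter_eligible_drivers(driver_days, min_weekdays=1,
                                      min_weekend_days=1)
means = {t: m for t, m in dx.driver_mean_twa(driver_days).items()
         if t in set(eligible)}
high, low = dx.select_extreme_drivers(means, fraction=0.1)
print(f"{len(eligible)} eligible drivers; high group {high}, low group {low}")

surfaces = dx.group_hotspots(matched, high, low, day_types=("weekday",))
for (group, day_type), surf in surfaces.items():
    lon, lat = surf.argmax_lonlat()
    mean_km, med_km, n = dx.trip_distance_stats(
        matched, high if group == "high" else low, day_type)
    print(f"{group:4s}/{day_type}: hotspot at ({lon:.3f}, {lat:.3f}), "
          f"KDE mass {surf.mass():.1f} points, "
          f"mean trip {mean_km:.2f} km (median {med_km:.2f}, n={n})")
print("\nSurfaces integrate to the number of origin/destination points; "
      "write them out with dynexposure.write_annual_grid(surf.to_grid(), path).")
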