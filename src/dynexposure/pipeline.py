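"""End-to-end pipeline: simulate -> preprocess -> field -> exposure ->
hotspots -> report, driven by a single structured config.

Each stage reads its inputs from files and writes its outputs into the
configured output directory, so stages can be rerun selectively.  All
randomness derives from the config seed; rerunning with identical config
and inputs reproduces identical result files byte for byte (outputs carry
no wall-clock timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import group_hotspots, trip_distance_stats
from .errors import ConfigError, DataError
from .exposure import (ExposureConfig, compute_trip_exposures, daily_summaries,
                       day_type_of, driver_mean_twa, filter_eligible_drivers,
                       guideline_comparison, hourly_summary,
                       select_extreme_drivers)
from .fusion import build_field
from .io_formats import (read_annual_grid, read_road_network_geojson,
                         read_station_csv, read_trajectory_frame,
                         read_trips_geojson, write_annual_grid,
                         write_road_network_geojson, write_station_csv,
                         write_trajectory_csv, write_trips_geojson)
from .preprocess import TripFilters, clean_fixes, extract_trips, match_trips
from .synthetic import (ScenarioConfig, gen_annual_grid, gen_road_network,
                        gen_station_series, gen_trajectories)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "preprocess", "field", "exposure", "hotspots",
              "report")


@dataclass
class PipelineConfig:
    """Structured configuration for the whole pipeline."""

    output_dir: str = "out"
    seed: int = 0
    simulate: bool = True
    log_level: str = "INFO"
    paths: dict = dc_field(default_factory=dict)  # raster/stations/trajectories/network
    scenario: dict = dc_field(default_factory=dict)
    preprocess: dict = dc_field(default_factory=dict)
    field: dict = dc_field(default_factory=dict)
    exposure: dict = dc_field(default_factory=dict)
    kde: dict = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def scenario_config(self) -> ScenarioConfig:
        from .synthetic import EpisodeSpec, Hotspot
        kw = dict(self.scenario)
        kw.setdefault("seed", self.seed)
        # coerce YAML-native lists/dicts into the scenario value types
        if "extent" in kw:
            kw["extent"] = tuple(kw["extent"])
        if "hotspots" in kw:
            kw["hotspots"] = tuple(
                h if isinstance(h, Hotspot) else Hotspot(**h)
                for h in kw["hotspots"])
        if "station_locations" in kw:
            kw["station_locations"] = tuple(
                tuple(s) for s in kw["station_locations"])
        if "diurnal" in kw:
            kw["diurnal"] = tuple(kw["diurnal"])
        ep = kw.get("episode")
        if isinstance(ep, dict):
            kw["episode"] = EpisodeSpec(**ep)
        try:
            return ScenarioConfig(**kw)
        except TypeError as exc:
            raise ConfigError(f"bad scenario config: {exc}") from exc

    def exposure_config(self) -> ExposureConfig:
        kw = {k: v for k, v in self.exposure.items()
              if k in {f.name for f in dataclasses.fields(ExposureConfig)}}
        if "china_thresholds" in kw:
            kw["china_thresholds"] = tuple(kw["china_thresholds"])
        return ExposureConfig(**kw)

    def path(self, key: str, default_name: Optional[str] = None) -> Path:
        if key in self.paths and self.paths[key]:
            return Path(self.paths[key])
        if default_name is None:
            raise ConfigError(f"config paths.{key} is required")
        return Path(self.output_dir) / default_name


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _stage_simulate(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    sc = cfg.scenario_config()
    grid = gen_annual_grid(sc)
    stations = gen_station_series(sc, grid)
    network = gen_road_network(sc)
    field, _ranked = build_field(grid, stations,
                                 z_threshold=cfg.field.get("z_threshold", 5.0),
                                 override_id=cfg.field.get("override_station"))
    lam = cfg.exposure_config().lambda_filtration
    fixes, gt = gen_trajectories(sc, network, field, lam=lam)
    write_annual_grid(grid, out / "annual.asc")
    write_station_csv(stations, out / "stations.csv")
    write_road_network_geojson(network, out / "network.geojson")
    write_trajectory_csv(fixes, out / "fixes.csv")
    true_rows = [(t.taxi_id, pd.Timestamp(t.t_start).isoformat(),
                  pd.Timestamp(t.t_end).isoformat(), t.ei, t.twa)
                 for t in gt.trips]
    pd.DataFrame(true_rows, columns=["taxi_id", "t_start", "t_end", "ei",
                                     "twa"]).to_csv(
        out / "true_trips.csv", index=False, float_format="%.10g")
    manifest["simulate"] = {"n_fixes": int(len(fixes)),
                            "n_true_trips": len(gt.trips),
                            "n_stations": len(stations),
                            "n_network_edges": network.n_edges}


def _stage_preprocess(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    grid = read_annual_grid(cfg.path("raster", "annual.asc"))
    network = read_road_network_geojson(cfg.path("network", "network.geojson"))
    fixes = read_trajectory_frame(cfg.path("trajectories", "fixes.csv"))
    pp = cfg.preprocess
    extent = (grid.origin_lon, grid.origin_lat, grid.lon_max, grid.lat_max)
    cleaned = clean_fixes(fixes, extent,
                          max_speed_kmh=pp.get("max_speed_kmh", 120.0))
    filters = TripFilters(
        min_fixes=pp.get("min_fixes", 2),
        min_duration_s=pp.get("min_duration_s", 60.0),
        min_distance_m=pp.get("min_distance_m", 200.0))
    trips = extract_trips(cleaned, filters)
    matched = match_trips(trips, network,
                          sigma_m=pp.get("sigma_m", 10.0),
                          beta_m=pp.get("beta_m", 200.0),
                          candidate_radius_m=pp.get("candidate_radius_m", 50.0),
                          filters=filters)
    write_trips_geojson(matched, out / "trips.geojson")
    manifest["preprocess"] = {
        "n_fixes_in": int(len(fixes)), "n_fixes_clean": int(len(cleaned)),
        "n_trips_extracted": len(trips), "n_trips_matched": len(matched)}


def _stage_field(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    grid = read_annual_grid(cfg.path("raster", "annual.asc"))
    stations = read_station_csv(cfg.path("stations", "stations.csv"))
    field, ranked = build_field(grid, stations,
                                z_threshold=cfg.field.get("z_threshold", 5.0),
                                override_id=cfg.field.get("override_station"))
    pd.DataFrame(
        [(f.station_id, f.variance, f.annual_value, f.n_hours, f.outlier_flag)
         for f in ranked],
        columns=["station_id", "variance", "annual_value", "n_hours",
                 "outlier_flag"]).to_csv(
        out / "station_ranking.csv", index=False, float_format="%.10g")
    _write_json({"base_station": field.base_station.station_id,
                 "base_annual_value": field.base_annual_value,
                 "grid_mean": grid.mean()},
                out / "field_manifest.json")
    manifest["field"] = {"base_station": field.base_station.station_id,
                         "n_stations_ranked": len(ranked)}


def _load_field(cfg: PipelineConfig, out: Path):
    grid = read_annual_grid(cfg.path("raster", "annual.asc"))
    stations = read_station_csv(cfg.path("stations", "stations.csv"))
    fm_path = out / "field_manifest.json"
    override = cfg.field.get("override_station")
    if fm_path.exists():
        with open(fm_path) as fh:
            override = json.load(fh)["base_station"]
    field, _ = build_field(grid, stations,
                           z_threshold=cfg.field.get("z_threshold", 5.0),
                           override_id=override)
    return field


def _stage_exposure(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    field = _load_field(cfg, out)
    trips = read_trips_geojson(out / "trips.geojson")
    xcfg = cfg.exposure_config()
    exposures = compute_trip_exposures(trips, field, xcfg)
    pd.DataFrame(
        [(te.taxi_id, pd.Timestamp(te.trip.time_start).isoformat(),
          pd.Timestamp(te.trip.time_end).isoformat(), te.trip.distance_km,
          te.ei, te.twa) for te in exposures],
        columns=["taxi_id", "time_start", "time_end", "distance_km", "ei",
                 "twa"]).to_csv(out / "trips_exposure.csv", index=False,
                                float_format="%.10g")
    for label, flt in (("all", None), ("weekday", "weekday"),
                       ("weekend", "weekend")):
        try:
            hs = hourly_summary(exposures, day_filter=flt,
                                ci_level=xcfg.ci_level)
        except DataError:
            continue
        hs.to_csv(out / f"hourly_{label}.csv", index=False,
                  float_format="%.10g")
    driver_days, per_day, wk, we = daily_summaries(exposures)
    pd.DataFrame([(d.taxi_id, d.date.isoformat(), d.day_type, d.daily_twa,
                   d.total_occupied_hours, d.n_trips) for d in driver_days],
                 columns=["taxi_id", "date", "day_type", "daily_twa",
                          "total_occupied_hours", "n_trips"]).to_csv(
        out / "driver_days.csv", index=False, float_format="%.10g")
    per_day.assign(date=per_day["date"].map(lambda d: d.isoformat())).to_csv(
        out / "daily.csv", index=False, float_format="%.10g")
    report = {}
    for label, (mean, sd) in (("weekday", wk), ("weekend", we)):
        if not np.isfinite(mean):
            continue
        ratio_who, excess_who = guideline_comparison(mean,
                                                     xcfg.guideline_who_24h)
        _, excess_cn = guideline_comparison(mean, xcfg.china_thresholds[1])
        report[label] = {
            "mean_24h_twa": mean, "sd": sd if np.isfinite(sd) else None,
            "who_ratio": ratio_who, "who_excess_pct": excess_who,
            "china_sensitive_excess_pct": excess_cn,
        }
    _write_json(report, out / "guideline_report.json")
    manifest["exposure"] = {"n_trip_exposures": len(exposures),
                            "n_driver_days": len(driver_days),
                            "clamp_count": field.clamp_count}


def _stage_hotspots(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    trips = read_trips_geojson(out / "trips.geojson")
    dd = pd.read_csv(out / "driver_days.csv", dtype={"taxi_id": str})
    xcfg = cfg.exposure_config()
    from .exposure import DriverDay  # lightweight reconstruction
    driver_days = [DriverDay(r.taxi_id, pd.Timestamp(r.date).date(),
                             r.day_type, r.daily_twa,
                             r.total_occupied_hours, r.n_trips)
                   for r in dd.itertuples(index=False)]
    eligible = filter_eligible_drivers(driver_days,
                                       min_weekdays=xcfg.min_weekdays,
                                       min_weekend_days=xcfg.min_weekend_days)
    if not eligible:
        raise DataError("no eligible drivers for hotspot analysis; "
                        "lower min_weekdays/min_weekend_days")
    means = {t: m for t, m in driver_mean_twa(driver_days).items()
             if t in set(eligible)}
    high, low = select_extreme_drivers(means, xcfg.extreme_fraction)
    present = {day_type_of(t.time_start) for t in trips}
    day_types = [d for d in ("weekday", "weekend") if d in present]
    surfaces = group_hotspots(trips, high, low, day_types=day_types,
                              cell_size=cfg.kde.get("cell_size", 0.001),
                              bandwidth=cfg.kde.get("bandwidth", 0.005))
    stats = {"n_eligible": len(eligible), "high_ids": high, "low_ids": low}
    for (gname, dt), surf in surfaces.items():
        write_annual_grid(surf.to_grid(), out / f"kde_{gname}_{dt}.asc")
        mean_km, med_km, n = trip_distance_stats(
            trips, high if gname == "high" else low, dt)
        stats[f"{gname}_{dt}"] = {
            "mean_trip_km": mean_km, "median_trip_km": med_km, "n_trips": n,
            "kde_mass": surf.mass(),
            "argmax_lonlat": list(surf.argmax_lonlat())}
    _write_json(stats, out / "hotspot_stats.json")
    manifest["hotspots"] = {"n_eligible": len(eligible),
                            "n_high": len(high), "n_low": len(low)}


def run_pipeline(config: PipelineConfig,
                 stages: Optional[Sequence[str]] = None) -> dict:
    """Run the requested stages (all by default) and return the manifest."""
    if stages is None:
        stages = ALL_STAGES if config.simulate else ALL_STAGES[1:]
    bad = set(stages) - set(ALL_STAGES)
    if bad:
        raise ConfigError(f"unknown stage(s): {sorted(bad)}")
    stages = [s for s in ALL_STAGES if s in set(stages)]
    # validate inputs before any compute
    if "simulate" not in stages:
        for key, name in (("raster", "annual.asc"), ("stations", "stations.csv")):
            p = config.path(key, name)
            if not p.exists():
                raise ConfigError(f"input path for {key!r} does not exist: {p}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": list(stages)}
    runners = {"simulate": _stage_simulate, "preprocess": _stage_preprocess,
               "field": _stage_field, "exposure": _stage_exposure,
               "hotspots": _stage_hotspots}
    for stage in stages:
        if stage == "report":
            continue
        logger.info("stage %s ...", stage)
        try:
            runners[stage](config, out, manifest)
        except Exception as exc:
            raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
    _write_json(manifest, out / "manifest.json")
    return manifest
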