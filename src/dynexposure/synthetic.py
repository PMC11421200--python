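"""Synthetic study scenario: annual raster, station series, road network,
and taxi trajectories with ground truth.

The generator emulates the statistical structure the analysis assumes: a
smooth annual surface with urban hotspots over a ~0.5 deg x 0.5 deg extent,
nine stations sharing a diurnal cycle and a multi-day pollution episode
peaking near 300 ug/m3, and a fleet of taxis alternating vacant/occupied
runs along shortest network paths, emitting GPS fixes with isotropic
Gaussian noise.  Everything is deterministic under the scenario seed, and
the ground truth (exact continuous paths, traversed edges, and per-trip
exposure) is retained so the pipeline's recovery can be measured.

Desk-scale defaults (50 taxis, 7 days, 10-s sampling) keep tests in the
minutes range; the study-scale shape (19 days, thousands of taxis) is a
configuration away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .geo import bearing_deg, haversine_m, meters_to_deg
from .io_formats import AnnualGrid, RoadNetwork, StationSeries

__all__ = [
    "Hotspot", "EpisodeSpec", "ScenarioConfig", "GroundTruth", "TrueTrip",
    "gen_annual_grid", "gen_station_series", "gen_road_network",
    "gen_trajectories",
]

#: diurnal multipliers (24 hourly factors, mean ~1): night/early-morning and
#: morning-rush peaks, early-afternoon trough
DEFAULT_DIURNAL = (
    1.10, 1.08, 1.12, 1.18, 1.16, 1.08, 1.04, 1.06, 1.10, 1.14,
    1.00, 0.84, 0.80, 0.84, 0.88, 0.90, 0.94, 1.00, 1.04, 1.02,
    1.00, 1.02, 1.04, 1.08,
)


@dataclass(frozen=True)
class Hotspot:
    """Gaussian bump added to the annual background surface."""

    lon: float
    lat: float
    amplitude: float  # ug/m3 at the bump center
    sigma_deg: float  # spatial scale of the bump


@dataclass(frozen=True)
class EpisodeSpec:
    """Multi-day pollution episode shared by all stations."""

    start_day: int  # 0-based day offset into the scenario
    duration_days: float
    peak: float  # target peak concentration, ug/m3


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of the synthetic scenario.

    The same seed always yields byte-identical outputs.
    """

    extent: tuple = (114.0, 30.3, 114.5, 30.8)  # lon_min, lat_min, lon_max, lat_max
    cell_size: float = 0.01
    background: float = 45.5
    hotspots: tuple = (
        Hotspot(114.30, 30.60, 30.0, 0.05),
        Hotspot(114.12, 30.40, 20.0, 0.06),
    )
    station_locations: tuple = (
        ("ST01", 114.08, 30.38), ("ST02", 114.25, 30.37), ("ST03", 114.42, 30.39),
        ("ST04", 114.10, 30.55), ("ST05", 114.28, 30.57), ("ST06", 114.44, 30.54),
        ("ST07", 114.07, 30.72), ("ST08", 114.26, 30.74), ("ST09", 114.43, 30.71),
    )
    start: str = "2014-05-13"  # local midnight of day 0
    n_days: int = 7
    n_taxis: int = 50
    sampling_interval_s: float = 10.0
    gps_noise_sigma_m: float = 10.0
    speed_kmh: float = 30.0
    mean_occupied_min: float = 10.0
    mean_vacant_min: float = 5.0
    diurnal: tuple = DEFAULT_DIURNAL
    episode: Optional[EpisodeSpec] = EpisodeSpec(start_day=3, duration_days=3,
                                                 peak=300.0)
    station_noise_sigma: float = 5.0
    network_kind: str = "grid"
    network_spacing_deg: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxis < 1 or self.n_days < 1:
            raise ConfigError("n_taxis and n_days must be >= 1")
        if self.gps_noise_sigma_m < 0:
            raise ConfigError("gps_noise_sigma_m must be >= 0")
        if self.speed_kmh <= 0:
            raise ConfigError("speed_kmh must be > 0")
        if len(self.diurnal) != 24:
            raise ConfigError("diurnal profile needs 24 multipliers")
        if self.network_kind not in {"grid", "radial"}:
            raise ConfigError(f"unknown network kind {self.network_kind!r}")

    @property
    def start_time(self) -> np.datetime64:
        return np.datetime64(self.start, "s")

    @property
    def n_hours(self) -> int:
        return self.n_days * 24

    def with_(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Annual raster
# ---------------------------------------------------------------------------

def gen_annual_grid(config: ScenarioConfig) -> AnnualGrid:
    """Smooth annual surface: constant background plus Gaussian hotspots."""
    lon_min, lat_min, lon_max, lat_max = config.extent
    s = config.cell_size
    n_cols = int(round((lon_max - lon_min) / s))
    n_rows = int(round((lat_max - lat_min) / s))
    if n_cols < 1 or n_rows < 1:
        raise ConfigError("extent too small for the cell size")
    lon_c = lon_min + (np.arange(n_cols) + 0.5) * s
    lat_c = lat_min + (np.arange(n_rows) + 0.5) * s
    LON, LAT = np.meshgrid(lon_c, lat_c)
    values = np.full((n_rows, n_cols), float(config.background))
    for h in config.hotspots:
        if not (lon_min <= h.lon <= lon_max and lat_min <= h.lat <= lat_max):
            raise ConfigError(f"hotspot at ({h.lon}, {h.lat}) outside extent")
        r2 = (LON - h.lon) ** 2 + (LAT - h.lat) ** 2
        values += h.amplitude * np.exp(-r2 / (2.0 * h.sigma_deg ** 2))
    if values.min() <= 0:
        raise ConfigError("annual surface not strictly positive")
    return AnnualGrid(lon_min, lat_min, s, values)


# ---------------------------------------------------------------------------
# Station series
# ---------------------------------------------------------------------------

def _episode_multiplier(config: ScenarioConfig, grid: AnnualGrid) -> np.ndarray:
    """Hourly episode multiplier shared by all stations (1 outside)."""
    mult = np.ones(config.n_hours)
    ep = config.episode
    if ep is None:
        return mult
    # scale so the most polluted station peaks near ep.peak
    annual_at = [float(grid.value_at(lon, lat))
                 for _, lon, lat in config.station_locations]
    ref = max(annual_at) * max(config.diurnal)
    peak_mult = max(ep.peak / ref, 1.0)
    h = np.arange(config.n_hours)
    h0 = ep.start_day * 24.0
    dur = ep.duration_days * 24.0
    inside = (h >= h0) & (h < h0 + dur)
    phase = (h[inside] - h0) / dur
    mult[inside] = 1.0 + (peak_mult - 1.0) * np.sin(np.pi * phase) ** 2
    return mult


def gen_station_series(config: ScenarioConfig, grid: AnnualGrid,
                       station_locations: Optional[Sequence] = None
                       ) -> list[StationSeries]:
    """Hourly series per station: annual x diurnal x episode + noise.

    All stations share the diurnal and episode signal (their series are
    perfectly correlated at zero noise); values are clipped at 0.
    """
    locs = station_locations or config.station_locations
    for sid, lon, lat in locs:
        if not np.all(grid.contains(lon, lat)):
            raise ConfigError(f"station {sid} at ({lon}, {lat}) outside grid")
    cfg = config if station_locations is None else config.with_(
        station_locations=tuple(station_locations))
    episode = _episode_multiplier(cfg, grid)
    hours = np.arange(cfg.n_hours)
    diurnal = np.asarray(cfg.diurnal)[hours % 24]
    timestamps = (cfg.start_time
                  + (hours * 3600).astype("timedelta64[s]"))
    rng = np.random.default_rng([cfg.seed, 1])
    out = []
    for sid, lon, lat in locs:
        annual = float(grid.value_at(lon, lat))
        series = annual * diurnal * episode
        if cfg.station_noise_sigma > 0:
            series = series + rng.normal(0.0, cfg.station_noise_sigma,
                                         size=cfg.n_hours)
        series = np.clip(series, 0.0, None)
        out.append(StationSeries(sid, lon, lat, timestamps, series))
    return out


# ---------------------------------------------------------------------------
# Road network
# ---------------------------------------------------------------------------

def gen_road_network(config: ScenarioConfig) -> RoadNetwork:
    """Connected planar network over the extent (grid lattice or radial)."""
    if config.network_kind == "grid":
        return _lattice_network(config)
    return _radial_network(config)


def _lattice_network(config: ScenarioConfig) -> RoadNetwork:
    lon_min, lat_min, lon_max, lat_max = config.extent
    sp = config.network_spacing_deg
    nx = int(math.floor((lon_max - lon_min) / sp + 1e-9)) + 1
    ny = int(math.floor((lat_max - lat_min) / sp + 1e-9)) + 1
    if nx < 2 or ny < 2:
        raise ConfigError("extent too small for the network spacing")
    lon = lon_min + sp * np.arange(nx)
    lat = lat_min + sp * np.arange(ny)
    LON, LAT = np.meshgrid(lon, lat)  # index [j, i] -> node j*nx + i
    node_lon, node_lat = LON.ravel(), LAT.ravel()
    eu, ev = [], []
    for j in range(ny):
        for i in range(nx - 1):
            eu.append(j * nx + i)
            ev.append(j * nx + i + 1)
    for j in range(ny - 1):
        for i in range(nx):
            eu.append(j * nx + i)
            ev.append((j + 1) * nx + i)
    eu = np.array(eu)
    ev = np.array(ev)
    coords = [np.array([[node_lon[u], node_lat[u]], [node_lon[v], node_lat[v]]])
              for u, v in zip(eu, ev)]
    lengths = haversine_m(node_lon[eu], node_lat[eu], node_lon[ev], node_lat[ev])
    return RoadNetwork(node_lon, node_lat, eu, ev, coords, lengths)


def _radial_network(config: ScenarioConfig, n_spokes: int = 8,
                    n_rings: int = 4) -> RoadNetwork:
    lon_min, lat_min, lon_max, lat_max = config.extent
    cx, cy = (lon_min + lon_max) / 2.0, (lat_min + lat_max) / 2.0
    r_max = min(lon_max - lon_min, lat_max - lat_min) / 2.0 * 0.95
    radii = r_max * (np.arange(1, n_rings + 1) / n_rings)
    angles = 2.0 * np.pi * np.arange(n_spokes) / n_spokes
    node_lon = [cx]
    node_lat = [cy]
    idx = {}
    for ri, r in enumerate(radii):
        for ai, a in enumerate(angles):
            idx[(ri, ai)] = len(node_lon)
            node_lon.append(cx + r * np.cos(a))
            node_lat.append(cy + r * np.sin(a))
    eu, ev = [], []
    for ai in range(n_spokes):
        eu.append(0)
        ev.append(idx[(0, ai)])
        for ri in range(n_rings - 1):
            eu.append(idx[(ri, ai)])
            ev.append(idx[(ri + 1, ai)])
    for ri in range(n_rings):
        for ai in range(n_spokes):
            eu.append(idx[(ri, ai)])
            ev.append(idx[(ri, (ai + 1) % n_spokes)])
    node_lon = np.array(node_lon)
    node_lat = np.array(node_lat)
    eu = np.array(eu)
    ev = np.array(ev)
    coords = [np.array([[node_lon[u], node_lat[u]], [node_lon[v], node_lat[v]]])
              for u, v in zip(eu, ev)]
    lengths = haversine_m(node_lon[eu], node_lat[eu], node_lon[ev], node_lat[ev])
    return RoadNetwork(node_lon, node_lat, eu, ev, coords, lengths)


# ---------------------------------------------------------------------------
# Trajectories + ground truth
# ---------------------------------------------------------------------------

@dataclass
class TrueTrip:
    """Ground-truth occupied run: exact window, traversed edges, exposure."""

    taxi_id: str
    t_start: np.datetime64
    t_end: np.datetime64
    edge_ids: list
    ei: float  # ug.h/m3, same lambda as the pipeline under test
    twa: float  # ug/m3


@dataclass
class _TaxiPath:
    """Exact continuous motion of one taxi: piecewise-linear in lon/lat."""

    t_s: np.ndarray  # seconds since scenario start, at polyline vertices
    lon: np.ndarray
    lat: np.ndarray
    edge_id: np.ndarray  # edge of the segment starting at each vertex
    flips_s: np.ndarray  # status change times (s); status before first flip
    first_occupied: bool

    def position(self, t_s) -> tuple[np.ndarray, np.ndarray]:
        t_s = np.asarray(t_s, dtype=float)
        return (np.interp(t_s, self.t_s, self.lon),
                np.interp(t_s, self.t_s, self.lat))

    def occupied(self, t_s) -> np.ndarray:
        k = np.searchsorted(self.flips_s, np.asarray(t_s, dtype=float),
                            side="right")
        return (k % 2 == 0) == self.first_occupied

    def edge_at(self, t_s) -> np.ndarray:
        k = np.searchsorted(self.t_s, np.asarray(t_s, dtype=float),
                            side="right") - 1
        k = np.clip(k, 0, self.edge_id.size - 1)
        return self.edge_id[k]


@dataclass
class GroundTruth:
    """Oracle data for recovery tests.

    Holds the exact 1-s-resolvable continuous path per taxi (stored as its
    piecewise-linear vertex representation), the true occupied runs with
    traversed edge sequences, and per-trip exposure integrated against the
    true field at small time steps with the same lambda as the pipeline.
    """

    start_time: np.datetime64
    paths: dict = field(default_factory=dict)  # taxi_id -> _TaxiPath
    trips: list = field(default_factory=list)  # list[TrueTrip]
    lam: float = 1.0

    def _rel_s(self, t) -> float:
        return float((np.datetime64(t, "s") - self.start_time)
                     .astype("timedelta64[s]").astype(float))

    def sample_path(self, taxi_id: str, t0, t1, step_s: float = 1.0):
        """True positions of a taxi sampled every ``step_s`` in [t0, t1]."""
        path = self.paths[taxi_id]
        a, b = self._rel_s(t0), self._rel_s(t1)
        ts = np.arange(a, b + step_s / 2.0, step_s)
        lon, lat = path.position(ts)
        return ts, lon, lat

    def true_exposure(self, taxi_id: str, t0, t1, concentration_field,
                      lam: Optional[float] = None,
                      step_s: Optional[float] = None) -> tuple[float, float]:
        """(EI, TWA) of the true path over [t0, t1] against the true field.

        With ``step_s=None`` (default) the piecewise-constant field is
        integrated exactly along the piecewise-linear path (splitting at
        every cell and hour boundary crossing).  A float ``step_s`` uses a
        midpoint Riemann sum at that step instead, which probes the
        convergence of plain time-step quadrature.  EI in ug.h/m3, TWA in
        ug/m3.
        """
        lam = self.lam if lam is None else lam
        path = self.paths[taxi_id]
        a, b = self._rel_s(t0), self._rel_s(t1)
        if b <= a:
            raise ConfigError("true_exposure needs t1 > t0")
        if step_s is None:
            integral_h = self._exact_integral(path, a, b, concentration_field)
        else:
            n = max(int(round((b - a) / step_s)), 1)
            h = (b - a) / n
            mids = a + (np.arange(n) + 0.5) * h
            lon, lat = path.position(mids)
            conc = self._field_values(concentration_field, lon, lat, mids)
            integral_h = float(np.sum(conc)) * (h / 3600.0)
        ei = lam * integral_h
        twa = ei / (lam * (b - a) / 3600.0)
        return ei, twa

    def _exact_integral(self, path: "_TaxiPath", a: float, b: float,
                        concentration_field) -> float:
        """Exact integral (ug.h/m3 per unit lambda) of the step field along
        the linear-in-time path segments, cut at cell/hour crossings."""
        grid = concentration_field.annual_grid
        s = grid.cell_size
        i0 = int(np.searchsorted(path.t_s, a, side="right"))
        i1 = int(np.searchsorted(path.t_s, b, side="left"))
        knots = np.concatenate([[a], path.t_s[i0:i1], [b]])
        lon_k, lat_k = path.position(knots)
        total = 0.0
        for k in range(knots.size - 1):
            t0k, t1k = float(knots[k]), float(knots[k + 1])
            if t1k <= t0k:
                continue
            xa, ya = float(lon_k[k]), float(lat_k[k])
            xb, yb = float(lon_k[k + 1]), float(lat_k[k + 1])
            cuts = [t0k, t1k]
            for p0, p1 in (((xa - grid.origin_lon) / s, (xb - grid.origin_lon) / s),
                           ((ya - grid.origin_lat) / s, (yb - grid.origin_lat) / s)):
                if p1 != p0:
                    lo, hi = (p0, p1) if p0 < p1 else (p1, p0)
                    for bound in range(math.floor(lo) + 1, math.floor(hi) + 1):
                        frac = (bound - p0) / (p1 - p0)
                        if 0.0 < frac < 1.0:
                            cuts.append(t0k + frac * (t1k - t0k))
            off0 = float((self.start_time - concentration_field.time_start)
                         .astype("timedelta64[s]").astype(float))
            for hb in range(math.floor((off0 + t0k) / 3600.0) + 1,
                            math.floor((off0 + t1k) / 3600.0) + 1):
                th = hb * 3600.0 - off0
                if t0k < th < t1k:
                    cuts.append(th)
            cuts = sorted(set(cuts))
            mids = (np.asarray(cuts[:-1]) + np.asarray(cuts[1:])) / 2.0
            u = (mids - t0k) / (t1k - t0k)
            conc = self._field_values(concentration_field,
                                      xa + u * (xb - xa), ya + u * (yb - ya),
                                      mids)
            total += float(np.sum(conc * np.diff(cuts))) / 3600.0
        return total

    def _field_values(self, concentration_field, lon, lat, rel_mid_s):
        """Fused field at exact float-second instants (no rounding to
        whole seconds, which would bias samples near hour boundaries)."""
        annual = concentration_field.annual_grid.value_at(lon, lat)
        off0 = float((self.start_time - concentration_field.time_start)
                     .astype("timedelta64[s]").astype(float))
        idx = np.floor((off0 + np.asarray(rel_mid_s)) / 3600.0).astype(np.int64)
        if idx.min() < 0 or idx.max() >= concentration_field._hourly.size:
            raise ConfigError("true path extends beyond the station series")
        fused = (concentration_field._hourly[idx]
                 + (annual - concentration_field.base_annual_value))
        if concentration_field.clamp_negative:
            fused = np.maximum(fused, 0.0)
        return fused

    def true_edges_between(self, taxi_id: str, t0, t1) -> list:
        """Deduplicated traversed edge sequence within [t0, t1]."""
        path = self.paths[taxi_id]
        a, b = self._rel_s(t0), self._rel_s(t1)
        i0 = max(int(np.searchsorted(path.t_s, a, side="right")) - 1, 0)
        i1 = max(int(np.searchsorted(path.t_s, b, side="left")) - 1, i0)
        seq = []
        for e in path.edge_id[i0:i1 + 1]:
            if not seq or seq[-1] != e:
                seq.append(int(e))
        return seq


def _simulate_taxi(config: ScenarioConfig, network: RoadNetwork,
                   rng: np.random.Generator) -> _TaxiPath:
    """Drive one taxi for the whole scenario.

    The taxi always moves at constant speed along shortest paths to random
    destination nodes; passenger status flips at exponentially distributed
    times (continuous analog of geometric run lengths) independent of the
    route, so flips can occur mid-edge.
    """
    total_s = config.n_days * 86400.0
    speed = config.speed_kmh / 3.6  # m/s
    node = int(rng.integers(network.n_nodes))
    t_v = [0.0]
    lon_v = [float(network.node_lon[node])]
    lat_v = [float(network.node_lat[node])]
    edge_v: list[int] = []
    t = 0.0
    while t < total_s:
        dest = int(rng.integers(network.n_nodes))
        if dest == node:
            continue
        path = network.shortest_node_path(node, dest)
        for a, b in zip(path[:-1], path[1:]):
            eid = network.edge_between(a, b)
            dt = float(network.edge_length_m[eid]) / speed
            t += dt
            t_v.append(t)
            lon_v.append(float(network.node_lon[b]))
            lat_v.append(float(network.node_lat[b]))
            edge_v.append(eid)
            if t >= total_s:
                break
        node = dest if t < total_s else node
    # status flips, independent of routing
    first_occupied = bool(rng.integers(2))
    flips = []
    tau = 0.0
    occupied = first_occupied
    while True:
        mean_s = (config.mean_occupied_min if occupied
                  else config.mean_vacant_min) * 60.0
        tau += float(rng.exponential(mean_s))
        if tau >= total_s:
            break
        flips.append(tau)
        occupied = not occupied
    return _TaxiPath(
        t_s=np.array(t_v), lon=np.array(lon_v), lat=np.array(lat_v),
        edge_id=np.array(edge_v + [edge_v[-1] if edge_v else 0]),
        flips_s=np.array(flips), first_occupied=first_occupied,
    )


def gen_trajectories(config: ScenarioConfig, network: RoadNetwork,
                     concentration_field=None, lam: float = 1.0,
                     ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the fleet; returns (fix table, ground truth).

    The fix table has the canonical columns (taxi_id, timestamp, lon, lat,
    heading, occupied); fixes are the true positions plus isotropic
    Gaussian noise of ``gps_noise_sigma_m``.  When ``concentration_field``
    is given, per-trip true exposure is precomputed with coefficient
    ``lam``.
    """
    if not network.is_connected():
        raise ConfigError("road network must be connected")
    gt = GroundTruth(start_time=config.start_time, lam=lam)
    frames = []
    total_s = config.n_days * 86400.0
    n_width = max(3, len(str(config.n_taxis)))
    for k in range(config.n_taxis):
        taxi_id = f"T{k:0{n_width}d}"
        rng = np.random.default_rng([config.seed, 2, k])
        path = _simulate_taxi(config, network, rng)
        gt.paths[taxi_id] = path
        ts = np.arange(0.0, total_s, config.sampling_interval_s)
        lon, lat = path.position(ts)
        occ = path.occupied(ts)
        heading = np.zeros(ts.size)
        if ts.size > 1:
            heading[:-1] = bearing_deg(lon[:-1], lat[:-1], lon[1:], lat[1:])
            heading[-1] = heading[-2]
        if config.gps_noise_sigma_m > 0:
            dx = rng.normal(0.0, config.gps_noise_sigma_m, ts.size)
            dy = rng.normal(0.0, config.gps_noise_sigma_m, ts.size)
            dlon, dlat = meters_to_deg(dx, dy, lat)
            lon = lon + dlon
            lat = lat + dlat
        stamps = (config.start_time
                  + np.round(ts).astype(np.int64).astype("timedelta64[s]"))
        frames.append(pd.DataFrame({
            "taxi_id": taxi_id,
            "timestamp": pd.to_datetime(stamps),
            "lon": lon, "lat": lat,
            "heading": heading, "occupied": occ,
        }))
        # ground-truth occupied runs
        bounds = np.concatenate([[0.0], path.flips_s, [total_s]])
        occupied = path.first_occupied
        for a, b in zip(bounds[:-1], bounds[1:]):
            if occupied:
                t0 = config.start_time + np.timedelta64(int(round(a)), "s")
                t1 = config.start_time + np.timedelta64(int(round(b)), "s")
                edges = gt.true_edges_between(taxi_id, t0, t1)
                ei = twa = float("nan")
                if concentration_field is not None and b - a >= 1.0:
                    ei, twa = gt.true_exposure(taxi_id, t0, t1,
                                               concentration_field, lam=lam)
                gt.trips.append(TrueTrip(taxi_id, t0, t1, edges, ei, twa))
            occupied = not occupied
    fixes = pd.concat(frames, ignore_index=True)
    return fixes, gt
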