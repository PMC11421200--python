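"""Readers and writers for every external format the pipeline touches.

Rasters come and go as ESRI ASCII grids or GeoTIFFs (geographic CRS only),
station series and GPS fixes as CSV, road networks and matched trips as
GeoJSON.  Readers validate and never silently drop data: rejected rows are
counted and logged through the module logger.

Grid georeferencing convention: cell (row r, col c) covers the half-open
box [origin_lon + c*s, origin_lon + (c+1)*s) x [origin_lat + r*s,
origin_lat + (r+1)*s), rows increasing northward; ``origin_lon/lat`` is the
lower-left corner of cell (0, 0).  Timestamps are naive local datetimes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AmbiguityError, DataError, FormatError, UnsupportedCRSError
from .geo import polyline_length_m

logger = logging.getLogger(__name__)

FIX_COLUMNS = ["taxi_id", "timestamp", "lon", "lat", "heading", "occupied"]

# GeoTIFF / GDAL tag codes used for georeferencing
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113
_GT_MODEL_TYPE_GEO_KEY = 1024
_MODEL_TYPE_GEOGRAPHIC = 2


# ---------------------------------------------------------------------------
# Annual concentration raster
# ---------------------------------------------------------------------------

@dataclass
class AnnualGrid:
    """Static annual-mean concentration raster on a regular lon/lat grid.

    ``values`` is an (n_rows, n_cols) float array with row 0 the *southern*
    most row; missing cells are ``nan`` internally and written out with the
    ``nodata`` marker.
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("grid values must be a 2-D array")
        if not self.cell_size > 0:
            raise DataError("cell_size must be positive")
        valid = self.values[np.isfinite(self.values)]
        if valid.size and valid.min() < 0:
            raise DataError("annual grid contains negative concentrations")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def lon_max(self) -> float:
        return self.origin_lon + self.n_cols * self.cell_size

    @property
    def lat_max(self) -> float:
        return self.origin_lat + self.n_rows * self.cell_size

    def contains(self, lon, lat):
        """Point-in-grid test; the outer upper boundary is included (points
        exactly on it belong to the outermost cell), interior cell
        assignment stays half-open."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return ((lon >= self.origin_lon) & (lon <= self.lon_max)
                & (lat >= self.origin_lat) & (lat <= self.lat_max))

    def cell_of(self, lon, lat):
        """Vectorized (row, col) of the cell containing each point.

        Points outside the grid raise; assignment follows the half-open
        box convention.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        inside = self.contains(lon, lat)
        if not np.all(inside):
            bad = np.argwhere(~np.atleast_1d(inside))
            raise DataError(f"{bad.shape[0]} point(s) outside the grid extent")
        col = np.floor((lon - self.origin_lon) / self.cell_size).astype(np.int64)
        row = np.floor((lat - self.origin_lat) / self.cell_size).astype(np.int64)
        # guard against floating point landing exactly on the upper edge
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        return row, col

    def value_at(self, lon, lat):
        """Annual concentration of the cell containing each point."""
        row, col = self.cell_of(lon, lat)
        return self.values[row, col]

    def cell_center(self, row, col):
        lon = self.origin_lon + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.origin_lat + (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def mean(self) -> float:
        """Mean over valid (non-nodata) cells."""
        return float(np.nanmean(self.values))


def read_annual_grid(path) -> AnnualGrid:
    """Read a raster as :class:`AnnualGrid` from ESRI ASCII or GeoTIFF."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return _read_geotiff(path)
    return _read_ascii_grid(path)


def write_annual_grid(grid: AnnualGrid, path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        _write_geotiff(grid, path)
    else:
        _write_ascii_grid(grid, path)


def _read_ascii_grid(path: Path) -> AnnualGrid:
    header: dict[str, float] = {}
    data_lines = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        }:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}: bad header line {i + 1}: {line!r}") from exc
        else:
            data_lines = lines[i:]
            break
    required = {"ncols", "nrows", "cellsize"}
    if not required.issubset(header):
        raise FormatError(f"{path}: ESRI ASCII header missing {required - set(header)}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        x0 = header["xllcorner"]
    elif "xllcenter" in header:
        x0 = header["xllcenter"] - cell / 2.0
    else:
        raise FormatError(f"{path}: missing xllcorner/xllcenter")
    if "yllcorner" in header:
        y0 = header["yllcorner"]
    elif "yllcenter" in header:
        y0 = header["yllcenter"] - cell / 2.0
    else:
        raise FormatError(f"{path}: missing yllcorner/yllcenter")
    nodata = header.get("nodata_value", -9999.0)
    try:
        flat = np.array(" ".join(data_lines).split(), dtype=float)
        values = flat.reshape(nrows, ncols)
    except ValueError as exc:
        raise FormatError(f"{path}: expected {nrows}x{ncols} data values") from exc
    values = np.flipud(values)  # file rows run north->south
    values = np.where(values == nodata, np.nan, values)
    return AnnualGrid(x0, y0, cell, values, nodata=nodata)


def _write_ascii_grid(grid: AnnualGrid, path: Path) -> None:
    values = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_lon!r}\n")
        fh.write(f"yllcorner {grid.origin_lat!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in np.flipud(values):
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def _read_geotiff(path: Path) -> AnnualGrid:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        tags = {t.code: t.value for t in page.tags.values()}
        if _TAG_GEO_KEY_DIRECTORY in tags:
            keys = np.asarray(tags[_TAG_GEO_KEY_DIRECTORY]).ravel()
            # entries of 4 shorts: (key, location, count, value)
            for k in range(4, len(keys) - 3, 4):
                if keys[k] == _GT_MODEL_TYPE_GEO_KEY and keys[k + 1] == 0:
                    if keys[k + 3] != _MODEL_TYPE_GEOGRAPHIC:
                        raise UnsupportedCRSError(
                            f"{path}: projected CRS not supported (degrees only)")
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise FormatError(f"{path}: GeoTIFF lacks georeferencing tags")
        scale = np.asarray(tags[_TAG_MODEL_PIXEL_SCALE], dtype=float)
        tie = np.asarray(tags[_TAG_MODEL_TIEPOINT], dtype=float)
        values = page.asarray().astype(float)
    if values.ndim != 2:
        raise FormatError(f"{path}: expected a single-band raster")
    sx, sy = float(scale[0]), float(scale[1])
    if not np.isclose(sx, sy, rtol=1e-9):
        raise FormatError(f"{path}: anisotropic pixels not supported")
    # tiepoint maps raster (0,0) = top-left corner to model space
    top_left_lon = float(tie[3] - tie[0] * sx)
    top_lat = float(tie[4] + tie[1] * sy)
    nrows = values.shape[0]
    origin_lat = top_lat - nrows * sy
    nodata = -9999.0
    if _TAG_GDAL_NODATA in tags:
        try:
            nodata = float(str(tags[_TAG_GDAL_NODATA]).strip("\x00 "))
        except ValueError:
            pass
    values = np.flipud(values)
    values = np.where(values == nodata, np.nan, values)
    return AnnualGrid(top_left_lon, origin_lat, sx, values, nodata=nodata)


def _write_geotiff(grid: AnnualGrid, path: Path) -> None:
    import tifffile

    values = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
    data = np.flipud(values)
    s = grid.cell_size
    tiepoint = (0.0, 0.0, 0.0, grid.origin_lon, grid.lat_max, 0.0)
    # minimal geographic-WGS84 key directory
    geokeys = (1, 1, 0, 2,
               _GT_MODEL_TYPE_GEO_KEY, 0, 1, _MODEL_TYPE_GEOGRAPHIC,
               2048, 0, 1, 4326)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (s, s, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, tiepoint),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_TAG_GDAL_NODATA, "s", 0, repr(grid.nodata)),
    ]
    tifffile.imwrite(str(path), data, extratags=extratags)


# ---------------------------------------------------------------------------
# Hourly station series
# ---------------------------------------------------------------------------

@dataclass
class StationSeries:
    """Hourly concentration series at one monitoring station.

    ``timestamps`` are hour starts (naive local time, strictly increasing
    with 1-h spacing); missing hours carry ``nan``.
    """

    station_id: str
    lon: float
    lat: float
    timestamps: np.ndarray  # datetime64[s], hourly
    concentrations: np.ndarray  # float, nan = missing

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.timestamps.shape != self.concentrations.shape:
            raise DataError("timestamps and concentrations differ in length")
        if self.timestamps.size > 1:
            steps = np.diff(self.timestamps).astype("timedelta64[s]").astype(int)
            if not np.all(steps == 3600):
                raise DataError(
                    f"station {self.station_id}: timestamps not hourly/increasing")
        valid = self.concentrations[np.isfinite(self.concentrations)]
        if valid.size and valid.min() < 0:
            raise DataError(f"station {self.station_id}: negative concentration")

    @property
    def n_hours(self) -> int:
        return int(self.timestamps.size)


def read_station_csv(path) -> list[StationSeries]:
    """Read hourly station series from a CSV with columns
    station_id, lon, lat, timestamp, pm25.

    Timestamps not on the hour are snapped down to the hour start (warning
    logged); duplicate (station, hour) rows raise; negative pm25 raises with
    the offending row number.
    """
    df = pd.read_csv(path, dtype={"station_id": str})
    required = {"station_id", "lon", "lat", "timestamp", "pm25"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    neg = df.index[df["pm25"] < 0]
    if len(neg):
        raise DataError(f"{path}: negative pm25 at data row {neg[0] + 1}")
    ts = pd.to_datetime(df["timestamp"])
    snapped = ts.dt.floor("h")
    n_snap = int((snapped != ts).sum())
    if n_snap:
        logger.warning("%s: %d timestamps snapped down to hour start", path, n_snap)
    df = df.assign(timestamp=snapped)
    dup = df.duplicated(subset=["station_id", "timestamp"])
    if dup.any():
        row = df.index[dup][0]
        raise AmbiguityError(f"{path}: duplicate (station, hour) at data row {row + 1}")
    out = []
    for sid, grp in df.groupby("station_id", sort=True):
        grp = grp.sort_values("timestamp")
        full = pd.date_range(grp["timestamp"].iloc[0], grp["timestamp"].iloc[-1],
                             freq="h")
        series = grp.set_index("timestamp")["pm25"].reindex(full)
        out.append(StationSeries(
            station_id=str(sid),
            lon=float(grp["lon"].iloc[0]),
            lat=float(grp["lat"].iloc[0]),
            timestamps=full.values.astype("datetime64[s]"),
            concentrations=series.values.astype(float),
        ))
    return out


def write_station_csv(stations: Sequence[StationSeries], path) -> None:
    rows = []
    for st in stations:
        ok = np.isfinite(st.concentrations)
        for t, c in zip(st.timestamps[ok], st.concentrations[ok]):
            rows.append((st.station_id, st.lon, st.lat,
                         pd.Timestamp(t).isoformat(), c))
    df = pd.DataFrame(rows, columns=["station_id", "lon", "lat", "timestamp", "pm25"])
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Raw GPS fixes
# ---------------------------------------------------------------------------

@dataclass
class RawFix:
    """One GPS record: taxi id, local timestamp, position, heading, status."""

    taxi_id: str
    timestamp: datetime
    lon: float
    lat: float
    heading: float
    occupied: bool


def fixes_to_frame(fixes: Iterable[RawFix]) -> pd.DataFrame:
    """Convert RawFix records to the canonical fix table."""
    fixes = list(fixes)
    df = pd.DataFrame({
        "taxi_id": [f.taxi_id for f in fixes],
        "timestamp": pd.to_datetime([f.timestamp for f in fixes]),
        "lon": [f.lon for f in fixes],
        "lat": [f.lat for f in fixes],
        "heading": [f.heading for f in fixes],
        "occupied": [bool(f.occupied) for f in fixes],
    })
    if df.empty:
        df = pd.DataFrame(columns=FIX_COLUMNS)
    return df


def frame_to_fixes(df: pd.DataFrame) -> list[RawFix]:
    return [RawFix(str(r.taxi_id), r.timestamp.to_pydatetime(), float(r.lon),
                   float(r.lat), float(r.heading), bool(r.occupied))
            for r in df.itertuples(index=False)]


def as_fix_frame(fixes) -> pd.DataFrame:
    """Normalize a list of RawFix or a fix table to a DataFrame."""
    if isinstance(fixes, pd.DataFrame):
        return fixes
    return fixes_to_frame(fixes)


def read_trajectory_frame(path) -> pd.DataFrame:
    """Read raw fixes as a DataFrame sorted by (taxi_id, timestamp).

    Rows with unparseable timestamps are rejected (count logged).
    """
    df = pd.read_csv(path, dtype={"taxi_id": str})
    missing = set(FIX_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        return pd.DataFrame(columns=FIX_COLUMNS)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="mixed")
    bad = ts.isna()
    if bad.any():
        logger.warning("%s: %d rows rejected (unparseable timestamp)",
                       path, int(bad.sum()))
        df = df.loc[~bad]
        ts = ts.loc[~bad]
    occ = df["occupied"]
    if occ.dtype != bool:
        occ = occ.astype(str).str.strip().str.lower().isin(
            {"1", "true", "t", "yes", "occupied"})
    df = df.assign(timestamp=ts, occupied=occ.astype(bool))
    df = df.sort_values(["taxi_id", "timestamp"], kind="mergesort")
    return df.reset_index(drop=True)[FIX_COLUMNS]


def read_trajectory_csv(path) -> list[RawFix]:
    """Read raw fixes as RawFix records (record view of the fix table)."""
    return frame_to_fixes(read_trajectory_frame(path))


def write_trajectory_csv(fixes, path) -> None:
    df = as_fix_frame(fixes).copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"]).map(lambda t: t.isoformat())
    df["occupied"] = df["occupied"].astype(int)
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Road network
# ---------------------------------------------------------------------------

@dataclass
class RoadNetwork:
    """Undirected road graph with polyline edge geometries.

    Node ``i`` sits at (node_lon[i], node_lat[i]).  ``edges`` maps edge id
    -> (u, v, coords, length_m) where coords is an (k, 2) lon/lat array from
    node u to node v.  Edge lengths are validated against the geodesic
    polyline length within 0.1%.
    """

    node_lon: np.ndarray
    node_lat: np.ndarray
    edge_u: np.ndarray
    edge_v: np.ndarray
    edge_coords: list
    edge_length_m: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.node_lon = np.asarray(self.node_lon, dtype=float)
        self.node_lat = np.asarray(self.node_lat, dtype=float)
        self.edge_u = np.asarray(self.edge_u, dtype=np.int64)
        self.edge_v = np.asarray(self.edge_v, dtype=np.int64)
        self.edge_length_m = np.asarray(self.edge_length_m, dtype=float)
        n = self.n_nodes
        if self.edge_u.size and (self.edge_u.max() >= n or self.edge_v.max() >= n
                                 or self.edge_u.min() < 0 or self.edge_v.min() < 0):
            raise DataError("edge references a nonexistent node")
        for eid, coords in enumerate(self.edge_coords):
            geod = polyline_length_m(coords)
            if geod > 0 and abs(geod - self.edge_length_m[eid]) > 1e-3 * geod:
                raise DataError(
                    f"edge {eid}: stored length {self.edge_length_m[eid]:.1f} m "
                    f"deviates >0.1% from geodesic {geod:.1f} m")

    @property
    def n_nodes(self) -> int:
        return int(self.node_lon.size)

    @property
    def n_edges(self) -> int:
        return int(self.edge_u.size)

    # -- cached derived structures -----------------------------------------
    def _adjacency(self):
        from scipy.sparse import coo_matrix
        if "adj" not in self._cache:
            n = self.n_nodes
            u, v, w = self.edge_u, self.edge_v, self.edge_length_m
            adj = coo_matrix((np.concatenate([w, w]),
                              (np.concatenate([u, v]), np.concatenate([v, u]))),
                             shape=(n, n)).tocsr()
            self._cache["adj"] = adj
        return self._cache["adj"]

    def node_distances(self):
        """All-pairs shortest-path distance (m) and predecessor matrices."""
        if "dist" not in self._cache:
            from scipy.sparse.csgraph import dijkstra
            dist, pred = dijkstra(self._adjacency(), directed=False,
                                  return_predecessors=True)
            self._cache["dist"] = dist
            self._cache["pred"] = pred
        return self._cache["dist"], self._cache["pred"]

    def shortest_node_path(self, a: int, b: int) -> list[int]:
        """Node sequence of the shortest path a -> b (inclusive)."""
        dist, pred = self.node_distances()
        if not np.isfinite(dist[a, b]):
            raise DataError(f"no path between nodes {a} and {b}")
        path = [b]
        while path[-1] != a:
            path.append(int(pred[a, path[-1]]))
        return path[::-1]

    def edge_between(self, a: int, b: int) -> int:
        """Edge id joining adjacent nodes a and b."""
        if "edge_lookup" not in self._cache:
            lookup = {}
            for eid in range(self.n_edges):
                u, v = int(self.edge_u[eid]), int(self.edge_v[eid])
                lookup[(u, v)] = eid
                lookup[(v, u)] = eid
            self._cache["edge_lookup"] = lookup
        return self._cache["edge_lookup"][(a, b)]

    def edge_tree(self):
        """shapely STRtree over edge geometries plus the geometry list."""
        if "tree" not in self._cache:
            import shapely
            geoms = [shapely.LineString(c) for c in self.edge_coords]
            self._cache["geoms"] = geoms
            self._cache["tree"] = shapely.STRtree(geoms)
        return self._cache["tree"], self._cache["geoms"]

    def is_connected(self) -> bool:
        from scipy.sparse.csgraph import connected_components
        n_comp, _ = connected_components(self._adjacency(), directed=False)
        return n_comp == 1


def read_road_network_geojson(path) -> RoadNetwork:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    node_pos: dict[int, tuple[float, float]] = {}
    records = []
    for feat in gj.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "LineString":
            continue
        props = feat.get("properties", {})
        try:
            u, v = int(props["u"]), int(props["v"])
            eid = int(props["edge_id"])
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: edge feature lacks edge_id/u/v") from exc
        coords = np.asarray(geom["coordinates"], dtype=float)
        node_pos[u] = tuple(coords[0])
        node_pos[v] = tuple(coords[-1])
        length = props.get("length_m")
        if length is None:
            length = polyline_length_m(coords)
        records.append((eid, u, v, coords, float(length)))
    if not records:
        raise FormatError(f"{path}: no LineString edges found")
    records.sort(key=lambda r: r[0])
    max_node = max(node_pos)
    lon = np.full(max_node + 1, np.nan)
    lat = np.full(max_node + 1, np.nan)
    for nid, (x, y) in node_pos.items():
        lon[nid], lat[nid] = x, y
    return RoadNetwork(
        node_lon=lon, node_lat=lat,
        edge_u=np.array([r[1] for r in records]),
        edge_v=np.array([r[2] for r in records]),
        edge_coords=[r[3] for r in records],
        edge_length_m=np.array([r[4] for r in records]),
    )


def write_road_network_geojson(network: RoadNetwork, path) -> None:
    features = []
    for eid in range(network.n_edges):
        coords = np.asarray(network.edge_coords[eid], dtype=float)
        features.append({
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": [[float(x), float(y)] for x, y in coords]},
            "properties": {
                "edge_id": eid,
                "u": int(network.edge_u[eid]),
                "v": int(network.edge_v[eid]),
                "length_m": float(network.edge_length_m[eid]),
            },
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# Matched trips (GeoJSON)
# ---------------------------------------------------------------------------

def write_trips_geojson(trips, path) -> None:
    """Export matched trips as LineString features.

    Per-fix times and along-path offsets are carried in the properties so a
    later stage can rebuild the space-time path without re-matching.
    """
    features = []
    for trip in trips:
        coords = np.asarray(trip.path_coords, dtype=float)
        if coords.ndim != 2 or coords.shape[0] < 2:
            coords = np.repeat(np.asarray(trip.path_coords, dtype=float
                                          ).reshape(-1, 2), 2, axis=0)[:2]
        features.append({
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": [[float(x), float(y)] for x, y in coords]},
            "properties": {
                "taxi_id": trip.taxi_id,
                "time_start": pd.Timestamp(trip.time_start).isoformat(),
                "time_end": pd.Timestamp(trip.time_end).isoformat(),
                "distance_km": float(trip.distance_km),
                "origin": [float(trip.origin[0]), float(trip.origin[1])],
                "destination": [float(trip.destination[0]),
                                float(trip.destination[1])],
                "fix_times": [pd.Timestamp(t).isoformat() for t in trip.fix_times],
                "fix_offsets_m": [float(o) for o in trip.fix_offsets_m],
                "path_edge_ids": [int(e) for e in trip.path_edge_ids],
            },
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_trips_geojson(path) -> list:
    from .preprocess import Trip  # local import to avoid a cycle

    with open(path) as fh:
        gj = json.load(fh)
    trips = []
    for feat in gj.get("features", []):
        props = feat["properties"]
        coords = np.asarray(feat["geometry"]["coordinates"], dtype=float)
        fix_times = np.array([np.datetime64(t, "s") for t in props["fix_times"]])
        trips.append(Trip(
            taxi_id=str(props["taxi_id"]),
            fix_times=fix_times,
            fix_lon=np.full(fix_times.size, np.nan),
            fix_lat=np.full(fix_times.size, np.nan),
            origin=tuple(props["origin"]),
            destination=tuple(props["destination"]),
            matched=True,
            path_coords=coords,
            path_edge_ids=list(props.get("path_edge_ids", [])),
            fix_offsets_m=np.asarray(props["fix_offsets_m"], dtype=float),
            distance_km=float(props["distance_km"]),
        ))
    return trips
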