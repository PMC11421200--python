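"""Activity hotspots: kernel density surfaces over trip origins and
destinations, and trip-distance statistics per driver group.

Densities use the quartic (biweight) kernel with compact support,

    K(r) = 3 / (pi h^2) * (1 - r^2/h^2)^2   for r < h, else 0,

evaluated at cell centers on a 0.001-degree grid by default.  Each point
contributes total mass 1, so the surface integral approximates the point
count.  Distances are in degrees (no metric reprojection); the small study
extents make the anisotropy a documented caveat rather than a correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import DataError, DomainError
from .io_formats import AnnualGrid
from .preprocess import Trip

logger = logging.getLogger(__name__)


@dataclass
class DensitySurface:
    """KDE surface on a regular lon/lat grid (density per squared degree)."""

    origin_lon: float
    origin_lat: float
    cell_size: float
    values: np.ndarray  # (n_rows, n_cols), row 0 southmost
    bandwidth: float
    kernel: str = "quartic"

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def mass(self) -> float:
        """Surface integral (approximates the number of points)."""
        return float(self.values.sum() * self.cell_size ** 2)

    def argmax_cell(self) -> tuple[int, int]:
        r, c = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return int(r), int(c)

    def argmax_lonlat(self) -> tuple[float, float]:
        r, c = self.argmax_cell()
        return (self.origin_lon + (c + 0.5) * self.cell_size,
                self.origin_lat + (r + 0.5) * self.cell_size)

    def to_grid(self) -> AnnualGrid:
        """View as a raster for export through the ASCII-grid writer."""
        return AnnualGrid(self.origin_lon, self.origin_lat, self.cell_size,
                          self.values)


def kde_surface(points: np.ndarray, cell_size: float = 0.001,
                bandwidth: float = 0.005, kernel: str = "quartic",
                extent: Optional[tuple] = None) -> DensitySurface:
    """Quartic-kernel density surface over lon/lat points.

    ``points`` is (n, 2) lon/lat.  The default extent is the point
    bounding box padded by one bandwidth (so no kernel mass is cut off);
    passing ``extent`` overrides it.  Deterministic.
    """
    if kernel != "quartic":
        raise DomainError(f"unsupported kernel {kernel!r}")
    if bandwidth <= 0:
        raise DomainError("bandwidth must be > 0")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise DataError("kde_surface needs at least one point")
    if extent is None:
        pad = bandwidth + cell_size
        extent = (pts[:, 0].min() - pad, pts[:, 1].min() - pad,
                  pts[:, 0].max() + pad, pts[:, 1].max() + pad)
    lon_min, lat_min, lon_max, lat_max = extent
    n_cols = max(int(np.ceil((lon_max - lon_min) / cell_size)), 1)
    n_rows = max(int(np.ceil((lat_max - lat_min) / cell_size)), 1)
    values = np.zeros((n_rows, n_cols))
    half = int(np.ceil(bandwidth / cell_size)) + 1
    norm = 3.0 / (np.pi * bandwidth ** 2)
    inv_h2 = 1.0 / bandwidth ** 2
    for x, y in pts:
        ci = int(np.floor((x - lon_min) / cell_size))
        ri = int(np.floor((y - lat_min) / cell_size))
        c0, c1 = max(ci - half, 0), min(ci + half + 1, n_cols)
        r0, r1 = max(ri - half, 0), min(ri + half + 1, n_rows)
        if c0 >= c1 or r0 >= r1:
            continue
        cx = lon_min + (np.arange(c0, c1) + 0.5) * cell_size
        cy = lat_min + (np.arange(r0, r1) + 0.5) * cell_size
        r2 = ((cx[None, :] - x) ** 2 + (cy[:, None] - y) ** 2) * inv_h2
        k = np.where(r2 < 1.0, norm * (1.0 - r2) ** 2, 0.0)
        values[r0:r1, c0:c1] += k
    return DensitySurface(lon_min, lat_min, cell_size, values, bandwidth,
                          kernel)


def _day_type_of_trip(trip: Trip) -> str:
    from .exposure import day_type_of
    return day_type_of(trip.time_start)


def group_hotspots(trips: Sequence[Trip], high_ids: Sequence[str],
                   low_ids: Sequence[str],
                   day_types: Sequence[str] = ("weekday", "weekend"),
                   cell_size: float = 0.001, bandwidth: float = 0.005,
                   ) -> dict:
    """KDE surfaces of trip origins+destinations for the high- and
    low-exposure driver groups, per day type.

    Returns {(group, day_type): DensitySurface} for group in
    {"high", "low"}.  Each surface uses only its own group's points, so
    the groups' surfaces are independent.  Raises naming the group when a
    selection is empty.
    """
    groups = {"high": set(map(str, high_ids)), "low": set(map(str, low_ids))}
    out = {}
    for gname, ids in groups.items():
        for dt in day_types:
            pts = []
            for trip in trips:
                if trip.taxi_id in ids and _day_type_of_trip(trip) == dt:
                    pts.append(trip.origin)
                    pts.append(trip.destination)
            if not pts:
                raise DataError(
                    f"no trips for group {gname!r} on {dt}s; cannot build KDE")
            out[(gname, dt)] = kde_surface(np.asarray(pts), cell_size,
                                           bandwidth)
    return out


def trip_distance_stats(trips: Sequence[Trip],
                        group_ids: Optional[Sequence[str]] = None,
                        day_type: Optional[str] = None
                        ) -> tuple[float, float, int]:
    """(mean km, median km, n) of matched trip distances for a selection."""
    ids = set(map(str, group_ids)) if group_ids is not None else None
    dist = [t.distance_km for t in trips
            if (ids is None or t.taxi_id in ids)
            and (day_type is None or _day_type_of_trip(t) == day_type)]
    if not dist:
        raise DataError("no trips match the requested group/day type")
    arr = np.asarray(dist)
    return float(arr.mean()), float(np.median(arr)), int(arr.size)
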