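"""Geodesic helpers on the WGS84 sphere.

All distances use the haversine formula with a fixed mean Earth radius
R = 6371.0088 km so that results are exactly reproducible.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088
EARTH_RADIUS_M = EARTH_RADIUS_KM * 1000.0
#: meters per degree of latitude on the sphere above
M_PER_DEG = EARTH_RADIUS_M * np.pi / 180.0


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in meters between points in degrees.

    Accepts scalars or numpy arrays (broadcast).
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def polyline_length_m(coords: np.ndarray) -> float:
    """Geodesic length of a lon/lat polyline given as an (n, 2) array."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        return 0.0
    seg = haversine_m(coords[:-1, 0], coords[:-1, 1], coords[1:, 0], coords[1:, 1])
    return float(np.sum(seg))


def polyline_cumdist_m(coords: np.ndarray) -> np.ndarray:
    """Cumulative geodesic distance (meters) along a lon/lat polyline."""
    coords = np.asarray(coords, dtype=float)
    out = np.zeros(coords.shape[0])
    if coords.shape[0] > 1:
        seg = haversine_m(coords[:-1, 0], coords[:-1, 1], coords[1:, 0], coords[1:, 1])
        out[1:] = np.cumsum(seg)
    return out


def bearing_deg(lon1, lat1, lon2, lat2):
    """Initial bearing in degrees [0, 360) from point 1 to point 2."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.mod(np.degrees(np.arctan2(y, x)), 360.0)


def meters_to_deg(dx_m, dy_m, lat_deg):
    """Convert local east/north displacements in meters to (dlon, dlat) degrees."""
    dlat = np.asarray(dy_m, dtype=float) / M_PER_DEG
    dlon = np.asarray(dx_m, dtype=float) / (M_PER_DEG * np.cos(np.radians(lat_deg)))
    return dlon, dlat
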