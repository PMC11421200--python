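"""Trajectory preprocessing: outlier cleaning, trip extraction, and
hidden-Markov-model map matching.

A *trip* is a maximal contiguous occupied run of one taxi's fixes.  Map
matching assigns each fix to a road edge with a Viterbi pass: emission
log-probability -d^2/(2 sigma^2) from the geodesic distance d between the
fix and its projection on a candidate edge, transition log-probability
-|route - great_circle| / beta between consecutive candidates, with route
distances taken along the network.  The matched path is the concatenation
of the shortest paths through the chosen candidate points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely

from .errors import DataError
from .geo import M_PER_DEG, haversine_m
from .io_formats import FIX_COLUMNS, RoadNetwork, as_fix_frame, frame_to_fixes

logger = logging.getLogger(__name__)


@dataclass
class TripFilters:
    """Minimum requirements for a run of fixes to count as a trip."""

    min_fixes: int = 2
    min_duration_s: float = 60.0
    min_distance_m: float = 200.0  # applied after matching


@dataclass
class Trip:
    """One occupied journey, optionally map-matched.

    Before matching only the fix arrays are populated.  After matching,
    ``path_coords`` is the traversed polyline (lon/lat), ``fix_offsets_m``
    the along-path offset of each fix's matched point, ``path_edge_ids``
    the traversed edge ids in order, and ``distance_km`` the along-path
    length from the first to the last matched point.
    """

    taxi_id: str
    fix_times: np.ndarray  # datetime64[s]
    fix_lon: np.ndarray
    fix_lat: np.ndarray
    origin: tuple
    destination: tuple
    matched: bool = False
    path_coords: Optional[np.ndarray] = None
    path_edge_ids: list = dc_field(default_factory=list)
    fix_offsets_m: Optional[np.ndarray] = None
    fix_edge_ids: Optional[np.ndarray] = None
    distance_km: float = 0.0

    def __post_init__(self) -> None:
        self.fix_times = np.asarray(self.fix_times, dtype="datetime64[s]")
        if self.fix_times.size and self.fix_times[0] > self.fix_times[-1]:
            raise DataError("trip fixes not time ordered")

    @property
    def time_start(self):
        return self.fix_times[0]

    @property
    def time_end(self):
        return self.fix_times[-1]

    @property
    def n_fixes(self) -> int:
        return int(self.fix_times.size)

    @property
    def duration_s(self) -> float:
        return float((self.fix_times[-1] - self.fix_times[0])
                     .astype("timedelta64[s]").astype(float))

    @property
    def duration_h(self) -> float:
        return self.duration_s / 3600.0


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

def clean_fixes(fixes, extent, max_speed_kmh: float = 120.0):
    """Remove implausible fixes; total (never raises), counts logged.

    Drops, per taxi: fixes outside ``extent`` (lon_min, lat_min, lon_max,
    lat_max), duplicate timestamps (first kept), and fixes implying a
    segment speed above ``max_speed_kmh`` from the previous surviving fix
    (violators removed iteratively until none remain, which makes the
    operation idempotent).  Accepts and returns either a fix DataFrame or a
    list of RawFix.
    """
    as_list = not isinstance(fixes, pd.DataFrame)
    df = as_fix_frame(fixes)
    n0 = len(df)
    if n0 == 0:
        return fixes if not as_list else []
    lon_min, lat_min, lon_max, lat_max = extent
    inside = ((df["lon"] >= lon_min) & (df["lon"] <= lon_max)
              & (df["lat"] >= lat_min) & (df["lat"] <= lat_max))
    df = df.loc[inside]
    df = df.loc[~df.duplicated(subset=["taxi_id", "timestamp"], keep="first")]
    # iterated speed rule: compare to previous surviving fix of the same taxi
    while True:
        same = df["taxi_id"].values[1:] == df["taxi_id"].values[:-1]
        dt = (df["timestamp"].values[1:] - df["timestamp"].values[:-1]
              ).astype("timedelta64[s]").astype(float)
        dist = haversine_m(df["lon"].values[:-1], df["lat"].values[:-1],
                           df["lon"].values[1:], df["lat"].values[1:])
        with np.errstate(divide="ignore", invalid="ignore"):
            speed_kmh = np.where(dt > 0, dist / 1000.0 / (dt / 3600.0), np.inf)
        bad = np.concatenate([[False], same & (speed_kmh > max_speed_kmh)])
        # drop only the first violator of each consecutive run, so later
        # fixes are re-judged against the surviving predecessor next pass
        bad &= ~np.concatenate([[False], bad[:-1]])
        if not bad.any():
            break
        df = df.loc[~bad]
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("clean_fixes: dropped %d of %d fixes", n_dropped, n0)
    df = df.reset_index(drop=True)
    return frame_to_fixes(df) if as_list else df


# ---------------------------------------------------------------------------
# Trip extraction
# ---------------------------------------------------------------------------

def extract_trips(fixes, filters: Optional[TripFilters] = None) -> list[Trip]:
    """One (unmatched) Trip per maximal contiguous occupied run.

    Runs failing the minimum-fix or minimum-duration filters are dropped
    (count logged); the matched-distance filter applies after matching.
    """
    filters = filters or TripFilters()
    df = as_fix_frame(fixes)
    if df.empty:
        return []
    df = df.sort_values(["taxi_id", "timestamp"], kind="mergesort")
    taxi = df["taxi_id"].values
    occ = df["occupied"].values.astype(bool)
    new_run = np.ones(len(df), dtype=bool)
    new_run[1:] = (taxi[1:] != taxi[:-1]) | (occ[1:] != occ[:-1])
    run_id = np.cumsum(new_run)
    trips: list[Trip] = []
    n_subthreshold = 0
    times = df["timestamp"].values.astype("datetime64[s]")
    lon = df["lon"].values.astype(float)
    lat = df["lat"].values.astype(float)
    starts = np.flatnonzero(new_run)
    ends = np.append(starts[1:], len(df))
    for s, e in zip(starts, ends):
        if not occ[s]:
            continue
        dur = (times[e - 1] - times[s]).astype("timedelta64[s]").astype(float)
        if (e - s) < filters.min_fixes or dur < filters.min_duration_s:
            n_subthreshold += 1
            continue
        trips.append(Trip(
            taxi_id=str(taxi[s]),
            fix_times=times[s:e].copy(),
            fix_lon=lon[s:e].copy(),
            fix_lat=lat[s:e].copy(),
            origin=(float(lon[s]), float(lat[s])),
            destination=(float(lon[e - 1]), float(lat[e - 1])),
        ))
    if n_subthreshold:
        logger.info("extract_trips: %d occupied runs below trip thresholds",
                    n_subthreshold)
    del run_id
    return trips


# ---------------------------------------------------------------------------
# Map matching
# ---------------------------------------------------------------------------

def _edge_candidates(trip: Trip, network: RoadNetwork, radius_m: float):
    """Per-fix candidate list: (edge, offset_m, proj_lon, proj_lat, dist_m).

    Candidate points are nearest points on edges within ``radius_m``
    (projection computed in degree space, distance by haversine).
    """
    tree, geoms = network.edge_tree()
    pts = shapely.points(trip.fix_lon, trip.fix_lat)
    lat0 = float(np.max(np.abs(trip.fix_lat)))
    radius_deg = radius_m / (M_PER_DEG * max(np.cos(np.radians(lat0)), 1e-6)) * 1.01
    pair = tree.query(pts, predicate="dwithin", distance=radius_deg)
    cands: list[list[tuple]] = [[] for _ in range(trip.n_fixes)]
    if pair.size == 0:
        return cands
    fix_idx, edge_idx = pair[0], pair[1]
    lines = np.take(np.asarray(geoms, dtype=object), edge_idx)
    locs_deg = shapely.line_locate_point(lines, pts[fix_idx])
    proj = shapely.line_interpolate_point(lines, locs_deg)
    px, py = shapely.get_x(proj), shapely.get_y(proj)
    len_deg = shapely.length(lines)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(len_deg > 0, locs_deg / len_deg, 0.0)
    off_m = frac * network.edge_length_m[edge_idx]
    d_m = haversine_m(trip.fix_lon[fix_idx], trip.fix_lat[fix_idx], px, py)
    ok = d_m <= radius_m
    for i, e, o, x, y, d in zip(fix_idx[ok], edge_idx[ok], off_m[ok],
                                px[ok], py[ok], d_m[ok]):
        cands[int(i)].append((int(e), float(o), float(x), float(y), float(d)))
    for lst in cands:
        lst.sort(key=lambda c: (c[0], c[1]))
    return cands


def _edge_sub(network: RoadNetwork, edge: int, f0: float, f1: float):
    """Sub-polyline of an edge between fractional positions f0 -> f1.

    Fractions are of the degree-space length; returns (coords, meters)
    where meters = |f1-f0| * edge_length_m.
    """
    coords = np.asarray(network.edge_coords[edge], dtype=float)
    meters = abs(f1 - f0) * float(network.edge_length_m[edge])
    if len(coords) == 2:  # straight edge: direct interpolation
        p0 = coords[0] + f0 * (coords[1] - coords[0])
        p1 = coords[0] + f1 * (coords[1] - coords[0])
        return np.array([p0, p1]), meters
    seg = np.hypot(np.diff(coords[:, 0]), np.diff(coords[:, 1]))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        return coords[:1], 0.0

    def point_at(f):
        d = f * total
        j = int(np.searchsorted(cum, d, side="right")) - 1
        j = min(max(j, 0), len(seg) - 1)
        t = 0.0 if seg[j] == 0 else (d - cum[j]) / seg[j]
        return coords[j] + t * (coords[j + 1] - coords[j])

    lo, hi = (f0, f1) if f0 <= f1 else (f1, f0)
    inner = [k for k in range(len(coords))
             if lo * total < cum[k] < hi * total]
    pts = [point_at(lo)] + [coords[k] for k in inner] + [point_at(hi)]
    if f0 > f1:
        pts = pts[::-1]
    return np.asarray(pts), meters


def _route_matrix(network: RoadNetwork, pe, poff, ce, coff):
    """Along-network distance (m) from each previous candidate to each
    current candidate; inf where no path exists."""
    dist, _ = network.node_distances()
    L = network.edge_length_m
    pu, pv = network.edge_u[pe], network.edge_v[pe]
    cu, cv = network.edge_u[ce], network.edge_v[ce]
    if pe.size == 1 and ce.size == 1:
        if pe[0] == ce[0]:
            return np.array([[abs(coff[0] - poff[0])]])
        p0, p1 = poff[0], L[pe[0]] - poff[0]
        c0, c1 = coff[0], L[ce[0]] - coff[0]
        a, b, c, d = int(pu[0]), int(pv[0]), int(cu[0]), int(cv[0])
        return np.array([[min(p0 + dist[a, c] + c0, p0 + dist[a, d] + c1,
                              p1 + dist[b, c] + c0, p1 + dist[b, d] + c1)]])
    d_pu, d_pv = poff, L[pe] - poff
    d_cu, d_cv = coff, L[ce] - coff
    route = np.minimum.reduce([
        d_pu[:, None] + dist[pu[:, None], cu[None, :]] + d_cu[None, :],
        d_pu[:, None] + dist[pu[:, None], cv[None, :]] + d_cv[None, :],
        d_pv[:, None] + dist[pv[:, None], cu[None, :]] + d_cu[None, :],
        d_pv[:, None] + dist[pv[:, None], cv[None, :]] + d_cv[None, :],
    ])
    same = pe[:, None] == ce[None, :]
    if same.any():
        direct = np.abs(coff[None, :] - poff[:, None])
        route = np.where(same, np.minimum(route, direct), route)
    return route


def _viterbi(trip: Trip, network: RoadNetwork, cands, sigma_m: float,
             beta_m: float, start: int, end: int) -> list[int]:
    """Viterbi pass over fixes [start, end); returns chosen candidate index
    per fix.  Tie-break: same edge as the previous state, else lowest edge
    id (candidates are pre-sorted by edge id)."""
    n = end - start
    arrays = []
    for i in range(start, end):
        c = cands[i]
        arrays.append((np.array([t[0] for t in c]),
                       np.array([t[1] for t in c]),
                       np.array([t[4] for t in c])))
    scores = -arrays[0][2] ** 2 / (2.0 * sigma_m ** 2)
    back: list[np.ndarray] = []
    gc_all = haversine_m(trip.fix_lon[start:end - 1], trip.fix_lat[start:end - 1],
                         trip.fix_lon[start + 1:end], trip.fix_lat[start + 1:end]
                         ) if n > 1 else np.zeros(0)
    for k in range(1, n):
        pe, poff, _ = arrays[k - 1]
        ce, coff, cd = arrays[k]
        gc = float(gc_all[k - 1])
        if pe.size == 1 and ce.size == 1:
            route1 = _route_matrix(network, pe, poff, ce, coff)[0, 0]
            if np.isfinite(route1) and np.isfinite(scores[0]):
                scores = np.array([scores[0] - abs(route1 - gc) / beta_m
                                   - cd[0] ** 2 / (2.0 * sigma_m ** 2)])
                back.append(np.zeros(1, dtype=np.int64))
                continue
            raise _Unreachable(start + k)
        route = _route_matrix(network, pe, poff, ce, coff)
        with np.errstate(invalid="ignore"):
            trans = -np.abs(route - gc) / beta_m
        trans[~np.isfinite(route)] = -np.inf
        total = scores[:, None] + trans
        emis = -cd ** 2 / (2.0 * sigma_m ** 2)
        best_prev = np.empty(len(ce), dtype=np.int64)
        new_scores = np.empty(len(ce))
        for j in range(len(ce)):
            col = total[:, j]
            m = col.max()
            if not np.isfinite(m):
                best_prev[j] = 0
                new_scores[j] = -np.inf
                continue
            ties = np.flatnonzero(col == m)
            same = ties[pe[ties] == ce[j]]
            best_prev[j] = int(same[0]) if same.size else int(ties[0])
            new_scores[j] = m + emis[j]
        if not np.any(np.isfinite(new_scores)):
            raise _Unreachable(start + k)
        scores = new_scores
        back.append(best_prev)
    choice = [int(np.argmax(scores))]
    for bp in reversed(back):
        choice.append(int(bp[choice[-1]]))
    return choice[::-1]


class _Unreachable(Exception):
    """Internal: no finite transition into this fix index."""

    def __init__(self, fix_index: int):
        self.fix_index = fix_index


def _build_path(trip: Trip, network: RoadNetwork, cands, choice,
                start: int, end: int) -> Trip:
    """Assemble the matched sub-trip from chosen candidates."""
    dist, _ = network.node_distances()
    L = network.edge_length_m
    coords_parts: list[np.ndarray] = []
    edge_seq: list[int] = []
    fix_offsets = np.zeros(end - start)
    fix_edges = np.zeros(end - start, dtype=np.int64)
    sel = [cands[i][choice[i - start]] for i in range(start, end)]
    e0, o0, x0, y0, _ = sel[0]
    coords_parts.append(np.array([[x0, y0]]))
    edge_seq.append(e0)
    fix_edges[0] = e0
    cum = 0.0
    for k in range(1, len(sel)):
        pe, poff, _, _, _ = sel[k - 1]
        ce, coff, cx, cy, _ = sel[k]
        if pe == ce:
            direct = abs(coff - poff)
        else:
            direct = np.inf
        pu, pv = int(network.edge_u[pe]), int(network.edge_v[pe])
        cu, cv = int(network.edge_u[ce]), int(network.edge_v[ce])
        combos = [(pu, cu, poff, coff), (pu, cv, poff, L[ce] - coff),
                  (pv, cu, L[pe] - poff, coff), (pv, cv, L[pe] - poff, L[ce] - coff)]
        routes = [da + dist[a, b] + db for a, b, da, db in combos]
        i_best = int(np.argmin(routes))
        via = routes[i_best]
        if direct <= via:
            # stay on the edge between the two offsets
            fp, fc = poff / L[pe] if L[pe] > 0 else 0.0, coff / L[ce] if L[ce] > 0 else 0.0
            pts, meters = _edge_sub(network, pe, fp, fc)
            coords_parts.append(pts[1:] if len(pts) > 1 else pts)
            cum += meters
        else:
            a, b, da, db = combos[i_best]
            # previous point -> node a along edge pe
            f_from = poff / L[pe] if L[pe] > 0 else 0.0
            f_to = 0.0 if a == pu else 1.0
            pts, meters = _edge_sub(network, pe, f_from, f_to)
            coords_parts.append(pts[1:] if len(pts) > 1 else pts)
            cum += meters
            # node path a -> b
            node_path = network.shortest_node_path(a, b)
            for na, nb in zip(node_path[:-1], node_path[1:]):
                eid = network.edge_between(na, nb)
                ec = np.asarray(network.edge_coords[eid], dtype=float)
                if int(network.edge_u[eid]) != na:
                    ec = ec[::-1]
                coords_parts.append(ec[1:])
                cum += float(L[eid])
                edge_seq.append(eid)
            # node b -> current point along edge ce
            f_from = 0.0 if b == cu else 1.0
            f_to = coff / L[ce] if L[ce] > 0 else 0.0
            pts, meters = _edge_sub(network, ce, f_from, f_to)
            coords_parts.append(pts[1:] if len(pts) > 1 else pts)
            cum += meters
        if edge_seq[-1] != ce:
            edge_seq.append(ce)
        fix_offsets[k] = cum
        fix_edges[k] = ce
    coords = np.vstack(coords_parts)
    keep = np.ones(len(coords), dtype=bool)
    keep[1:] = np.any(np.diff(coords, axis=0) != 0, axis=1)
    coords = coords[keep]
    # collapse consecutive duplicate edges (degenerate hops)
    edges = [edge_seq[0]]
    for e in edge_seq[1:]:
        if e != edges[-1]:
            edges.append(e)
    return Trip(
        taxi_id=trip.taxi_id,
        fix_times=trip.fix_times[start:end],
        fix_lon=trip.fix_lon[start:end],
        fix_lat=trip.fix_lat[start:end],
        origin=(float(trip.fix_lon[start]), float(trip.fix_lat[start])),
        destination=(float(trip.fix_lon[end - 1]), float(trip.fix_lat[end - 1])),
        matched=True,
        path_coords=coords,
        path_edge_ids=edges,
        fix_offsets_m=fix_offsets,
        fix_edge_ids=fix_edges,
        distance_km=cum / 1000.0,
    )


def map_match(trip: Trip, network: RoadNetwork, sigma_m: float = 10.0,
              beta_m: float = 200.0, candidate_radius_m: float = 50.0,
              trip_filters: Optional[TripFilters] = None) -> list[Trip]:
    """HMM map matching of one trip; returns the matched trip(s).

    A fix with no candidate edge within ``candidate_radius_m`` (or no
    network path into it) splits the trip there; each part is matched
    independently.  When ``trip_filters`` is given, every resulting
    sub-trip must still pass the minimum-fix/duration/distance filters.
    Usually the returned list has exactly one element.
    """
    cands = _edge_candidates(trip, network, candidate_radius_m)
    out: list[Trip] = []
    n = trip.n_fixes
    start = 0
    while start < n:
        while start < n and not cands[start]:
            start += 1
        if start >= n:
            break
        end = start
        while end < n and cands[end]:
            end += 1
        s = start
        while s < end:
            try:
                choice = _viterbi(trip, network, cands, sigma_m, beta_m, s, end)
            except _Unreachable as exc:
                split = exc.fix_index
                if split > s:
                    out.append(_build_path(
                        trip, network, cands,
                        _viterbi(trip, network, cands, sigma_m, beta_m, s, split),
                        s, split))
                s = split
                continue
            out.append(_build_path(trip, network, cands, choice, s, end))
            break
        start = end
    if trip_filters is not None:
        out = [t for t in out
               if t.n_fixes >= trip_filters.min_fixes
               and t.duration_s >= trip_filters.min_duration_s
               and t.distance_km * 1000.0 >= trip_filters.min_distance_m]
    return out


def match_trips(trips: Sequence[Trip], network: RoadNetwork,
                sigma_m: float = 10.0, beta_m: float = 200.0,
                candidate_radius_m: float = 50.0,
                filters: Optional[TripFilters] = None) -> list[Trip]:
    """Match many trips, applying the standard trip filters; counts logged."""
    filters = filters or TripFilters()
    matched: list[Trip] = []
    n_split = 0
    for trip in trips:
        parts = map_match(trip, network, sigma_m, beta_m,
                          candidate_radius_m, trip_filters=filters)
        if len(parts) > 1:
            n_split += 1
        matched.extend(parts)
    logger.info("match_trips: %d trips in, %d matched out (%d split)",
                len(trips), len(matched), n_split)
    return matched
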