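"""Trip-level exposure integration and fleet summaries.

A matched trip, traversed at the constant speed implied between
consecutive fix times, is cut at every grid-cell boundary crossing and
every clock-hour boundary.  Each piece contributes C * dt to the exposure
integral

    EI(trip) = lambda * sum_pieces( C_cell,hour * dt )        [ug.h/m3]

with lambda the in-cabin filtration coefficient (1 = open windows).  The
time-weighted average exposure TWA = EI / (lambda * duration) is in ug/m3
and is what hourly/daily summaries aggregate.  Piece durations are exact
differences of a common time grid, so sum(dt) telescopes to the trip
duration to machine precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DomainError
from .fusion import ConcentrationField
from .geo import polyline_cumdist_m
from .preprocess import Trip

logger = logging.getLogger(__name__)

Z_95 = 1.959964  # normal 97.5% quantile used for 95% confidence intervals


@dataclass(frozen=True)
class ExposureConfig:
    """Exposure parameters and guideline references.

    lambda_filtration is dimensionless in (0, 1]; china_thresholds are the
    good/moderate/unhealthy-for-sensitive-groups cutoffs in ug/m3.
    """

    lambda_filtration: float = 1.0
    guideline_who_24h: float = 25.0
    china_thresholds: tuple = (35.0, 75.0, 115.0)
    ci_level: float = 0.95
    min_weekdays: int = 10
    min_weekend_days: int = 4
    extreme_fraction: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.lambda_filtration <= 1):
            raise DomainError("lambda_filtration must be in (0, 1]")
        t = self.china_thresholds
        if not all(a < b for a, b in zip(t, t[1:])):
            raise DomainError("china_thresholds must be strictly increasing")


@dataclass
class GridSegment:
    """One piece of a trip inside a single grid cell and clock hour."""

    cell: tuple  # (row, col)
    hour_start: np.datetime64
    delta_t_h: float
    concentration: float  # fused C of this cell and hour, ug/m3


@dataclass
class TripExposure:
    """Exposure of one trip: raw integral, time-weighted mean, pieces."""

    trip: Trip
    ei: float  # ug.h/m3
    twa: float  # ug/m3
    lam: float
    segments: list = dc_field(default_factory=list)

    @property
    def taxi_id(self) -> str:
        return self.trip.taxi_id

    @property
    def time_start(self):
        return self.trip.time_start

    @property
    def duration_h(self) -> float:
        return self.trip.duration_h

    @property
    def date(self):
        return pd.Timestamp(self.trip.time_start).date()

    @property
    def day_type(self) -> str:
        return day_type_of(self.trip.time_start)


@dataclass
class DriverDay:
    """One driver-day: time-weighted mean over that day's trips."""

    taxi_id: str
    date: object  # datetime.date
    day_type: str  # weekday | weekend
    daily_twa: float
    total_occupied_hours: float
    n_trips: int


def day_type_of(t) -> str:
    """weekday (Mon-Fri) or weekend (Sat-Sun) in local time."""
    return "weekend" if pd.Timestamp(t).dayofweek >= 5 else "weekday"


# ---------------------------------------------------------------------------
# Trip segmentation (Eq. 3 splitting)
# ---------------------------------------------------------------------------

def segment_trip(trip: Trip, field: ConcentrationField) -> list[GridSegment]:
    """Cut a matched trip at grid-cell and clock-hour boundaries.

    Between consecutive fixes the vehicle moves along the matched path at
    constant speed.  Returns pieces whose durations sum exactly to the trip
    duration; raises if the trip leaves the grid or the field's time range.
    """
    if not trip.matched or trip.path_coords is None:
        raise DataError("segment_trip requires a matched trip")
    grid = field.annual_grid
    s = grid.cell_size
    coords = np.asarray(trip.path_coords, dtype=float)
    d_vertex = polyline_cumdist_m(coords)
    offs = np.maximum.accumulate(np.asarray(trip.fix_offsets_m, dtype=float))
    # align the two distance scales (both measure the same polyline)
    if offs[-1] > 0 and d_vertex[-1] > 0:
        offs = offs * (d_vertex[-1] / offs[-1])
    t_fix = (trip.fix_times - field.time_start).astype("timedelta64[s]"
                                                       ).astype(float)
    # elementary breakpoints: polyline vertices + fix knots, in distance
    d_all = np.unique(np.concatenate([d_vertex, offs]))
    lon_all = np.interp(d_all, d_vertex, coords[:, 0])
    lat_all = np.interp(d_all, d_vertex, coords[:, 1])
    t_all = np.interp(d_all, offs, t_fix)
    inside = grid.contains(lon_all, lat_all)
    if not np.all(inside):
        j = int(np.argmin(inside))
        raise DataError(
            f"trip leaves the grid near ({lon_all[j]:.5f}, {lat_all[j]:.5f})")
    # stationary leading/trailing time (zero-distance but time passing) is
    # represented by repeated offsets; add explicit time-only pieces
    pieces: list[tuple] = []  # (t0, t1, x0, y0, x1, y1)
    if offs[0] > d_all[0] or t_all[0] > t_fix[0]:
        pieces.append((t_fix[0], t_all[0], lon_all[0], lat_all[0],
                       lon_all[0], lat_all[0]))
    for k in range(d_all.size - 1):
        pieces.append((t_all[k], t_all[k + 1], lon_all[k], lat_all[k],
                       lon_all[k + 1], lat_all[k + 1]))
    if t_all.size and t_fix[-1] > t_all[-1]:
        pieces.append((t_all[-1], t_fix[-1], lon_all[-1], lat_all[-1],
                       lon_all[-1], lat_all[-1]))
    if not pieces:  # single-point trip
        pieces = [(t_fix[0], t_fix[-1], coords[0, 0], coords[0, 1],
                   coords[0, 0], coords[0, 1])]
    piece_rows: list[int] = []
    piece_cols: list[int] = []
    piece_hours: list[int] = []
    piece_dt: list[float] = []
    x0g, y0g = grid.origin_lon, grid.origin_lat
    for t0, t1, xa, ya, xb, yb in pieces:
        if t1 <= t0:
            continue
        # crossing times within (t0, t1): cell boundaries + hour boundaries
        cuts = [t0, t1]
        fx0, fx1 = (xa - x0g) / s, (xb - x0g) / s
        fy0, fy1 = (ya - y0g) / s, (yb - y0g) / s
        for f0, f1 in ((fx0, fx1), (fy0, fy1)):
            if f1 != f0:
                lo, hi = (f0, f1) if f0 < f1 else (f1, f0)
                for b in range(math.floor(lo) + 1, math.floor(hi) + 1):
                    frac = (b - f0) / (f1 - f0)
                    if 0.0 < frac < 1.0:
                        cuts.append(t0 + frac * (t1 - t0))
        for hb in range(math.floor(t0 / 3600.0) + 1,
                        math.floor(t1 / 3600.0) + 1):
            th = hb * 3600.0
            if t0 < th < t1:
                cuts.append(th)
        cuts = sorted(set(cuts))
        for a, b in zip(cuts[:-1], cuts[1:]):
            tm = 0.5 * (a + b)
            u = (tm - t0) / (t1 - t0)
            xm = xa + u * (xb - xa)
            ym = ya + u * (yb - ya)
            piece_cols.append(math.floor((xm - x0g) / s))
            piece_rows.append(math.floor((ym - y0g) / s))
            piece_hours.append(math.floor(tm / 3600.0))
            piece_dt.append(b - a)
    # paths on the outer boundary floor to the row/col just outside; fold
    # them into the outermost cell, matching the grid's closed boundary
    rows_a = np.clip(np.array(piece_rows, dtype=np.int64), 0, grid.n_rows - 1)
    cols_a = np.clip(np.array(piece_cols, dtype=np.int64), 0, grid.n_cols - 1)
    # merge consecutive pieces that stay in the same cell and hour
    if rows_a.size:
        hours_arr = np.array(piece_hours, dtype=np.int64)
        keep = np.ones(rows_a.size, dtype=bool)
        keep[1:] = ((rows_a[1:] != rows_a[:-1]) | (cols_a[1:] != cols_a[:-1])
                    | (hours_arr[1:] != hours_arr[:-1]))
        group = np.cumsum(keep) - 1
        merged_dt = np.zeros(int(group[-1]) + 1)
        np.add.at(merged_dt, group, np.asarray(piece_dt))
        rows_a = rows_a[keep]
        cols_a = cols_a[keep]
        piece_hours = hours_arr[keep]
        piece_dt = merged_dt
    hours_a = np.array(piece_hours, dtype=np.int64)
    hour_starts = field.time_start + (hours_a * 3600).astype("timedelta64[s]")
    conc = field.evaluate(
        grid.origin_lon + (cols_a + 0.5) * s,
        grid.origin_lat + (rows_a + 0.5) * s,
        hour_starts)
    conc = np.atleast_1d(conc)
    return [GridSegment(cell=(int(r), int(c)), hour_start=hs,
                        delta_t_h=dt / 3600.0, concentration=float(cv))
            for r, c, hs, dt, cv in zip(rows_a, cols_a, hour_starts,
                                        piece_dt, conc)]


def trip_exposure(trip: Trip, field: ConcentrationField,
                  config: Optional[ExposureConfig] = None) -> TripExposure:
    """Exposure integral EI and time-weighted average for one trip."""
    config = config or ExposureConfig()
    if trip.duration_s <= 0:
        raise DataError("zero-duration trip (should be filtered upstream)")
    segments = segment_trip(trip, field)
    lam = config.lambda_filtration
    integral = sum(seg.concentration * seg.delta_t_h for seg in segments)
    ei = lam * integral
    twa = ei / (lam * trip.duration_h)
    return TripExposure(trip=trip, ei=ei, twa=twa, lam=lam, segments=segments)


def compute_trip_exposures(trips: Sequence[Trip], field: ConcentrationField,
                           config: Optional[ExposureConfig] = None
                           ) -> list[TripExposure]:
    config = config or ExposureConfig()
    return [trip_exposure(t, field, config) for t in trips]


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def hourly_summary(trip_exposures: Sequence[TripExposure],
                   day_filter: Optional[str] = None,
                   ci_level: float = 0.95) -> pd.DataFrame:
    """Mean exposure and 95% CI per hour of day (24 rows).

    Each trip contributes, per hour-of-day bucket, its time-weighted mean
    concentration within that hour as one sample weighted by the time
    spent.  The CI is the normal approximation mean +/- z * se; hours with
    no samples are left missing (NaN), a single sample yields a CI equal
    to the mean.  ``day_filter`` restricts to "weekday" or "weekend"
    (judged per segment date).
    """
    if not trip_exposures:
        raise DataError("hourly_summary needs at least one exposure sample")
    from scipy.stats import norm
    z = Z_95 if abs(ci_level - 0.95) < 1e-12 else float(
        norm.ppf(0.5 + ci_level / 2.0))
    samples: dict[int, list[tuple[float, float]]] = {h: [] for h in range(24)}
    for te in trip_exposures:
        acc: dict[int, tuple[float, float]] = {}
        for seg in te.segments:
            ts = pd.Timestamp(seg.hour_start)
            if day_filter and day_type_of(ts) != day_filter:
                continue
            h = ts.hour
            w, sw = acc.get(h, (0.0, 0.0))
            acc[h] = (w + seg.delta_t_h, sw + seg.concentration * seg.delta_t_h)
        for h, (w, sw) in acc.items():
            if w > 0:
                samples[h].append((sw / w, w))
    rows = []
    for h in range(24):
        vals = samples[h]
        n = len(vals)
        if n == 0:
            rows.append((h, np.nan, np.nan, np.nan, 0))
            continue
        x = np.array([v for v, _ in vals])
        w = np.array([wt for _, wt in vals])
        mean = float(np.sum(w * x) / np.sum(w))
        if n == 1:
            rows.append((h, mean, mean, mean, 1))
            continue
        denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
        var = float(np.sum(w * (x - mean) ** 2) / denom) if denom > 0 else 0.0
        se = math.sqrt(max(var, 0.0)) * math.sqrt(float(np.sum(w ** 2))) / float(
            np.sum(w))
        rows.append((h, mean, mean - z * se, mean + z * se, n))
    return pd.DataFrame(rows, columns=["hour", "mean", "ci_low", "ci_high", "n"])


def daily_summaries(trip_exposures: Sequence[TripExposure]
                    ) -> tuple[list[DriverDay], pd.DataFrame,
                               tuple[float, float], tuple[float, float]]:
    """Driver-day summaries and fleet daily means.

    Returns (driver_days, per-day fleet table, (weekday mean, sd),
    (weekend mean, sd)).  A driver-day's TWA is sum(EI) / (lambda *
    sum(duration)) over that driver's trips of the day; the fleet value of
    a day is the unweighted mean over its drivers; weekday/weekend
    statistics (n-1 sd) are over the per-day fleet values.
    """
    if not trip_exposures:
        raise DataError("daily_summaries needs at least one exposure")
    acc: dict[tuple, list[TripExposure]] = {}
    for te in trip_exposures:
        acc.setdefault((te.taxi_id, te.date), []).append(te)
    driver_days = []
    for (taxi_id, date), tes in sorted(acc.items()):
        dur = sum(t.duration_h for t in tes)
        lam = tes[0].lam
        twa = sum(t.ei for t in tes) / (lam * dur)
        driver_days.append(DriverDay(
            taxi_id=taxi_id, date=date,
            day_type=day_type_of(pd.Timestamp(date)),
            daily_twa=twa, total_occupied_hours=dur, n_trips=len(tes)))
    per_day = (pd.DataFrame([(d.date, d.day_type, d.daily_twa)
                             for d in driver_days],
                            columns=["date", "day_type", "daily_twa"])
               .groupby(["date", "day_type"], as_index=False)
               .agg(fleet_mean=("daily_twa", "mean"),
                    n_drivers=("daily_twa", "size")))

    def _stats(day_type):
        v = per_day.loc[per_day["day_type"] == day_type, "fleet_mean"].values
        if v.size == 0:
            return (float("nan"), float("nan"))
        sd = float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
        return (float(np.mean(v)), sd)

    return driver_days, per_day, _stats("weekday"), _stats("weekend")


# ---------------------------------------------------------------------------
# Guidelines and subgroup selection
# ---------------------------------------------------------------------------

AIR_QUALITY_CATEGORIES = ("good", "moderate", "unhealthy_sensitive", "poor")


def classify_air_quality(c: float,
                         thresholds: tuple = (35.0, 75.0, 115.0)) -> str:
    """Chinese air-quality category of a 24-h PM2.5 concentration.

    Half-open bins: [0,35) good, [35,75) moderate, [75,115)
    unhealthy_sensitive, [115,inf) poor.
    """
    if c < 0:
        raise DomainError("concentration must be >= 0")
    for cat, thr in zip(AIR_QUALITY_CATEGORIES, thresholds):
        if c < thr:
            return cat
    return AIR_QUALITY_CATEGORIES[-1]


def guideline_comparison(mean_c: float, reference: float
                         ) -> tuple[float, float]:
    """(ratio, percent excess) of a mean concentration vs a guideline."""
    if reference <= 0:
        raise DomainError("guideline reference must be > 0")
    ratio = mean_c / reference
    return ratio, 100.0 * (mean_c - reference) / reference


def filter_eligible_drivers(driver_days: Iterable[DriverDay],
                            min_weekdays: int = 10,
                            min_weekend_days: int = 4) -> list[str]:
    """Drivers with enough distinct operating days for subgroup analysis."""
    wd: dict[str, set] = {}
    we: dict[str, set] = {}
    for d in driver_days:
        (wd if d.day_type == "weekday" else we).setdefault(
            d.taxi_id, set()).add(d.date)
    ids = set(wd) | set(we)
    return sorted(t for t in ids
                  if len(wd.get(t, ())) >= min_weekdays
                  or len(we.get(t, ())) >= min_weekend_days)


def driver_mean_twa(driver_days: Iterable[DriverDay]) -> dict[str, float]:
    """Mean daily TWA per driver over their operating days."""
    acc: dict[str, list[float]] = {}
    for d in driver_days:
        acc.setdefault(d.taxi_id, []).append(d.daily_twa)
    return {t: float(np.mean(v)) for t, v in sorted(acc.items())}


def select_extreme_drivers(driver_means: Mapping[str, float],
                           fraction: float = 0.01
                           ) -> tuple[list[str], list[str]]:
    """Top and bottom ceil(fraction * n) drivers by mean daily TWA.

    Ties broken by driver id; raises on an empty input.
    """
    if not (0 < fraction <= 0.5):
        raise DomainError("fraction must be in (0, 0.5]")
    items = list(driver_means.items())
    if not items:
        raise DataError("no eligible drivers to rank")
    k = math.ceil(fraction * len(items))
    high = [t for t, _ in sorted(items, key=lambda kv: (-kv[1], kv[0]))[:k]]
    low = [t for t, _ in sorted(items, key=lambda kv: (kv[1], kv[0]))[:k]]
    return high, low
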