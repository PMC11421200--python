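"""Raster-station fusion: representative-station selection and the fused
spatio-temporal concentration field.

The fused field combines an annual raster C_ij (spatial variability, no
temporal signal) with the hourly series of one representative monitoring
station (temporal variability, single location):

    C_ij(t) = C_base(t) + (C_ij - C_base_annual)

i.e. the annual spatial anomaly is shifted hour by hour by the station's
departure from its own annual value.  The representative station is the one
whose hourly series deviates least (minimum variance of the difference
series) from the annual raster at its location, among stations without
obvious outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DataError, DomainError
from .io_formats import AnnualGrid, StationSeries

logger = logging.getLogger(__name__)


@dataclass
class StationFit:
    """Agreement between one station's hourly series and the annual raster."""

    station_id: str
    annual_value: float
    difference_series: np.ndarray  # D_t = C_t(station) - C_annual(station)
    variance: float  # sample variance of D_t, (ug/m3)^2
    outlier_flag: bool = False

    @property
    def n_hours(self) -> int:
        return int(self.difference_series.size)


def station_difference_series(station: StationSeries, grid: AnnualGrid) -> StationFit:
    """Difference series D_t and its sample (n-1) variance for one station.

    Missing hours are excluded; at least two non-missing hours are required.
    """
    if not np.all(grid.contains(station.lon, station.lat)):
        raise DataError(f"station {station.station_id} lies outside the grid")
    annual = float(grid.value_at(station.lon, station.lat))
    if not np.isfinite(annual):
        raise DataError(f"station {station.station_id} sits on a nodata cell")
    conc = station.concentrations
    ok = np.isfinite(conc)
    if ok.sum() < 2:
        raise DataError(
            f"station {station.station_id}: need >=2 non-missing hours")
    diffs = conc[ok] - annual
    return StationFit(
        station_id=station.station_id,
        annual_value=annual,
        difference_series=diffs,
        variance=float(np.var(diffs, ddof=1)),
    )


def flag_outlier_stations(fits: Sequence[StationFit],
                          z_threshold: float = 5.0) -> list[StationFit]:
    """Flag stations whose difference series contains a z-score outlier.

    A station is flagged when any |D_t - mean(D)| exceeds z_threshold
    standard deviations of D.  Flat series are never flagged.
    """
    out = []
    for fit in fits:
        d = fit.difference_series
        sd = float(np.std(d, ddof=1))
        flagged = False
        if sd > 0 and np.isfinite(z_threshold):
            flagged = bool(np.any(np.abs(d - d.mean()) > z_threshold * sd))
        out.append(StationFit(fit.station_id, fit.annual_value,
                              fit.difference_series, fit.variance, flagged))
    return out


def select_representative_station(
        fits: Sequence[StationFit],
        override_id: Optional[str] = None) -> tuple[StationFit, list[StationFit]]:
    """Pick the representative station and return (selected, ranked list).

    Unflagged stations are ranked ascending by variance (ties broken by
    station id); the minimum-variance station is selected unless a manual
    ``override_id`` names another unflagged station.
    """
    unflagged = [f for f in fits if not f.outlier_flag]
    if not unflagged:
        raise DataError("all stations flagged as outliers; "
                        "raise the z threshold or inspect the series")
    ranked = sorted(unflagged, key=lambda f: (f.variance, f.station_id))
    if override_id is not None:
        by_id = {f.station_id: f for f in unflagged}
        if override_id not in by_id:
            raise DataError(f"override station {override_id!r} not among "
                            "unflagged stations")
        return by_id[override_id], ranked
    return ranked[0], ranked


class ConcentrationField:
    """Fused space-time concentration field driven by one base station.

    Hourly station values apply as a step function over [hour, hour+1);
    missing base-station hours are linearly interpolated across gaps of at
    most ``max_gap_h`` hours, longer gaps stay excluded (evaluations there
    raise).  Negative fused values are clamped to 0 (counted).
    """

    def __init__(self, annual_grid: AnnualGrid, base_station: StationSeries,
                 clamp_negative: bool = True, max_gap_h: int = 3):
        self.annual_grid = annual_grid
        self.base_station = base_station
        self.clamp_negative = clamp_negative
        self.clamp_count = 0
        if not np.all(annual_grid.contains(base_station.lon, base_station.lat)):
            raise DataError(f"base station {base_station.station_id} "
                            "lies outside the grid")
        self.base_annual_value = float(
            annual_grid.value_at(base_station.lon, base_station.lat))
        if not np.isfinite(self.base_annual_value):
            raise DataError(f"base station {base_station.station_id} "
                            "sits on a nodata cell")
        self._t0 = base_station.timestamps[0]
        conc = base_station.concentrations.astype(float).copy()
        missing = ~np.isfinite(conc)
        if missing.any():
            conc = _fill_short_gaps(conc, max_gap_h)
            n_left = int((~np.isfinite(conc)).sum())
            logger.info("base station %s: %d missing hours, %d remain excluded",
                        base_station.station_id, int(missing.sum()), n_left)
        self._hourly = conc

    @property
    def time_start(self):
        return self._t0

    @property
    def time_end(self):
        return self._t0 + np.timedelta64(self._hourly.size * 3600, "s")

    def hour_index(self, times) -> np.ndarray:
        times = np.asarray(times, dtype="datetime64[s]")
        return ((times - self._t0).astype("timedelta64[s]").astype(np.int64)
                // 3600)

    def station_value(self, times) -> np.ndarray:
        """Base-station concentration for the hour containing each time."""
        idx = self.hour_index(times)
        if np.any(idx < 0) or np.any(idx >= self._hourly.size):
            raise DomainError("time outside the base-station series")
        return self._hourly[idx]

    def evaluate(self, lon, lat, times):
        """Fused concentration (ug/m3) at each (lon, lat, time).

        Vectorized; raises if any point is outside the grid, on a nodata
        cell, or in an excluded (long-gap) hour.  Negative values clamp to
        0 and increment ``clamp_count``.
        """
        annual = self.annual_grid.value_at(lon, lat)
        if np.any(~np.isfinite(np.atleast_1d(annual))):
            raise DomainError("point falls on a nodata cell")
        base_t = self.station_value(times)
        if np.any(~np.isfinite(np.atleast_1d(base_t))):
            raise DomainError("time falls in an excluded base-station hour")
        fused = base_t + (annual - self.base_annual_value)
        if self.clamp_negative:
            neg = np.atleast_1d(fused) < 0
            n_neg = int(np.count_nonzero(neg))
            if n_neg:
                self.clamp_count += n_neg
                logger.debug("clamped %d negative fused values to 0", n_neg)
                fused = np.where(np.asarray(fused) < 0, 0.0, fused)
        if np.ndim(lon) == 0 and np.ndim(times) == 0:
            return float(fused)
        return np.asarray(fused, dtype=float)


def _fill_short_gaps(values: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate interior nan runs of length <= max_gap."""
    out = values.copy()
    n = out.size
    isnan = ~np.isfinite(out)
    i = 0
    while i < n:
        if isnan[i]:
            j = i
            while j < n and isnan[j]:
                j += 1
            gap = j - i
            if 0 < i and j < n and gap <= max_gap:
                left, right = out[i - 1], out[j]
                for k in range(gap):
                    out[i + k] = left + (right - left) * (k + 1) / (gap + 1)
            i = j
        else:
            i += 1
    return out


def fused_concentration(field: ConcentrationField, lon: float, lat: float,
                        t) -> float:
    """Fused concentration at one point and instant (scalar convenience)."""
    return field.evaluate(float(lon), float(lat), np.datetime64(t, "s"))


def build_field(grid: AnnualGrid, stations: Sequence[StationSeries],
                z_threshold: float = 5.0,
                override_id: Optional[str] = None,
                clamp_negative: bool = True,
                ) -> tuple[ConcentrationField, list[StationFit]]:
    """Full fusion stage: fit, flag, select, and assemble the field.

    Returns the field plus the ranked station list (variance ascending).
    """
    fits = [station_difference_series(st, grid) for st in stations]
    fits = flag_outlier_stations(fits, z_threshold)
    selected, ranked = select_representative_station(fits, override_id)
    base = next(st for st in stations if st.station_id == selected.station_id)
    field = ConcentrationField(grid, base, clamp_negative=clamp_negative)
    logger.info("representative station: %s (variance %.2f)",
                selected.station_id, selected.variance)
    return field, ranked
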