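"""Representative-station selection and the fused concentration field."""

import numpy as np
import pandas as pd
import pytest

import dynexposure as dx
from dynexposure.errors import DataError, DomainError

HOURS24 = pd.date_range("2014-05-13", periods=24, freq="h").values


def flat_grid(value=45.0, extent=(114.0, 30.3, 114.2, 30.5), cell=0.01):
    n = int(round((extent[2] - extent[0]) / cell))
    m = int(round((extent[3] - extent[1]) / cell))
    return dx.AnnualGrid(extent[0], extent[1], cell, np.full((m, n), value))


def series(values, sid="S1", lon=114.05, lat=30.4):
    ts = pd.date_range("2014-05-13", periods=len(values), freq="h").values
    return dx.StationSeries(sid, lon, lat, ts, np.asarray(values, float))


class TestDifferenceSeries:
    def test_identical_series_zero_variance(self):
        fit = dx.station_difference_series(series([45.0] * 24), flat_grid(45.0))
        assert np.all(fit.difference_series == 0.0)
        assert fit.variance == 0.0

    def test_constant_offset_zero_variance(self):
        fit = dx.station_difference_series(series([55.0] * 24), flat_grid(45.0))
        assert fit.variance == 0.0
        assert np.all(fit.difference_series == 10.0)

    def test_three_point_variance(self):
        """[50, 60, 70] vs annual 45 -> diffs [5, 15, 25], n-1 variance 100."""
        fit = dx.station_difference_series(series([50.0, 60.0, 70.0]),
                                           flat_grid(45.0))
        np.testing.assert_array_equal(fit.difference_series, [5.0, 15.0, 25.0])
        assert fit.variance == pytest.approx(100.0)

    def test_missing_hours_excluded(self):
        vals = [50.0] * 24
        vals[5] = np.nan
        fit = dx.station_difference_series(series(vals), flat_grid(45.0))
        assert fit.n_hours == 23

    def test_station_outside_grid(self):
        with pytest.raises(DataError):
            dx.station_difference_series(series([50.0] * 24, lon=115.0),
                                         flat_grid())


class TestOutlierFlagging:
    def test_flat_never_flagged(self):
        fits = [dx.station_difference_series(series([45.0] * 24),
                                             flat_grid(45.0))]
        assert not dx.flag_outlier_stations(fits, 5.0)[0].outlier_flag

    def test_spike_flagged(self, rng):
        vals = 50.0 + rng.normal(0, 1.0, 48)
        vals[10] += 100.0  # huge spike
        fits = [dx.station_difference_series(series(list(vals)),
                                             flat_grid(45.0))]
        assert dx.flag_outlier_stations(fits, 5.0)[0].outlier_flag

    def test_infinite_threshold_never_flags(self, rng):
        vals = 50.0 + rng.normal(0, 20.0, 48)
        vals = np.clip(vals, 0, None)
        fits = [dx.station_difference_series(series(list(vals)),
                                             flat_grid(45.0))]
        assert not dx.flag_outlier_stations(fits, np.inf)[0].outlier_flag


def fits_with_variances(variances: dict):
    return [dx.StationFit(sid, 45.0, np.zeros(2), var)
            for sid, var in variances.items()]


class TestSelection:
    # hourly-vs-annual difference variances of the nine-station fixture
    NINE = {"a": 308.04, "b": 355.41, "c": 657.53, "d": 183.68, "e": 131.97,
            "f": 253.47, "g": 238.32, "h": 747.47, "i": 358.51}

    def test_nine_station_ranking(self):
        sel, ranked = dx.select_representative_station(
            fits_with_variances(self.NINE))
        assert sel.station_id == "e"
        assert sel.variance == pytest.approx(131.97)
        assert ranked[1].station_id == "d"
        assert ranked[1].variance == pytest.approx(183.68)

    def test_order_invariance(self, rng):
        fits = fits_with_variances(self.NINE)
        for _ in range(5):
            perm = list(rng.permutation(len(fits)))
            sel, ranked = dx.select_representative_station(
                [fits[i] for i in perm])
            assert sel.station_id == "e"
            assert [f.station_id for f in ranked] == [
                "e", "d", "g", "f", "a", "b", "i", "c", "h"]

    def test_single_unflagged_selected(self):
        fits = fits_with_variances({"a": 10.0, "b": 5.0})
        fits[1].outlier_flag = True
        sel, _ = dx.select_representative_station(fits)
        assert sel.station_id == "a"

    def test_tie_break_lower_id(self):
        sel, _ = dx.select_representative_station(
            fits_with_variances({"b": 10.0, "a": 10.0}))
        assert sel.station_id == "a"

    def test_manual_override(self):
        sel, ranked = dx.select_representative_station(
            fits_with_variances(self.NINE), override_id="d")
        assert sel.station_id == "d"
        assert ranked[0].station_id == "e"  # ranking unaffected

    def test_all_flagged_errors(self):
        fits = fits_with_variances({"a": 1.0})
        fits[0].outlier_flag = True
        with pytest.raises(DataError, match="threshold"):
            dx.select_representative_station(fits)


class TestFusedField:
    def make_field(self, annual=50.0, station_vals=None, station_annual=45.0):
        """Grid with the station's cell at station_annual, elsewhere annual."""
        g = flat_grid(annual)
        r, c = g.cell_of(114.05, 30.4)
        g.values[r, c] = station_annual
        st = series(station_vals if station_vals is not None else [100.0] * 24)
        return dx.ConcentrationField(g, st), g

    def test_station_cell_returns_station_value(self):
        field, _ = self.make_field()
        v = dx.fused_concentration(field, 114.05, 30.4, HOURS24[3])
        assert v == 100.0

    def test_substitution(self):
        """C_ij=50, C_base=45, station hour 100 -> 105."""
        field, _ = self.make_field(annual=50.0, station_annual=45.0)
        v = dx.fused_concentration(field, 114.15, 30.45, HOURS24[0])
        assert v == pytest.approx(105.0)

    def test_negative_clamped_and_counted(self):
        """C_ij=10, C_base=45, station hour 20 -> raw -15, clamped to 0."""
        field, g = self.make_field(annual=10.0, station_vals=[20.0] * 24,
                                   station_annual=45.0)
        v = dx.fused_concentration(field, 114.15, 30.45, HOURS24[0])
        assert v == 0.0
        assert field.clamp_count == 1

    def test_spatial_anomaly_preserved(self, tiny_world, rng):
        """fused(p,t) - fused(q,t) = annual(p) - annual(q) absent clamping."""
        grid, stations, _, field = tiny_world
        n = 1000
        lon = rng.uniform(114.0, 114.199, n)
        lat = rng.uniform(30.3, 30.499, n)
        lon2 = rng.uniform(114.0, 114.199, n)
        lat2 = rng.uniform(30.3, 30.499, n)
        hours = field.base_station.timestamps[rng.integers(0, 24, n)]
        d_fused = field.evaluate(lon, lat, hours) - field.evaluate(lon2, lat2,
                                                                   hours)
        d_annual = grid.value_at(lon, lat) - grid.value_at(lon2, lat2)
        np.testing.assert_allclose(d_fused, d_annual, atol=1e-9)

    def test_temporal_shape_preserved(self, tiny_world, rng):
        grid, stations, _, field = tiny_world
        n = 1000
        lon = rng.uniform(114.0, 114.199, n)
        lat = rng.uniform(30.3, 30.499, n)
        i1 = rng.integers(0, 24, n)
        i2 = rng.integers(0, 24, n)
        t1 = field.base_station.timestamps[i1]
        t2 = field.base_station.timestamps[i2]
        d_fused = field.evaluate(lon, lat, t1) - field.evaluate(lon, lat, t2)
        d_station = field.station_value(t1) - field.station_value(t2)
        np.testing.assert_allclose(d_fused, d_station, atol=1e-9)

    def test_constant_grid_equals_station(self):
        field, _ = self.make_field(annual=45.0, station_annual=45.0,
                                   station_vals=list(range(30, 54)))
        for h in (0, 7, 23):
            v = dx.fused_concentration(field, 114.19, 30.31, HOURS24[h])
            assert v == pytest.approx(30.0 + h)

    def test_missing_hours_interpolated_short_gaps(self):
        vals = [100.0] * 24
        vals[5] = vals[6] = np.nan  # 2-h gap -> interpolated
        field, _ = self.make_field(station_vals=vals)
        assert field.station_value(HOURS24[5]) == pytest.approx(100.0)

    def test_long_gap_excluded(self):
        vals = [100.0] * 24
        for h in range(5, 10):  # 5-h gap > 3 -> excluded
            vals[h] = np.nan
        field, _ = self.make_field(station_vals=vals)
        with pytest.raises(DomainError):
            dx.fused_concentration(field, 114.05, 30.4, HOURS24[7])

    def test_outside_grid_errors(self):
        field, _ = self.make_field()
        with pytest.raises((DataError, DomainError)):
            dx.fused_concentration(field, 115.0, 30.4, HOURS24[0])

    def test_time_outside_series_errors(self):
        field, _ = self.make_field()
        with pytest.raises(DomainError):
            dx.fused_concentration(field, 114.05, 30.4,
                                   np.datetime64("2014-05-20T00:00:00"))
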