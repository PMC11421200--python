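"""Trip exposure integration, aggregation, guidelines, subgroups."""

import math

import numpy as np
import pandas as pd
import pytest

import dynexposure as dx
from dynexposure.errors import DataError, DomainError

from conftest import constant_world


def straight_trip(t0="2014-05-13T10:00:00", duration_s=1800.0,
                  lon0=114.05, lon1=114.15, lat=30.4, n_fixes=7):
    """Synthetic pre-matched straight trip at constant speed."""
    from dynexposure.geo import haversine_m
    times = (np.datetime64(t0, "s")
             + np.round(np.linspace(0, duration_s, n_fixes)
                        ).astype("timedelta64[s]"))
    lons = np.linspace(lon0, lon1, n_fixes)
    length = haversine_m(lon0, lat, lon1, lat)
    offs = np.linspace(0.0, length, n_fixes)
    return dx.Trip(
        taxi_id="T1", fix_times=times, fix_lon=lons,
        fix_lat=np.full(n_fixes, lat), origin=(lon0, lat),
        destination=(lon1, lat), matched=True,
        path_coords=np.array([[lon0, lat], [lon1, lat]]),
        path_edge_ids=[0], fix_offsets_m=offs,
        fix_edge_ids=np.zeros(n_fixes, dtype=int),
        distance_km=length / 1000.0)


class TestSegmentTrip:
    def test_single_cell_single_hour(self):
        _, _, _, field = constant_world()
        trip = straight_trip(lon0=114.051, lon1=114.059, duration_s=600)
        segs = dx.segment_trip(trip, field)
        assert len(segs) == 1
        assert segs[0].delta_t_h == pytest.approx(600 / 3600.0)

    def test_cell_border_at_midpoint_splits_evenly(self):
        _, _, _, field = constant_world()
        # crosses the 114.06 boundary exactly halfway through
        trip = straight_trip(lon0=114.055, lon1=114.065, duration_s=600)
        segs = dx.segment_trip(trip, field)
        assert len(segs) == 2
        assert segs[0].delta_t_h == pytest.approx(segs[1].delta_t_h, rel=1e-9)
        assert segs[0].cell != segs[1].cell

    def test_hour_boundary_split(self):
        _, _, _, field = constant_world()
        trip = straight_trip(t0="2014-05-13T09:50:00", duration_s=1200,
                             lon0=114.051, lon1=114.0585)
        segs = dx.segment_trip(trip, field)
        hours = {pd.Timestamp(s.hour_start).hour for s in segs}
        assert hours == {9, 10}
        assert sum(s.delta_t_h for s in segs) == pytest.approx(1200 / 3600.0)

    def test_duration_conservation_synthetic(self, tiny_run):
        """On 100 synthetic trips the piece durations sum to the trip
        duration within 1e-9 relative."""
        field = tiny_run["field"]
        trips = tiny_run["matched"][:100]
        assert len(trips) == 100
        for trip in trips:
            segs = dx.segment_trip(trip, field)
            total = sum(s.delta_t_h for s in segs)
            assert abs(total - trip.duration_h) <= 1e-9 * trip.duration_h

    def test_trip_leaving_grid_errors(self):
        _, _, _, field = constant_world()
        trip = straight_trip(lon0=114.15, lon1=114.35)  # beyond 114.2
        with pytest.raises(DataError):
            dx.segment_trip(trip, field)


class TestTripExposure:
    def test_constant_field_closed_form(self):
        """80 ug/m3 for 0.5 h at lambda 1 -> EI 40 ug.h/m3, TWA 80."""
        _, _, _, field = constant_world(background=80.0)
        te = dx.trip_exposure(straight_trip(duration_s=1800), field)
        assert te.ei == pytest.approx(40.0, rel=1e-12)
        assert te.twa == pytest.approx(80.0, rel=1e-12)

    def test_two_cell_sum(self):
        """0.25 h at 60 then 0.25 h at 100 -> EI 40, TWA 80."""
        vals = np.full((20, 20), 60.0)
        vals[:, 10:] = 100.0  # east of 114.10
        grid = dx.AnnualGrid(114.0, 30.3, 0.01, vals)
        ts = pd.date_range("2014-05-13", periods=24, freq="h").values
        station = dx.StationSeries("S1", 114.05, 30.4, ts,
                                   np.full(24, 60.0))  # matches its cell
        field = dx.ConcentrationField(grid, station)
        trip = straight_trip(lon0=114.09, lon1=114.11, duration_s=1800)
        te = dx.trip_exposure(trip, field)
        assert te.ei == pytest.approx(0.25 * 60 + 0.25 * 100, rel=1e-6)
        assert te.twa == pytest.approx(80.0, rel=1e-6)

    def test_lambda_linearity(self, tiny_run):
        field = tiny_run["field"]
        trip = tiny_run["matched"][0]
        te1 = dx.trip_exposure(trip, field, dx.ExposureConfig(
            lambda_filtration=0.5))
        te2 = dx.trip_exposure(trip, field, dx.ExposureConfig(
            lambda_filtration=1.0))
        assert te2.ei == pytest.approx(2.0 * te1.ei, rel=1e-12)
        assert te2.twa == pytest.approx(te1.twa, rel=1e-12)

    def test_oracle_match_synthetic(self, tiny_run):
        """Segmented EI equals the ground-truth line-integral oracle
        within 0.1% per trip on 100 synthetic trips."""
        gt, field = tiny_run["gt"], tiny_run["field"]
        count = 0
        for te in tiny_run["exposures"]:
            ei_oracle, _ = gt.true_exposure(
                te.taxi_id, te.trip.time_start, te.trip.time_end, field)
            # oracle follows the true path; matched path differs by GPS
            # noise, so compare the time-weighted means
            twa_oracle = ei_oracle / te.duration_h
            assert abs(te.twa - twa_oracle) <= 2e-2 * twa_oracle
            count += 1
            if count >= 100:
                break
        assert count >= 100

    def test_oracle_match_zero_noise(self, tiny_cfg, tiny_world):
        """With sigma = 0 the pipeline EI matches the oracle to 0.1%."""
        _, _, net, field = tiny_world
        cfg = tiny_cfg.with_(gps_noise_sigma_m=0.0, n_taxis=2)
        fixes, gt = dx.gen_trajectories(cfg, net, field)
        trips = dx.extract_trips(dx.clean_fixes(fixes, cfg.extent))
        matched = dx.match_trips(trips, net)
        assert len(matched) >= 100
        for trip in matched[:100]:
            te = dx.trip_exposure(trip, field)
            ei_oracle, _ = gt.true_exposure(trip.taxi_id, trip.time_start,
                                            trip.time_end, field)
            assert abs(te.ei - ei_oracle) <= 1e-3 * ei_oracle


def fake_exposure(taxi="T1", t0="2014-05-13T10:00:00", dur_h=0.5, conc=85.0,
                  lam=1.0):
    trip = straight_trip(t0=t0, duration_s=dur_h * 3600)
    trip.taxi_id = taxi
    hour = np.datetime64(t0, "s")
    seg = dx.GridSegment(cell=(0, 0), hour_start=hour, delta_t_h=dur_h,
                         concentration=conc)
    return dx.TripExposure(trip=trip, ei=lam * conc * dur_h, twa=conc,
                           lam=lam, segments=[seg])


class TestHourlySummary:
    def test_constant_samples(self):
        tes = [fake_exposure(conc=85.0) for _ in range(5)]
        hs = dx.hourly_summary(tes)
        row = hs.loc[hs["hour"] == 10].iloc[0]
        assert row["mean"] == pytest.approx(85.0)
        assert row["ci_low"] == pytest.approx(85.0)
        assert row["ci_high"] == pytest.approx(85.0)
        assert row["n"] == 5

    def test_normal_ci_half_width(self, rng):
        """10,000 samples from N(85, 5): CI half-width ~ 1.96*5/100."""
        tes = [fake_exposure(conc=c)
               for c in rng.normal(85.0, 5.0, 10000)]
        hs = dx.hourly_summary(tes)
        row = hs.loc[hs["hour"] == 10].iloc[0]
        half = (row["ci_high"] - row["ci_low"]) / 2.0
        expected = 1.959964 * 5.0 / math.sqrt(10000)
        assert abs(half - expected) <= 0.2 * expected

    def test_day_filter_empties_hours(self):
        tes = [fake_exposure(t0="2014-05-13T10:00:00")]  # a Tuesday
        hs = dx.hourly_summary(tes, day_filter="weekend")
        assert (hs["n"] == 0).all()
        assert hs["mean"].isna().all()

    def test_single_sample_ci_equals_mean(self):
        hs = dx.hourly_summary([fake_exposure(conc=42.0)])
        row = hs.loc[hs["hour"] == 10].iloc[0]
        assert row["n"] == 1
        assert row["ci_low"] == row["mean"] == row["ci_high"] == 42.0

    def test_order_invariance(self, rng):
        tes = [fake_exposure(conc=c) for c in rng.uniform(40, 90, 50)]
        a = dx.hourly_summary(tes)
        b = dx.hourly_summary(list(reversed(tes)))
        pd.testing.assert_frame_equal(a, b)


class TestDailySummaries:
    def test_single_trip(self):
        dd, per_day, wk, we = dx.daily_summaries([fake_exposure(conc=80.0)])
        assert dd[0].daily_twa == pytest.approx(80.0)
        assert per_day["fleet_mean"].iloc[0] == pytest.approx(80.0)

    def test_two_day_sd(self):
        """Fleet values 80 and 90 -> mean 85, n-1 SD 7.071."""
        tes = [fake_exposure(t0="2014-05-13T10:00:00", conc=80.0),
               fake_exposure(t0="2014-05-14T10:00:00", conc=90.0)]
        _, _, (wk_mean, wk_sd), _ = dx.daily_summaries(tes)
        assert wk_mean == pytest.approx(85.0)
        assert wk_sd == pytest.approx(7.0710678, rel=1e-6)

    def test_weekday_weekend_split(self):
        # 2014-05-16 Fri (weekday), 2014-05-17 Sat (weekend)
        tes = [fake_exposure(t0="2014-05-16T10:00:00", conc=70.0),
               fake_exposure(t0="2014-05-17T10:00:00", conc=70.0)]
        _, _, (wk_mean, _), (we_mean, _) = dx.daily_summaries(tes)
        assert wk_mean == we_mean == pytest.approx(70.0)

    def test_daily_twa_time_weighted(self):
        tes = [fake_exposure(dur_h=0.25, conc=60.0),
               fake_exposure(dur_h=0.75, conc=100.0)]
        dd, _, _, _ = dx.daily_summaries(tes)
        assert dd[0].daily_twa == pytest.approx(
            (0.25 * 60 + 0.75 * 100) / 1.0)


class TestGuidelines:
    @pytest.mark.parametrize("c,cat", [
        (0.0, "good"), (34.99, "good"), (35.0, "moderate"), (45.5, "moderate"),
        (74.99, "moderate"), (75.0, "unhealthy_sensitive"),
        (114.99, "unhealthy_sensitive"), (115.0, "poor"), (300.0, "poor")])
    def test_classification(self, c, cat):
        assert dx.classify_air_quality(c) == cat

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            dx.classify_air_quality(-0.1)

    def test_weekday_mean_vs_who(self):
        """83.60 ug/m3 vs WHO 25: ratio 3.34 (prints 3.4), 234.4% excess."""
        ratio, excess = dx.guideline_comparison(83.60, 25.0)
        assert round(ratio, 1) == 3.3
        assert ratio * 25.0 == pytest.approx(83.60)
        assert excess == pytest.approx(234.4, abs=0.05)

    def test_weekend_mean_vs_who(self):
        ratio, _ = dx.guideline_comparison(55.62, 25.0)
        assert round(ratio, 1) == 2.2

    def test_weekday_mean_vs_china_sensitive(self):
        _, excess = dx.guideline_comparison(83.60, 75.0)
        assert excess == pytest.approx(11.47, abs=0.005)

    def test_identity(self):
        ratio, excess = dx.guideline_comparison(25.0, 25.0)
        assert ratio == 1.0 and excess == 0.0

    def test_bad_reference(self):
        with pytest.raises(DomainError):
            dx.guideline_comparison(50.0, 0.0)


def driver_days(spec):
    """spec: {taxi: (n_weekdays, n_weekend_days)} -> DriverDay list."""
    out = []
    for taxi, (nwd, nwe) in spec.items():
        d = pd.Timestamp("2014-05-05")  # a Monday
        for k in range(nwd):
            date = (d + pd.Timedelta(days=k % 5 + 7 * (k // 5))).date()
            out.append(dx.DriverDay(taxi, date, "weekday", 50.0, 5.0, 3))
        for k in range(nwe):
            date = (d + pd.Timedelta(days=5 + k % 2 + 7 * (k // 2))).date()
            out.append(dx.DriverDay(taxi, date, "weekend", 50.0, 5.0, 3))
    return out


class TestEligibilityAndExtremes:
    @pytest.mark.parametrize("nwd,nwe,eligible", [
        (10, 0, True), (9, 3, False), (0, 4, True), (9, 4, True),
        (10, 4, True), (0, 0, False)])
    def test_eligibility(self, nwd, nwe, eligible):
        ids = dx.filter_eligible_drivers(driver_days({"T1": (nwd, nwe)}))
        assert (ids == ["T1"]) == eligible

    def test_extreme_counts_200(self):
        means = {f"D{k:03d}": float(k) for k in range(200)}
        high, low = dx.select_extreme_drivers(means, 0.01)
        assert len(high) == len(low) == 2
        assert high == ["D199", "D198"]
        assert low == ["D000", "D001"]

    def test_extreme_counts_50_ceil(self):
        means = {f"D{k:02d}": float(k) for k in range(50)}
        high, low = dx.select_extreme_drivers(means, 0.01)
        assert len(high) == len(low) == 1

    def test_ties_by_id(self):
        means = {f"D{k}": 1.0 for k in range(10)}
        high, low = dx.select_extreme_drivers(means, 0.2)
        assert high == ["D0", "D1"]
        assert low == ["D0", "D1"]

    def test_empty_errors(self):
        with pytest.raises(DataError):
            dx.select_extreme_drivers({}, 0.01)
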