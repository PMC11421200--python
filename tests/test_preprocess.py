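"""Cleaning, trip extraction, and HMM map matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dynexposure as dx
from dynexposure.geo import haversine_m
from dynexposure.io_formats import fixes_to_frame

from conftest import TINY_EXTENT


def fix_frame(rows):
    """rows: (taxi_id, iso_time, lon, lat, occupied)"""
    return pd.DataFrame(
        {"taxi_id": [r[0] for r in rows],
         "timestamp": pd.to_datetime([r[1] for r in rows]),
         "lon": [r[2] for r in rows], "lat": [r[3] for r in rows],
         "heading": 0.0, "occupied": [bool(r[4]) for r in rows]})


class TestCleanFixes:
    def test_speed_rule(self):
        df = fix_frame([
            ("T1", "2014-05-13T00:00:00", 114.05, 30.40, 1),
            ("T1", "2014-05-13T00:00:10", 114.05, 34.90, 1),  # ~500 km jump
            ("T1", "2014-05-13T00:00:20", 114.051, 30.40, 1),
        ])
        out = dx.clean_fixes(df, (110, 28, 118, 36), max_speed_kmh=120)
        assert len(out) == 2
        assert 34.9 not in out["lat"].values

    def test_duplicate_timestamp_keeps_first(self):
        df = fix_frame([
            ("T1", "2014-05-13T00:00:00", 114.05, 30.40, 1),
            ("T1", "2014-05-13T00:00:00", 114.06, 30.40, 1),
        ])
        out = dx.clean_fixes(df, TINY_EXTENT)
        assert len(out) == 1
        assert out["lon"].iloc[0] == 114.05

    def test_outside_extent_dropped(self):
        df = fix_frame([
            ("T1", "2014-05-13T00:00:00", 114.05, 30.40, 1),
            ("T1", "2014-05-13T00:00:10", 113.00, 30.40, 1),
        ])
        out = dx.clean_fixes(df, TINY_EXTENT)
        assert len(out) == 1

    def test_valid_input_untouched(self, tiny_run):
        df = tiny_run["fixes"].head(1000)
        # pad the extent so boundary fixes jittered by GPS noise stay valid
        e = tiny_run["cfg"].extent
        pad = (e[0] - 0.01, e[1] - 0.01, e[2] + 0.01, e[3] + 0.01)
        out = dx.clean_fixes(df, pad, max_speed_kmh=1e6)
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), df.reset_index(drop=True))

    def test_accepts_rawfix_list(self):
        fixes = [dx.RawFix("T1", pd.Timestamp("2014-05-13").to_pydatetime(),
                           114.05, 30.4, 0.0, True)]
        out = dx.clean_fixes(fixes, TINY_EXTENT)
        assert isinstance(out, list) and len(out) == 1

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.tuples(st.integers(0, 1),  # taxi
                              st.integers(0, 300),  # time offset s
                              st.floats(114.0, 114.2),
                              st.floats(30.3, 30.5)),
                    min_size=0, max_size=20))
    def test_idempotent(self, raw):
        rows = [(f"T{t}", pd.Timestamp("2014-05-13") + pd.Timedelta(seconds=s),
                 lon, lat, 1) for t, s, lon, lat in raw]
        df = fix_frame([(a, str(b), c, d, e) for a, b, c, d, e in rows])
        df = df.sort_values(["taxi_id", "timestamp"], kind="mergesort")
        once = dx.clean_fixes(df, TINY_EXTENT, max_speed_kmh=120)
        twice = dx.clean_fixes(once, TINY_EXTENT, max_speed_kmh=120)
        pd.testing.assert_frame_equal(once.reset_index(drop=True),
                                      twice.reset_index(drop=True))


class TestExtractTrips:
    def run_statuses(self, statuses, interval_s=60):
        rows = [("T1", str(pd.Timestamp("2014-05-13")
                           + pd.Timedelta(seconds=i * interval_s)),
                 114.05 + i * 1e-3, 30.40, s)
                for i, s in enumerate(statuses)]
        return dx.extract_trips(fix_frame(rows))

    def test_single_occupied_run(self):
        trips = self.run_statuses([0, 0, 1, 1, 1, 0])
        assert len(trips) == 1
        assert trips[0].n_fixes == 3

    def test_all_vacant(self):
        assert self.run_statuses([0, 0, 0, 0]) == []

    def test_two_runs(self):
        trips = self.run_statuses([1, 1, 0, 1, 1])
        assert len(trips) == 2

    def test_min_duration_filter(self):
        trips = self.run_statuses([1, 1], interval_s=10)  # 10 s < 60 s
        assert trips == []

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.booleans(), min_size=1, max_size=40))
    def test_partitions_occupied_fixes(self, statuses):
        trips = self.run_statuses(statuses)
        # trips cover disjoint occupied stretches and never a vacant fix
        covered = []
        for tr in trips:
            for t in tr.fix_times:
                i = int((t - np.datetime64("2014-05-13", "s"))
                        .astype("timedelta64[s]").astype(int) // 60)
                assert statuses[i]
                covered.append(i)
        assert len(covered) == len(set(covered))


class TestMapMatch:
    def straight_edge_network(self):
        cfg = dx.ScenarioConfig(extent=(114.0, 30.3, 114.05, 30.31),
                                hotspots=(), network_spacing_deg=0.01)
        return dx.gen_road_network(cfg)

    def test_noise_free_single_edge(self):
        net = self.straight_edge_network()
        # fixes along the southern row, between nodes at 114.01 and 114.02
        rows = [("T1", str(pd.Timestamp("2014-05-13")
                           + pd.Timedelta(seconds=30 * i)),
                 114.011 + 0.002 * i, 30.30, 1) for i in range(5)]
        (trip,) = dx.extract_trips(fix_frame(rows))
        (m,) = dx.map_match(trip, net)
        assert len(m.path_edge_ids) == 1
        span_m = haversine_m(114.011, 30.30, 114.019, 30.30)
        assert m.distance_km * 1000 == pytest.approx(span_m, rel=1e-6)

    def test_single_fix_degenerate(self):
        net = self.straight_edge_network()
        trip = dx.Trip("T1", np.array(["2014-05-13T00:00:00"],
                                      dtype="datetime64[s]"),
                       np.array([114.0151]), np.array([30.3001]),
                       origin=(114.0151, 30.3001),
                       destination=(114.0151, 30.3001))
        (m,) = dx.map_match(trip, net)
        assert m.distance_km == 0.0
        assert len(m.path_edge_ids) == 1

    def test_no_candidate_splits_trip(self):
        net = self.straight_edge_network()
        rows = ([("T1", str(pd.Timestamp("2014-05-13")
                            + pd.Timedelta(seconds=30 * i)),
                  114.011 + 0.002 * i, 30.30, 1) for i in range(4)]
                # far off-network point mid-trip
                + [("T1", "2014-05-13 00:02:00", 114.025, 30.305, 1)]
                + [("T1", str(pd.Timestamp("2014-05-13T00:02:30")
                              + pd.Timedelta(seconds=30 * i)),
                    114.031 + 0.002 * i, 30.31, 1) for i in range(4)])
        (trip,) = dx.extract_trips(fix_frame(rows))
        parts = dx.map_match(trip, net)
        assert len(parts) == 2
        assert all(p.matched for p in parts)

    def test_zero_noise_exact_recovery(self, tiny_cfg, tiny_world):
        """Without GPS noise the ground-truth edge sequence is recovered
        for every trip."""
        _, _, net, field = tiny_world
        cfg = tiny_cfg.with_(gps_noise_sigma_m=0.0, n_taxis=2)
        fixes, gt = dx.gen_trajectories(cfg, net, field)
        trips = dx.extract_trips(dx.clean_fixes(fixes, cfg.extent))
        matched = dx.match_trips(trips, net)
        assert matched
        n_exact = 0
        for m in matched:
            ts = (m.fix_times - cfg.start_time).astype("timedelta64[s]"
                                                       ).astype(float)
            true_e = gt.paths[m.taxi_id].edge_at(ts)
            n_exact += bool(np.all(true_e == m.fix_edge_ids))
        assert n_exact == len(matched)

    def test_noisy_recovery_at_least_95pct(self, tiny_run):
        """At sigma = 10 m noise, >=95% of fixes get the true edge."""
        gt = tiny_run["gt"]
        cfg = tiny_run["cfg"]
        ok = n = 0
        for m in tiny_run["matched"]:
            ts = (m.fix_times - cfg.start_time).astype("timedelta64[s]"
                                                       ).astype(float)
            true_e = gt.paths[m.taxi_id].edge_at(ts)
            ok += int((true_e == m.fix_edge_ids).sum())
            n += len(ts)
        assert n > 1000
        assert ok / n >= 0.95

    def test_matched_distance_at_least_straight_line(self, tiny_run):
        for m in tiny_run["matched"]:
            straight = haversine_m(*m.origin, *m.destination)
            assert m.distance_km * 1000 >= straight - 25.0  # GPS noise slack

    def test_matched_path_edges_adjacent(self, tiny_run, tiny_world):
        _, _, net, _ = tiny_world
        for m in tiny_run["matched"][:50]:
            for e1, e2 in zip(m.path_edge_ids[:-1], m.path_edge_ids[1:]):
                n1 = {int(net.edge_u[e1]), int(net.edge_v[e1])}
                n2 = {int(net.edge_u[e2]), int(net.edge_v[e2])}
                assert n1 & n2, f"edges {e1},{e2} not adjacent"
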