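import numpy as np
import pytest

import dynexposure as dx

TINY_EXTENT = (114.0, 30.3, 114.2, 30.5)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small scenario (2 taxis, 1 day, 0.2 deg extent) for fast unit tests."""
    return dx.ScenarioConfig(
        n_taxis=2, n_days=1, extent=TINY_EXTENT,
        hotspots=(dx.Hotspot(114.10, 30.40, 30.0, 0.05),),
        station_locations=(("A", 114.05, 30.35), ("B", 114.15, 30.45),
                           ("C", 114.12, 30.41)),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_cfg):
    """(grid, stations, network, field) for the tiny scenario."""
    grid = dx.gen_annual_grid(tiny_cfg)
    stations = dx.gen_station_series(tiny_cfg, grid)
    network = dx.gen_road_network(tiny_cfg)
    field, ranked = dx.build_field(grid, stations)
    return grid, stations, network, field


@pytest.fixture(scope="session")
def tiny_run(tiny_cfg, tiny_world):
    """Full chain on the tiny scenario: fixes, ground truth, matched trips,
    exposures."""
    grid, stations, network, field = tiny_world
    fixes, gt = dx.gen_trajectories(tiny_cfg, network, field)
    cleaned = dx.clean_fixes(fixes, tiny_cfg.extent)
    trips = dx.extract_trips(cleaned)
    matched = dx.match_trips(trips, network)
    exposures = dx.compute_trip_exposures(matched, field)
    return {"cfg": tiny_cfg, "grid": grid, "stations": stations,
            "network": network, "field": field, "fixes": fixes, "gt": gt,
            "trips": trips, "matched": matched, "exposures": exposures}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def constant_world(extent=TINY_EXTENT, background=80.0, n_hours=24,
                   station=("S1", 114.1, 30.4)):
    """Spatially and temporally constant field: annual = station = C."""
    cfg = dx.ScenarioConfig(extent=extent, background=background, hotspots=(),
                            station_locations=(station,), episode=None,
                            diurnal=(1.0,) * 24, station_noise_sigma=0.0,
                            n_days=max(n_hours // 24, 1), seed=0)
    grid = dx.gen_annual_grid(cfg)
    stations = dx.gen_station_series(cfg, grid)
    field = dx.ConcentrationField(grid, stations[0])
    return cfg, grid, stations[0], field
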