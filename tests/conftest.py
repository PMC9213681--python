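import numpy as np
import pytest

from agrochill import (
    HourlyStationSeries,
    ScenarioKey,
    SyntheticNetworkSpec,
    WarmingScenarioSpec,
    accumulate_all_seasons,
    generate_projection_ensemble,
    generate_station_network,
    run_scenario,
    station_mean_metrics,
)


@pytest.fixture
def make_series():
    """Factory for small hand-built hourly series."""

    def _make(start, temps, station_id="T1", lat=40.0, lon=-3.0, times=None):
        temps = np.asarray(temps, dtype=float)
        if times is None:
            t0 = np.datetime64(start, "s")
            times = t0 + np.arange(temps.size) * np.timedelta64(3600, "s")
        return HourlyStationSeries(
            station_id=station_id, lat=lat, lon=lon, times=times, temps=temps
        )

    return _make


# ---------------------------------------------------------------------------
# Shared heavy fixtures (session-scoped: generated once per test run)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def network60():
    """60-station synthetic network spanning the three climate archetypes."""
    spec = SyntheticNetworkSpec(n_stations=60, years=(2000, 2020), seed=11)
    return generate_station_network(spec)


@pytest.fixture(scope="session")
def means60(network60):
    """Observed-climate station mean metrics for the 60-station network."""
    return {
        s.station_id: station_mean_metrics(accumulate_all_seasons(s))
        for s in network60
    }


@pytest.fixture(scope="session")
def ensemble60_2055_rcp85(network60):
    """Full 11-GCM ensemble run of the warmest scenario on the 60 stations."""
    sc = WarmingScenarioSpec.default("2055", "RCP8.5", seed=5)
    proj = generate_projection_ensemble(network60, sc)
    return run_scenario(network60, proj, ScenarioKey("2055", "RCP8.5"))


@pytest.fixture(scope="session")
def network12():
    """The default-sized 12-station demo network."""
    spec = SyntheticNetworkSpec(n_stations=12, years=(2000, 2020), seed=42)
    return generate_station_network(spec)


@pytest.fixture(scope="session")
def means12(network12):
    return {
        s.station_id: station_mean_metrics(accumulate_all_seasons(s))
        for s in network12
    }


@pytest.fixture(scope="session")
def scenario_ladder12(network12):
    """Ensemble runs of the mildest and warmest scenarios on the 12 stations."""
    out = {}
    for hor, rcp in (("2035", "RCP4.5"), ("2055", "RCP8.5")):
        sc = WarmingScenarioSpec.default(hor, rcp, seed=5)
        proj = generate_projection_ensemble(network12, sc)
        out[sc.label] = run_scenario(network12, proj, ScenarioKey(hor, rcp))
    return out
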