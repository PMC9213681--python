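"""Model-kernel correctness: Utah bands, Dynamic-model kinetics, GDH forms,
and seasonal accumulation over the chill/heat windows."""

import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agrochill import (
    DynamicModelState,
    SeasonWindow,
    accumulate_season,
    dynamic_portions,
    dynamic_step,
    gdh_anderson_hour,
    gdh_richardson_hour,
    utah_hour,
)
from agrochill.chill_heat import accumulate_window

# ---------------------------------------------------------------------------
# Independent oracle: literal transcription of the published Dynamic-model
# recursion (two-step precursor kinetics with deterministic portion banking),
# kept deliberately separate from the package implementation.
# ---------------------------------------------------------------------------


def dynamic_oracle(temps_c):
    e0, e1 = 4153.5, 12888.8
    a0, a1 = 139500.0, 2.567e18
    slp, tetmlt = 1.6, 277.0
    n = len(temps_c)
    tk = [t + 273.15 for t in temps_c]
    xi = []
    xs = []
    ak1 = []
    for t in tk:
        sr = math.exp(slp * tetmlt * (t - tetmlt) / t)
        xi.append(sr / (1.0 + sr))
        xs.append((a0 / a1) * math.exp((e1 - e0) / t))
        ak1.append(a1 * math.exp(-e1 / t))
    inter_e = [0.0] * n
    delt = [0.0] * n
    inter_s = 0.0
    for l in range(n):
        if l > 0:
            inter_s = inter_e[l - 1] - delt[l - 1]
        inter_e[l] = xs[l] - (xs[l] - inter_s) * math.exp(-ak1[l])
        if inter_e[l] >= 1.0:
            delt[l] = xi[l] * inter_e[l]
    return sum(delt)


# ---------------------------------------------------------------------------
# Utah model
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "temp,expected",
    [
        (-5.0, 0.0),  # sub-chilling band
        (1.4, 0.0),  # upper edge of the zero band
        (2.0, 0.5),
        (2.4, 0.5),
        (6.0, 1.0),  # full-chill band
        (9.1, 1.0),
        (10.0, 0.5),
        (12.4, 0.5),
        (14.0, 0.0),
        (15.9, 0.0),
        (17.0, -0.5),
        (18.0, -0.5),
        (20.0, -1.0),  # chill-negation band
    ],
)
def test_utah_band_weights(temp, expected):
    assert utah_hour(temp) == expected


def test_utah_vectorized_matches_scalar():
    temps = np.linspace(-10, 30, 401)
    vec = utah_hour(temps)
    assert vec.shape == temps.shape
    assert all(vec[i] == utah_hour(float(t)) for i, t in enumerate(temps))


# ---------------------------------------------------------------------------
# Dynamic model
# ---------------------------------------------------------------------------


def test_dynamic_empty_series_has_zero_portions():
    assert dynamic_portions(np.array([])) == 0.0


def test_dynamic_hot_series_banks_nothing():
    # at 45 °C the precursor is destroyed faster than formed
    assert dynamic_portions(np.full(1000, 45.0)) == 0.0


def test_dynamic_constant_six_degrees_matches_oracle():
    temps = np.full(1440, 6.0)
    assert dynamic_portions(temps) == pytest.approx(dynamic_oracle(temps), abs=1e-9)


def test_dynamic_random_series_matches_oracle():
    rng = np.random.default_rng(7)
    temps = rng.uniform(-10.0, 40.0, 1000)
    assert dynamic_portions(temps) == pytest.approx(dynamic_oracle(temps), abs=1e-9)


def test_dynamic_step_equals_loop():
    rng = np.random.default_rng(3)
    temps = rng.uniform(-5.0, 25.0, 500)
    state = DynamicModelState()
    for t in temps:
        state = dynamic_step(state, t + 273.15)
    assert state.portions == pytest.approx(dynamic_portions(temps), abs=1e-12)


def test_dynamic_portions_never_decrease():
    rng = np.random.default_rng(11)
    temps = rng.uniform(-10.0, 40.0, 300)
    state = DynamicModelState()
    prev = 0.0
    for t in temps:
        state = dynamic_step(state, t + 273.15)
        assert state.portions >= prev
        prev = state.portions


def test_dynamic_step_rejects_bad_temperature():
    with pytest.raises(ValueError):
        dynamic_step(DynamicModelState(), float("nan"))
    with pytest.raises(ValueError):
        dynamic_step(DynamicModelState(), 100.0)


def test_dynamic_stochastic_banking_close_to_deterministic():
    temps = np.full(2880, 6.0)
    det = dynamic_portions(temps)
    sto = dynamic_portions(temps, banking="stochastic", rng=np.random.default_rng(0))
    assert sto == pytest.approx(det, rel=0.1)


# ---------------------------------------------------------------------------
# Growing degree hours
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "temp,expected",
    [(4.5, 0.0), (10.0, 5.5), (25.0, 20.5), (30.0, 20.5), (0.0, 0.0)],
)
def test_gdh_richardson(temp, expected):
    assert gdh_richardson_hour(temp) == pytest.approx(expected)


@pytest.mark.parametrize(
    "temp,expected",
    [
        (4.0, 0.0),  # base
        (25.0, 21.0),  # optimum: response maximum = optimum − base
        (36.0, 0.0),  # critical endpoint
        (0.0, 0.0),
        (40.0, 0.0),
        (14.5, 10.5),  # midpoint of the rising half-cosine
    ],
)
def test_gdh_anderson_cardinal_points(temp, expected):
    assert gdh_anderson_hour(temp) == pytest.approx(expected, abs=1e-12)


def test_gdh_anderson_peaks_at_optimum():
    temps = np.linspace(4.0, 36.0, 321)
    resp = gdh_anderson_hour(temps)
    assert temps[np.argmax(resp)] == pytest.approx(25.0, abs=0.1)
    assert np.all(resp >= 0.0)


# ---------------------------------------------------------------------------
# Seasonal accumulation
# ---------------------------------------------------------------------------


def _constant_series(make_series, value):
    t0 = np.datetime64("2014-11-01T00", "s")
    t1 = np.datetime64("2015-03-01T00", "s")
    n = int((t1 - t0) / np.timedelta64(3600, "s"))
    return make_series(None, np.full(n, value), times=t0 + np.arange(n) * np.timedelta64(3600, "s"))


def test_constant_six_degree_chill_window(make_series):
    series = _constant_series(make_series, 6.0)
    m = accumulate_season(series, 2014)
    window = SeasonWindow.chill(2014)
    assert m.hours_used["chill"] == window.n_hours == 2880
    assert m.chill_utah == pytest.approx(window.n_hours * 1.0)


def test_all_missing_window_gives_zero(make_series):
    series = make_series("2014-06-01T00", np.full(24, 15.0))
    m = accumulate_season(series, 2014)
    assert m.hours_used["chill"] == 0
    assert m.chill_utah == 0.0 and m.chill_portions == 0.0
    assert not m.complete


def test_portions_monotone_in_window_end(make_series):
    rng = np.random.default_rng(2)
    series = _constant_series(make_series, 0.0)
    series.temps[:] = rng.uniform(-5.0, 15.0, series.temps.size)
    prev = 0.0
    for end_day in range(10, 110, 10):
        w = SeasonWindow(
            "chill", 2014, dt.date(2014, 11, 1), dt.date(2014, 11, 1) + dt.timedelta(days=end_day)
        )
        p = accumulate_window(series, w)["chill_portions"]
        assert p >= prev - 1e-12
        prev = p


def test_chill_window_excludes_leap_day(make_series):
    # 2016 is a leap year: season 2015 chill window must skip 29 Feb 2016
    t0 = np.datetime64("2015-11-01T00", "s")
    t1 = np.datetime64("2016-03-01T00", "s")
    n = int((t1 - t0) / np.timedelta64(3600, "s"))
    series = make_series(None, np.full(n, 6.0), times=t0 + np.arange(n) * np.timedelta64(3600, "s"))
    w = SeasonWindow.chill(2015)
    assert w.n_hours == 2880
    assert accumulate_window(series, w)["hours_used"] == 2880
    # while the heat window of season 2015 includes it
    wh = SeasonWindow.heat(2015)
    assert wh.n_hours == 24 * 99


@settings(deadline=None, max_examples=25)
@given(delta=st.floats(0.5, 5.0))
def test_warming_never_decreases_gdh(delta):
    # below the 25 °C optimum/cap both GDH responses are non-decreasing
    rng = np.random.default_rng(17)
    temps = rng.uniform(-5.0, 25.0 - delta, 500)
    for kernel in (gdh_richardson_hour, gdh_anderson_hour):
        assert kernel(temps + delta).sum() >= kernel(temps).sum() - 1e-9
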