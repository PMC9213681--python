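"""Run detection semantics (strict thresholds, maximal runs, missing-hour
splits) and the at-least-one-per-year weekly probability statistic."""

import numpy as np
import pytest

from agrochill import (
    ABNORMAL_HEAT,
    FROST,
    EventDefinition,
    detect_events,
    threshold_mask,
    week_of,
    weekly_probabilities,
)
from agrochill.event_metrics import FROST_WEEKS, HEAT_WEEKS, WeeklyProbabilityTable


# ---------------------------------------------------------------------------
# Week indexing
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "ts,week",
    [
        ("2015-01-01", 1),
        ("2015-01-07", 1),
        ("2015-01-08", 2),
        ("2015-12-05", 49),  # day-of-year 339 -> week 49
        ("2015-12-31", 52),  # day 365 fragment merged into week 52
        ("2016-12-31", 52),  # leap-year day 366 as well
        ("2015-03-11", 10),
    ],
)
def test_week_of(ts, week):
    assert week_of(ts) == week


def test_analysis_week_ranges():
    assert FROST_WEEKS == tuple(range(2, 11))
    assert HEAT_WEEKS == (49, 50, 51, 52, 1, 2, 3, 4, 5, 6, 7, 8)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def test_three_cold_hours_is_one_event(make_series):
    s = make_series("2020-01-10T03", [-2.0, -2.0, -2.0])
    (ev,) = detect_events(s, FROST)
    assert ev.duration_h == 3
    assert ev.extreme_c == -2.0
    assert ev.week == 2


def test_two_cold_hours_is_no_event(make_series):
    s = make_series("2020-01-10T03", [-5.0, -5.0])
    assert detect_events(s, FROST) == []


def test_exactly_minus_one_is_not_frost(make_series):
    s = make_series("2020-01-10T03", [-1.0] * 6)
    assert detect_events(s, FROST) == []  # strict "falls below"


def test_exactly_twenty_five_is_not_abnormal_heat(make_series):
    s = make_series("2020-02-01T12", [25.0] * 6)
    assert detect_events(s, ABNORMAL_HEAT) == []
    s2 = make_series("2020-02-01T12", [25.1] * 3)
    assert len(detect_events(s2, ABNORMAL_HEAT)) == 1


def test_long_run_counts_once(make_series):
    s = make_series("2020-01-10T00", [-3.0] * 7)
    events = detect_events(s, FROST)
    assert len(events) == 1 and events[0].duration_h == 7


def test_runs_split_by_missing_hour(make_series):
    # 4 cold hours, a missing hour, then 2 cold hours: one event only
    t0 = np.datetime64("2020-01-10T00", "s")
    offsets = [0, 1, 2, 3, 5, 6]
    times = t0 + np.array(offsets) * np.timedelta64(3600, "s")
    s = make_series(None, [-4.0] * 6, times=times)
    events = detect_events(s, FROST)
    assert len(events) == 1
    assert events[0].duration_h == 4


def test_runs_split_by_warm_hour(make_series):
    s = make_series("2020-01-10T00", [-4, -4, -4, 0.5, -4, -4, -4, -4])
    events = detect_events(s, FROST)
    assert [e.duration_h for e in events] == [3, 4]


def test_run_attributed_to_week_of_first_hour(make_series):
    # run starts 23:00 on the last day of week 1 and continues into week 2
    s = make_series("2020-01-07T23", [-3.0] * 5)
    (ev,) = detect_events(s, FROST)
    assert ev.week == 1


def test_december_events_attach_to_following_season(make_series):
    s = make_series("2019-12-05T00", [28.0] * 4)
    (ev,) = detect_events(s, ABNORMAL_HEAT)
    assert ev.week == 49
    assert ev.year == 2020


def test_custom_definition_direction_validation():
    with pytest.raises(ValueError):
        EventDefinition("x", 0.0, "sideways")
    with pytest.raises(ValueError):
        EventDefinition("x", 0.0, "below", min_consecutive_hours=0)


# ---------------------------------------------------------------------------
# Weekly probabilities
# ---------------------------------------------------------------------------


def _runs(make_series, specs):
    """Build events from (start, n_hours) cold blocks separated in time."""
    events = []
    for start, n in specs:
        s = make_series(start, [-3.0] * n)
        events.extend(detect_events(s, FROST))
    return events


def test_probability_seven_of_twentyone_years(make_series):
    # week 3 (Jan 15-21): events in 7 distinct years out of 21
    specs = [(f"{y}-01-16T02", 4) for y in range(2000, 2007)]
    events = _runs(make_series, specs)
    table = weekly_probabilities(events, n_years=21, weeks=FROST_WEEKS)
    assert table.entries[3] == pytest.approx(1 / 3)
    assert all(table.entries[w] == 0.0 for w in FROST_WEEKS if w != 3)


def test_multiple_events_in_one_week_count_once(make_series):
    specs = [("2005-01-25T01", 5), ("2005-01-26T01", 4), ("2005-01-27T01", 3)]
    events = _runs(make_series, specs)
    assert len(events) == 3  # all in week 4 of 2005
    table = weekly_probabilities(events, n_years=10, weeks=FROST_WEEKS)
    assert table.entries[4] == pytest.approx(0.1)


def test_no_events_all_zero():
    table = weekly_probabilities([], n_years=8, weeks=FROST_WEEKS)
    assert set(table.entries) == set(FROST_WEEKS)
    assert all(p == 0.0 for p in table.entries.values())


def test_probabilities_invariant_to_event_order(make_series):
    specs = [(f"{y}-02-0{d}T04", 3) for y in range(2001, 2011) for d in (1, 3)]
    events = _runs(make_series, specs)
    fwd = weekly_probabilities(events, 10, FROST_WEEKS)
    rev = weekly_probabilities(events[::-1], 10, FROST_WEEKS)
    dup = weekly_probabilities(events + events, 10, FROST_WEEKS)
    assert fwd.entries == rev.entries == dup.entries


def test_whole_series_equals_pooled_yearly_chunks(make_series):
    rng = np.random.default_rng(13)
    t0 = np.datetime64("2010-01-01T00", "s")
    n = 3 * 8760
    temps = rng.uniform(-4.0, 10.0, n)
    times = t0 + np.arange(n) * np.timedelta64(3600, "s")
    # keep the hours around each 31 Dec / 1 Jan midnight above freezing so
    # no run straddles a chunk boundary (a straddling run would be split)
    boundary = np.abs((times - times.astype("datetime64[Y]")).astype("timedelta64[h]").astype(int)) < 3
    boundary |= ((times + np.timedelta64(3, "h")).astype("datetime64[Y]") != times.astype("datetime64[Y]"))
    temps[boundary] = np.abs(temps[boundary]) + 1.0
    whole = make_series(None, temps, times=times)
    pooled = []
    years = times.astype("datetime64[Y]").astype(int) + 1970
    for y in np.unique(years):
        m = years == y
        pooled.extend(detect_events(make_series(None, temps[m], times=times[m]), FROST))
    whole_events = detect_events(whole, FROST)
    # runs straddling 31 Dec midnight may split into two, but the weekly
    # tables agree because both fragments land in already-counted weeks
    t_whole = weekly_probabilities(whole_events, 3, tuple(range(1, 53)))
    t_pool = weekly_probabilities(pooled, 3, tuple(range(1, 53)))
    assert t_whole.entries == t_pool.entries


def test_poisson_injection_recovers_rate(make_series):
    """With lambda episodes per target week per year, the yearly hit
    probability converges to 1 - exp(-lambda)."""
    rng = np.random.default_rng(99)
    lam = 0.8
    n_years = 250
    events = []
    for y in range(1500, 1500 + n_years):
        k = rng.poisson(lam)
        days = ("01-29", "01-31", "02-02")  # separate days of week 5 (doy 29-35)
        for j in range(min(k, 3)):
            events.extend(detect_events(make_series(f"{y}-{days[j]}T02", [-3.0] * 4), FROST))
    table = weekly_probabilities(events, n_years, FROST_WEEKS)
    p_expected = 1.0 - np.exp(-lam)
    se = np.sqrt(p_expected * (1 - p_expected) / n_years)
    assert abs(table.entries[5] - p_expected) <= 3 * se


def test_threshold_mask_inclusive():
    table = WeeklyProbabilityTable(
        station_id="S", kind="frost", n_years=10,
        entries={2: 0.05, 3: 0.10, 4: 0.5},
    )
    kept = threshold_mask(table, 0.10)
    assert kept.entries == {3: 0.10, 4: 0.5}
    assert threshold_mask(table, 0.0).entries == table.entries
    assert threshold_mask(table, 0.9).entries == {}
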