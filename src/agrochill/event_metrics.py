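"""Frost and abnormal winter-heat events and their weekly probabilities.

A *frost event* is a run of at least three consecutive hours strictly below
−1 °C; an *abnormal heat event* a run of at least three consecutive hours
strictly above 25 °C (a winter episode warm enough to trigger premature
dormancy release). Runs are maximal, are split by missing hours, and are
assigned to the week containing their first hour.

Weeks are fixed 7-day blocks of the calendar year: week ``w`` covers days
of year ``(w−1)·7+1 … w·7``, week 1 starting on 1 January; the 1–2 day
fragment after week 52 is merged into week 52. Frost risk is analysed over
weeks 2–10; abnormal-heat risk over weeks 49 (early December, attached to
the *following* season) through 8. The weekly probability is the number of
years in which that week had at least one event, divided by the number of
years considered.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import HourlyStationSeries

#: weeks scanned for frost risk (late-winter / spring frost exposure)
FROST_WEEKS: tuple[int, ...] = tuple(range(2, 11))
#: weeks scanned for abnormal winter heat (early Dec .. end of Feb)
HEAT_WEEKS: tuple[int, ...] = (49, 50, 51, 52, 1, 2, 3, 4, 5, 6, 7, 8)
#: default probability cutoff used when mapping risk surfaces
PROBABILITY_CUTOFF = 0.10

#: December weeks attach to the following season
_WRAP_WEEK = 49


@dataclass(frozen=True)
class EventDefinition:
    kind: str
    threshold_c: float
    direction: str  # "below" | "above", strict comparison
    min_consecutive_hours: int = 3

    def __post_init__(self) -> None:
        if self.direction not in ("below", "above"):
            raise ValueError("direction must be 'below' or 'above'")
        if self.min_consecutive_hours < 1:
            raise ValueError("min_consecutive_hours must be >= 1")


FROST = EventDefinition(kind="frost", threshold_c=-1.0, direction="below")
ABNORMAL_HEAT = EventDefinition(kind="abnormal_heat", threshold_c=25.0, direction="above")


@dataclass(frozen=True)
class EventRun:
    """One maximal qualifying run."""

    station_id: str
    kind: str
    start: np.datetime64
    duration_h: int
    extreme_c: float
    week: int
    year: int  # attribution year: December weeks count toward year + 1


def week_of(timestamp) -> int:
    """Fixed-block week index of a timestamp (week 1 starts 1 January)."""
    ts = pd.Timestamp(timestamp)
    w = (ts.dayofyear - 1) // 7 + 1
    return min(w, 52)  # day-of-year 365/366 fragment merges into week 52


def _attribution_year(ts: pd.Timestamp, week: int) -> int:
    return ts.year + 1 if week >= _WRAP_WEEK else ts.year


def detect_events(series: HourlyStationSeries, defn: EventDefinition) -> list[EventRun]:
    """Maximal runs satisfying the strict threshold comparison.

    Runs interrupted by a missing hour (a gap in the hourly record or a
    non-finite temperature) are split; each surviving segment must reach
    ``min_consecutive_hours`` on its own.
    """
    n = len(series)
    if n == 0:
        return []
    finite = np.isfinite(series.temps)
    if defn.direction == "below":
        hit = finite & (series.temps < defn.threshold_c)
    else:
        hit = finite & (series.temps > defn.threshold_c)

    # a "new run" starts where hit goes False->True or where the hourly
    # clock jumps (missing hour)
    contiguous = np.empty(n, dtype=bool)
    contiguous[0] = False
    contiguous[1:] = np.diff(series.times) == np.timedelta64(3600, "s")
    prev_hit = np.empty(n, dtype=bool)
    prev_hit[0] = False
    prev_hit[1:] = hit[:-1]
    run_start = hit & ~(prev_hit & contiguous)

    events: list[EventRun] = []
    starts = np.flatnonzero(run_start)
    for s in starts:
        e = s
        while e + 1 < n and hit[e + 1] and contiguous[e + 1]:
            e += 1
        dur = e - s + 1
        if dur < defn.min_consecutive_hours:
            continue
        seg = series.temps[s : e + 1]
        extreme = float(seg.min() if defn.direction == "below" else seg.max())
        ts = pd.Timestamp(series.times[s])
        w = week_of(ts)
        events.append(
            EventRun(
                station_id=series.station_id,
                kind=defn.kind,
                start=series.times[s],
                duration_h=int(dur),
                extreme_c=extreme,
                week=w,
                year=_attribution_year(ts, w),
            )
        )
    return events


@dataclass
class WeeklyProbabilityTable:
    """Per-station week -> occurrence probability for one event kind."""

    station_id: str
    kind: str
    n_years: int
    entries: dict[int, float] = field(default_factory=dict)

    def as_rows(self) -> list[dict]:
        return [
            {
                "station_id": self.station_id,
                "kind": self.kind,
                "week": w,
                "probability": p,
                "n_years": self.n_years,
            }
            for w, p in self.entries.items()
        ]


def weekly_probabilities(
    events: list[EventRun],
    n_years: int,
    weeks: tuple[int, ...],
    station_id: str = "",
    kind: str = "",
) -> WeeklyProbabilityTable:
    """Probability per week: years with >= 1 event in that week / n_years.

    Multiple events in the same week of the same year count once.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if events:
        station_id = station_id or events[0].station_id
        kind = kind or events[0].kind
    seen: dict[int, set[int]] = {w: set() for w in weeks}
    for ev in events:
        if ev.week in seen:
            seen[ev.week].add(ev.year)
    entries = {w: len(years) / n_years for w, years in seen.items()}
    return WeeklyProbabilityTable(
        station_id=station_id, kind=kind, n_years=n_years, entries=entries
    )


def threshold_mask(
    table: WeeklyProbabilityTable, cutoff: float = PROBABILITY_CUTOFF
) -> WeeklyProbabilityTable:
    """Drop entries with probability below ``cutoff`` (inclusive keep)."""
    return WeeklyProbabilityTable(
        station_id=table.station_id,
        kind=table.kind,
        n_years=table.n_years,
        entries={w: p for w, p in table.entries.items() if p >= cutoff},
    )


def station_event_tables(
    series: HourlyStationSeries,
    n_years: int,
    frost_defn: EventDefinition = FROST,
    heat_defn: EventDefinition = ABNORMAL_HEAT,
) -> dict[str, WeeklyProbabilityTable]:
    """Frost and abnormal-heat weekly probability tables for one station."""
    frost_ev = detect_events(series, frost_defn)
    heat_ev = detect_events(series, heat_defn)
    return {
        "frost": weekly_probabilities(
            frost_ev, n_years, FROST_WEEKS, series.station_id, frost_defn.kind
        ),
        "abnormal_heat": weekly_probabilities(
            heat_ev, n_years, HEAT_WEEKS, series.station_id, heat_defn.kind
        ),
    }


def events_to_frame(events: list[EventRun]) -> pd.DataFrame:
    cols = ["station_id", "kind", "start", "duration_h", "extreme_c", "week"]
    if not events:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(
        [
            {
                "station_id": e.station_id,
                "kind": e.kind,
                "start": e.start,
                "duration_h": e.duration_h,
                "extreme_c": e.extreme_c,
                "week": e.week,
            }
            for e in events
        ]
    )
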