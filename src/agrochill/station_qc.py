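"""Station record ingestion and completeness screening.

Mirrors the observational workflow: a network of candidate stations is
read from long-format CSV, each station is screened for per-season
completeness of its hourly record, and only stations with enough complete
seasons are retained for the climatology. Missing hours are never filled.

A season-year is *complete* when the fraction of present hourly records in
each of its two accumulation windows (chill: 1 Nov–28 Feb; heat: 1 Jan–
8 Apr) reaches ``min_fraction`` (default 0.90); a station is *retained*
when it has at least ``min_years`` (default 5) complete seasons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chill_heat import season_years_covered
from .types import HourlyStationSeries, IntegrityError, SeasonWindow

CSV_COLUMNS = ["station_id", "lat", "lon", "timestamp", "temp_c"]

DEFAULT_MIN_COMPLETE_YEARS = 5
DEFAULT_MIN_FRACTION = 0.90


@dataclass
class QcReport:
    """Completeness screening outcome for one station."""

    station_id: str
    years_total: int
    years_complete: int
    retained: bool
    fractions: dict = field(default_factory=dict)  # season_year -> {window kind: fraction}
    complete_years: list = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "station_id": self.station_id,
            "years_total": self.years_total,
            "years_complete": self.years_complete,
            "retained": self.retained,
        }


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------


def read_station_csv(path: str | Path) -> list[HourlyStationSeries]:
    """Read hourly station records from long-format CSV.

    One series per station_id, sorted by timestamp. Duplicate
    (station, timestamp) pairs and unparseable timestamps are rejected.
    """
    df = pd.read_csv(path, dtype={"station_id": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        return []
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: malformed timestamp ({exc})") from exc
    dup = df.duplicated(subset=["station_id", "timestamp"], keep=False)
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise IntegrityError(
            f"{path}: duplicate timestamp {first['timestamp']} "
            f"for station {first['station_id']}"
        )
    out = []
    for sid, grp in df.groupby("station_id", sort=True):
        grp = grp.sort_values("timestamp")
        out.append(
            HourlyStationSeries(
                station_id=str(sid),
                lat=float(grp["lat"].iloc[0]),
                lon=float(grp["lon"].iloc[0]),
                times=grp["timestamp"].to_numpy(),
                temps=grp["temp_c"].to_numpy(dtype=float),
            )
        )
    return out


def write_station_csv(stations: list[HourlyStationSeries], path: str | Path) -> None:
    frames = [s.to_frame() for s in stations]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=CSV_COLUMNS)
    )
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S", float_format="%.4f")


# --------------------------------------------------------------------------
# Screening
# --------------------------------------------------------------------------


def window_completeness(series: HourlyStationSeries, window: SeasonWindow) -> float:
    """Fraction of the window's hours present (and finite) in the record."""
    m = window.hour_mask(series.times)
    present = int(np.isfinite(series.temps[m]).sum())
    return present / window.n_hours


def screen_station(
    series: HourlyStationSeries,
    windows: list[SeasonWindow] | None = None,
    min_years: int = DEFAULT_MIN_COMPLETE_YEARS,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> QcReport:
    """Screen one station for per-season completeness.

    ``windows`` may list the chill/heat windows explicitly; by default every
    season year touched by the record is screened. A season is complete iff
    *each* of its windows reaches ``min_fraction`` coverage.
    """
    if min_years < 1:
        raise ValueError("min_years must be >= 1")
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")

    if windows is None:
        windows = []
        for y in season_years_covered(series):
            windows.append(SeasonWindow.chill(y))
            windows.append(SeasonWindow.heat(y))

    by_year: dict[int, dict[str, float]] = {}
    for w in windows:
        by_year.setdefault(w.season_year, {})[w.kind] = window_completeness(series, w)

    complete_years = sorted(
        y
        for y, fr in by_year.items()
        if fr and all(v >= min_fraction for v in fr.values())
    )
    # a season with zero coverage in every window is not a candidate year
    years_total = sum(1 for fr in by_year.values() if any(v > 0 for v in fr.values()))
    return QcReport(
        station_id=series.station_id,
        years_total=years_total,
        years_complete=len(complete_years),
        retained=len(complete_years) >= min_years,
        fractions=by_year,
        complete_years=complete_years,
    )


def screen_network(
    stations: list[HourlyStationSeries],
    min_years: int = DEFAULT_MIN_COMPLETE_YEARS,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> tuple[list[HourlyStationSeries], pd.DataFrame]:
    """Screen every station; return retained stations and the QC table."""
    reports = [
        screen_station(s, min_years=min_years, min_fraction=min_fraction)
        for s in stations
    ]
    retained = [s for s, r in zip(stations, reports) if r.retained]
    table = pd.DataFrame([r.as_row() for r in reports])
    return retained, table
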