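"""Core data containers shared across the pipeline.

The atom of the observed-climate path is :class:`HourlyStationSeries`; the
future-scenario path starts from :class:`DailyProjectionSeries` (per grid
point, per climate model, per scenario). Seasonal accumulation windows are
represented by :class:`SeasonWindow`.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TEMP_BOUNDS_C = (-40.0, 55.0)

HOUR = np.timedelta64(1, "h")


class IntegrityError(ValueError):
    """Raised when input records violate a structural contract."""


@dataclass
class HourlyStationSeries:
    """One station's hourly temperature record with metadata.

    ``times`` must be strictly increasing hourly timestamps (gaps allowed:
    missing hours are simply absent, never imputed); ``temps`` are dry-bulb
    air temperatures in °C.
    """

    station_id: str
    lat: float
    lon: float
    times: np.ndarray  # datetime64
    temps: np.ndarray  # float64, °C
    elevation: float | None = None
    archetype: str | None = None  # set by the synthetic generator, if any

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.temps = np.asarray(self.temps, dtype=float)
        if self.times.shape != self.temps.shape:
            raise ValueError("times and temps must have equal length")
        if not (-90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0):
            raise ValueError(f"station {self.station_id}: coordinates out of range")
        if self.times.size:
            if np.any(np.diff(self.times) <= np.timedelta64(0, "s")):
                raise IntegrityError(
                    f"station {self.station_id}: timestamps not strictly increasing"
                )
            lo, hi = TEMP_BOUNDS_C
            finite = self.temps[np.isfinite(self.temps)]
            if finite.size and (finite.min() < lo or finite.max() > hi):
                raise ValueError(
                    f"station {self.station_id}: temperatures outside [{lo}, {hi}] °C"
                )

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def years(self) -> np.ndarray:
        """Distinct calendar years present in the record."""
        return np.unique(self.times.astype("datetime64[Y]").astype(int) + 1970)

    def slice(self, start: dt.date, end: dt.date) -> "HourlyStationSeries":
        """Sub-series with start <= timestamp date <= end."""
        t0 = np.datetime64(start, "s")
        t1 = np.datetime64(end + dt.timedelta(days=1), "s")
        m = (self.times >= t0) & (self.times < t1)
        return HourlyStationSeries(
            self.station_id, self.lat, self.lon, self.times[m], self.temps[m],
            elevation=self.elevation, archetype=self.archetype,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "station_id": self.station_id,
                "lat": self.lat,
                "lon": self.lon,
                "timestamp": self.times,
                "temp_c": self.temps,
            }
        )


@dataclass(frozen=True)
class SeasonWindow:
    """A seasonal accumulation window.

    Chill seasons run 1 November (``season_year``) to 28 February of the
    following calendar year; 29 February never belongs to a chill window.
    Heat seasons run 1 January to 8 April of a single calendar year (29
    February included when present). A season is labeled by the calendar
    year containing its 1 November start, so heat accumulation for season
    ``y`` is computed over ``y + 1``.
    """

    kind: str  # "chill" | "heat"
    season_year: int
    start: dt.date
    end: dt.date  # inclusive

    def __post_init__(self) -> None:
        if self.kind not in ("chill", "heat"):
            raise ValueError(f"unknown window kind {self.kind!r}")
        if self.start >= self.end:
            raise ValueError("window start must precede end")

    @classmethod
    def chill(cls, season_year: int) -> "SeasonWindow":
        return cls(
            "chill",
            season_year,
            dt.date(season_year, 11, 1),
            dt.date(season_year + 1, 2, 28),
        )

    @classmethod
    def heat(cls, season_year: int) -> "SeasonWindow":
        # labeled by the chill-season convention: season y's heat window is
        # Jan 1 - Apr 8 of year y+1
        return cls(
            "heat",
            season_year,
            dt.date(season_year + 1, 1, 1),
            dt.date(season_year + 1, 4, 8),
        )

    def hour_mask(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask of timestamps inside the window (leap-aware)."""
        t0 = np.datetime64(self.start, "s")
        t1 = np.datetime64(self.end + dt.timedelta(days=1), "s")
        m = (times >= t0) & (times < t1)
        if self.kind == "chill":
            # 29 February is excluded from chill accumulation; only the
            # in-window subset needs the (slow) calendar decomposition
            idx = np.flatnonzero(m)
            if idx.size:
                days = times[idx].astype("datetime64[D]")
                months = (days.astype("datetime64[M]").astype(int) % 12) + 1
                dom = (days - days.astype("datetime64[M]")).astype(int) + 1
                m[idx[(months == 2) & (dom == 29)]] = False
        return m

    @property
    def n_hours(self) -> int:
        """Window capacity in hours (24 x days, leap-aware, chill excludes 29 Feb)."""
        ndays = (self.end - self.start).days + 1
        if self.kind == "chill":
            for y in range(self.start.year, self.end.year + 1):
                try:
                    feb29 = dt.date(y, 2, 29)
                except ValueError:
                    continue
                if self.start <= feb29 <= self.end:
                    ndays -= 1  # 29 Feb never counts toward chill capacity
        return 24 * ndays


@dataclass
class DailyProjectionSeries:
    """Projected daily Tmin/Tmax at one grid point for one climate model."""

    grid_id: str
    lat: float
    lon: float
    gcm: str
    horizon: str  # "2035" | "2055"
    rcp: str  # "RCP4.5" | "RCP8.5"
    dates: np.ndarray = field(default_factory=lambda: np.array([], dtype="datetime64[D]"))
    tmin: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))
    tmax: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.tmin = np.asarray(self.tmin, dtype=float)
        self.tmax = np.asarray(self.tmax, dtype=float)
        if not (self.dates.size == self.tmin.size == self.tmax.size):
            raise ValueError("dates, tmin, tmax must have equal length")
        if self.dates.size:
            if np.any(np.diff(self.dates) <= np.timedelta64(0, "D")):
                raise IntegrityError(
                    f"grid point {self.grid_id}/{self.gcm}: dates not strictly increasing"
                )
            if np.any(self.tmin > self.tmax + 1e-12):
                raise ValueError(
                    f"grid point {self.grid_id}/{self.gcm}: tmin exceeds tmax"
                )

    def __len__(self) -> int:
        return int(self.dates.size)
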