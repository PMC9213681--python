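"""Idealized hourly temperatures from daily Tmin/Tmax and latitude.

The future-scenario path only has projected daily minimum and maximum
temperatures, while all agroclimatic kernels are hourly. Hours are
reconstructed with the classical two-piece idealization: between sunrise
and sunset the temperature follows a sine rising from Tmin (at sunrise)
to Tmax, with the sine period stretched to ``daylength + 4`` hours so the
maximum occurs in mid-afternoon; after sunset it decays logarithmically
from the sunset temperature toward the next day's Tmin at the following
sunrise. Sunrise and sunset come from standard solar declination /
hour-angle geometry. All times are local solar time; samples sit on the
hour.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

from .types import DailyProjectionSeries, HourlyStationSeries

#: stretch of the daytime sine period beyond the photoperiod, hours
DAY_SINE_STRETCH_H = 4.0


# --------------------------------------------------------------------------
# Solar geometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SolarDay:
    """Sunrise/sunset (local solar hours) for one latitude and day of year."""

    doy: int
    lat: float
    sunrise: float
    sunset: float

    @property
    def daylength(self) -> float:
        return self.sunset - self.sunrise


def solar_declination(doy) -> np.ndarray:
    """Solar declination in radians (Cooper's formula)."""
    return np.deg2rad(23.44) * np.sin(2.0 * np.pi * (284.0 + np.asarray(doy, dtype=float)) / 365.0)


def _sunrise_sunset(lat: float, doy) -> tuple[np.ndarray, np.ndarray]:
    if not abs(lat) < 60.0:
        raise ValueError(
            f"latitude {lat}° outside supported range |lat| < 60° "
            "(polar day/night not handled)"
        )
    decl = solar_declination(doy)
    cos_ha = -np.tan(np.deg2rad(lat)) * np.tan(decl)
    ha = np.arccos(np.clip(cos_ha, -1.0, 1.0))  # hour angle at sunset, radians
    half_day = ha * 12.0 / np.pi  # hours from solar noon
    return 12.0 - half_day, 12.0 + half_day


def solar_geometry(lat: float, doy: int) -> SolarDay:
    """Sunrise/sunset for one day, symmetric about solar noon (hour 12)."""
    sr, ss = _sunrise_sunset(lat, doy)
    return SolarDay(doy=int(doy), lat=lat, sunrise=float(sr), sunset=float(ss))


# --------------------------------------------------------------------------
# Daily curve
# --------------------------------------------------------------------------


def _day_curve(
    hours: np.ndarray,
    tmin_today: float,
    tmax_today: float,
    tmin_tomorrow: float,
    sunrise: float,
    sunset: float,
    sunrise_next: float,
) -> np.ndarray:
    """Evaluate the idealized curve at arbitrary in-day hours [0, 24).

    Pre-dawn hours are modelled as the tail of an identical previous night
    (same sunset temperature, decaying toward today's Tmin at sunrise), so
    the curve is defined on the whole day even without yesterday's data.
    """
    h = np.asarray(hours, dtype=float)
    daylength = sunset - sunrise
    t_sunset = tmin_today + (tmax_today - tmin_today) * np.sin(
        np.pi * daylength / (daylength + DAY_SINE_STRETCH_H)
    )

    out = np.empty_like(h)

    day = (h >= sunrise) & (h <= sunset)
    out[day] = tmin_today + (tmax_today - tmin_today) * np.sin(
        np.pi * (h[day] - sunrise) / (daylength + DAY_SINE_STRETCH_H)
    )

    # evening: log decay from sunset temperature toward tomorrow's Tmin at
    # the next sunrise; +1 inside the log keeps the curve finite and
    # continuous at sunset. A "decay" toward a warmer tomorrow rises and is
    # capped at today's Tmax so the daily envelope is never exceeded.
    night_span = 24.0 + sunrise_next - sunset
    evening = h > sunset
    b = (t_sunset - tmin_tomorrow) / np.log(night_span + 1.0)
    out[evening] = np.minimum(
        t_sunset - b * np.log(h[evening] - sunset + 1.0), tmax_today
    )

    # pre-dawn: tail of the previous night re-targeted at today's Tmin
    predawn = h < sunrise
    span0 = 24.0 + sunrise - sunset
    b0 = (t_sunset - tmin_today) / np.log(span0 + 1.0)
    out[predawn] = np.minimum(
        t_sunset - b0 * np.log(h[predawn] + 24.0 - sunset + 1.0), tmax_today
    )
    return out


def idealize_day(
    tmin_today: float,
    tmax_today: float,
    tmin_tomorrow: float,
    solar: SolarDay,
) -> np.ndarray:
    """24 idealized hourly temperatures (hours 0..23, local solar time)."""
    if tmin_today > tmax_today:
        raise ValueError("tmin exceeds tmax")
    return _day_curve(
        np.arange(24.0),
        tmin_today,
        tmax_today,
        tmin_tomorrow,
        solar.sunrise,
        solar.sunset,
        solar.sunrise,
    )


# --------------------------------------------------------------------------
# Multi-day series
# --------------------------------------------------------------------------


def hourly_from_daily(
    dates: np.ndarray,
    tmin: np.ndarray,
    tmax: np.ndarray,
    lat: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated hourly reconstruction of a daily Tmin/Tmax series.

    Returns ``(times, temps)`` with one sample per hour. Each night decays
    toward the *following* day's Tmin at its sunrise, so the series is
    continuous at day boundaries; the last day (no tomorrow) targets its
    own Tmin.
    """
    dates = np.asarray(dates, dtype="datetime64[D]")
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    n = dates.size
    if n == 0:
        return np.array([], dtype="datetime64[s]"), np.array([], dtype=float)
    if np.any(tmin > tmax):
        raise ValueError("tmin exceeds tmax")

    doy = (dates - dates.astype("datetime64[Y]")).astype(int) + 1
    sunrise, sunset = _sunrise_sunset(lat, doy)
    daylength = sunset - sunrise
    tmin_next = np.append(tmin[1:], tmin[-1])
    sunrise_next = np.append(sunrise[1:], sunrise[-1])

    t_sunset = tmin + (tmax - tmin) * np.sin(
        np.pi * daylength / (daylength + DAY_SINE_STRETCH_H)
    )

    h = np.arange(24.0)  # in-day sample hours
    H = np.broadcast_to(h, (n, 24))
    SR = sunrise[:, None]
    SS = sunset[:, None]
    DL = daylength[:, None]

    # daytime sine
    day = (H >= SR) & (H <= SS)
    sine = tmin[:, None] + (tmax - tmin)[:, None] * np.sin(
        np.pi * (H - SR) / (DL + DAY_SINE_STRETCH_H)
    )

    # evening decay of the same day, capped at the day's own Tmax (a night
    # "decaying" toward a warmer tomorrow rises)
    night_span = (24.0 + sunrise_next - sunset)[:, None]
    b = (t_sunset[:, None] - tmin_next[:, None]) / np.log(night_span + 1.0)
    evening = np.minimum(
        t_sunset[:, None] - b * np.log(np.maximum(H - SS, 0.0) + 1.0),
        tmax[:, None],
    )

    # pre-dawn: continuation of the previous day's night decay, sharing the
    # previous day's cap so the series stays continuous at midnight
    ts_prev = np.concatenate([[t_sunset[0]], t_sunset[:-1]])
    ss_prev = np.concatenate([[sunset[0]], sunset[:-1]])
    tmax_prev = np.concatenate([[tmax[0]], tmax[:-1]])
    span_prev = 24.0 + sunrise - ss_prev
    b_prev = (ts_prev - tmin) / np.log(span_prev + 1.0)
    predawn = np.minimum(
        ts_prev[:, None]
        - b_prev[:, None] * np.log(H + 24.0 - ss_prev[:, None] + 1.0),
        tmax_prev[:, None],
    )

    temps = np.where(day, sine, np.where(H > SS, evening, predawn)).ravel()
    times = (
        dates.astype("datetime64[s]")[:, None]
        + (h.astype(int) * np.timedelta64(3600, "s"))[None, :]
    ).ravel()
    return times, temps


def idealize_projection(series: DailyProjectionSeries) -> HourlyStationSeries:
    """Hourly reconstruction of one projected daily series.

    The result uses the grid point's id and coordinates so that every
    downstream module treats reconstructed and observed series identically.
    """
    times, temps = hourly_from_daily(series.dates, series.tmin, series.tmax, series.lat)
    return HourlyStationSeries(
        station_id=series.grid_id,
        lat=series.lat,
        lon=series.lon,
        times=times,
        temps=np.clip(temps, -40.0, 55.0),
    )
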