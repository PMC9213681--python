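"""Dormancy and growth model kernels and their seasonal accumulation.

Four hourly-temperature response models are implemented:

* **Utah chill units** (Richardson-type banded weights): each hour
  contributes a piecewise-constant weight between −1 and +1 chill units
  depending on its temperature band; moderate chill temperatures count
  fully, warm hours count negatively.
* **Dynamic model chill portions** (Fishman/Erez two-step kinetics): chill
  is banked as indivisible "portions" once a thermally labile intermediate,
  formed at cool temperatures and destroyed at warm ones, completes. Unlike
  Utah units, banked portions can never be negated by later heat.
* **Richardson growing degree hours**: linear heat accumulation above a
  4.5 °C base, capped at 25 °C.
* **Anderson (ASYMCUR) growing degree hours**: an asymmetric cosine
  response with cardinal temperatures 4 °C (base), 25 °C (optimum) and
  36 °C (critical), zero outside the base–critical interval.

Seasonal totals are produced by :func:`accumulate_season`, which sums the
kernels over exactly the hours that fall inside a :class:`~agrochill.types.SeasonWindow`;
missing hours contribute nothing and are reflected in ``hours_used``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .types import HourlyStationSeries, SeasonWindow

# --------------------------------------------------------------------------
# Utah model
# --------------------------------------------------------------------------

# Band upper edges and weights; membership is (lower, upper]: a temperature
# exactly on an edge takes the weight of the band it closes (e.g. 1.4 °C
# contributes 0, 2.4 °C contributes 0.5, 9.1 °C contributes 1.0).
UTAH_EDGES_C = np.array([1.4, 2.4, 9.1, 12.4, 15.9, 18.0])
UTAH_WEIGHTS = np.array([0.0, 0.5, 1.0, 0.5, 0.0, -0.5, -1.0])


def utah_hour(temp_c):
    """Utah chill units for hourly temperature(s) in °C (vectorized)."""
    t = np.asarray(temp_c, dtype=float)
    idx = np.searchsorted(UTAH_EDGES_C, t, side="left")
    out = UTAH_WEIGHTS[idx]
    return float(out) if np.isscalar(temp_c) else out


# --------------------------------------------------------------------------
# Dynamic model
# --------------------------------------------------------------------------

# Canonical two-step kinetic parameterization (Fishman et al. 1987 /
# Erez et al. 1990). Temperatures enter in kelvin; K = °C + 273.15 here.
DYN_E0 = 4153.5
DYN_E1 = 12888.8
DYN_A0 = 139500.0
DYN_A1 = 2.567e18
DYN_SLP = 1.6
DYN_TETMLT = 277.0
KELVIN = 273.15


@dataclass(frozen=True)
class DynamicModelState:
    """State of the Dynamic-model recursion after some number of hours.

    ``intermediate`` is the precursor level *after* any banking at the end
    of the previous hour; ``portions`` is the running chill-portion total.
    """

    intermediate: float = 0.0
    portions: float = 0.0

    def __post_init__(self) -> None:
        if self.intermediate < 0 or self.portions < 0:
            raise ValueError("Dynamic-model state must be non-negative")


def _dyn_coeffs(temp_k: float) -> tuple[float, float, float]:
    """Per-hour coefficients (xi, xs, ak1) at temperature ``temp_k``."""
    ftmprt = DYN_SLP * DYN_TETMLT * (temp_k - DYN_TETMLT) / temp_k
    sr = math.exp(ftmprt)
    xi = sr / (1.0 + sr)
    xs = (DYN_A0 / DYN_A1) * math.exp((DYN_E1 - DYN_E0) / temp_k)
    ak1 = DYN_A1 * math.exp(-DYN_E1 / temp_k)
    return xi, xs, ak1


def dynamic_step(state: DynamicModelState, temp_kelvin: float) -> DynamicModelState:
    """Advance the Dynamic-model recursion by one hour at ``temp_kelvin``.

    One hour of precursor formation/destruction toward the temperature-
    dependent steady state, followed by deterministic banking: when the
    precursor reaches 1, a fraction ``xi`` of it is converted into chill
    portions and the remainder carries over.
    """
    if not math.isfinite(temp_kelvin):
        raise ValueError("non-finite temperature")
    if not (233.0 <= temp_kelvin <= 328.0):
        raise ValueError(f"temperature {temp_kelvin} K outside [233, 328] K")
    xi, xs, ak1 = _dyn_coeffs(temp_kelvin)
    x = xs - (xs - state.intermediate) * math.exp(-ak1)
    if x >= 1.0:
        delt = xi * x
        return DynamicModelState(intermediate=x - delt, portions=state.portions + delt)
    return DynamicModelState(intermediate=x, portions=state.portions)


@njit(cache=True)
def _dynamic_portions_loop(temps_k, stochastic, u):  # pragma: no cover - numba
    inter = 0.0
    portions = 0.0
    for i in range(temps_k.shape[0]):
        tk = temps_k[i]
        ftmprt = DYN_SLP * DYN_TETMLT * (tk - DYN_TETMLT) / tk
        sr = math.exp(ftmprt)
        xi = sr / (1.0 + sr)
        xs = (DYN_A0 / DYN_A1) * math.exp((DYN_E1 - DYN_E0) / tk)
        ak1 = DYN_A1 * math.exp(-DYN_E1 / tk)
        x = xs - (xs - inter) * math.exp(-ak1)
        if x >= 1.0:
            if stochastic:
                # original probabilistic variant: bank one whole portion
                # with probability xi
                if u[i] < xi:
                    portions += 1.0
                    inter = x - 1.0
                else:
                    inter = x
            else:
                delt = xi * x
                portions += delt
                inter = x - delt
        else:
            inter = x
    return portions


def dynamic_portions(
    temps_c: np.ndarray,
    *,
    banking: str = "deterministic",
    rng: np.random.Generator | None = None,
) -> float:
    """Total chill portions over an hourly °C series.

    ``banking="deterministic"`` (default) banks the fractional amount
    ``xi * x`` whenever the precursor ``x`` reaches 1 — the convention of
    the standard horticultural toolkits. ``banking="stochastic"`` restores
    the original probabilistic whole-portion variant (requires ``rng``).
    """
    t = np.ascontiguousarray(np.asarray(temps_c, dtype=float) + KELVIN)
    if t.size == 0:
        return 0.0
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite temperature in series")
    if banking == "deterministic":
        u = np.empty(0)
        return float(_dynamic_portions_loop(t, False, u))
    if banking == "stochastic":
        if rng is None:
            raise ValueError("stochastic banking requires an rng")
        u = rng.random(t.size)
        return float(_dynamic_portions_loop(t, True, u))
    raise ValueError(f"unknown banking mode {banking!r}")


# --------------------------------------------------------------------------
# Growing degree hours
# --------------------------------------------------------------------------

GDH_RICHARDSON_BASE_C = 4.5
GDH_RICHARDSON_CAP_C = 25.0

GDH_ANDERSON_BASE_C = 4.0
GDH_ANDERSON_OPTIMUM_C = 25.0
GDH_ANDERSON_CRITICAL_C = 36.0
GDH_ANDERSON_STRESS = 1.0  # stress factor F, fixed (no stress data)


def gdh_richardson_hour(temp_c):
    """Richardson GDH: max(0, min(T, 25) − 4.5) (vectorized)."""
    t = np.asarray(temp_c, dtype=float)
    out = np.maximum(0.0, np.minimum(t, GDH_RICHARDSON_CAP_C) - GDH_RICHARDSON_BASE_C)
    return float(out) if np.isscalar(temp_c) else out


def gdh_anderson_hour(temp_c):
    """Anderson ASYMCUR GDH with cardinal temperatures 4/25/36 °C (vectorized).

    Rising half-cosine from base to optimum, falling quarter-cosine from
    optimum to critical, zero outside [base, critical].
    """
    t = np.asarray(temp_c, dtype=float)
    tb, tu, tc = GDH_ANDERSON_BASE_C, GDH_ANDERSON_OPTIMUM_C, GDH_ANDERSON_CRITICAL_C
    f = GDH_ANDERSON_STRESS
    out = np.zeros_like(t)
    rising = (t >= tb) & (t <= tu)
    out = np.where(
        rising,
        f * (tu - tb) / 2.0 * (1.0 + np.cos(np.pi + np.pi * (t - tb) / (tu - tb))),
        out,
    )
    falling = (t > tu) & (t <= tc)
    out = np.where(
        falling,
        f * (tu - tb) * (1.0 + np.cos(np.pi / 2.0 + np.pi / 2.0 * (t - tu) / (tc - tu))),
        out,
    )
    return float(out) if np.isscalar(temp_c) else out


# --------------------------------------------------------------------------
# Seasonal accumulation
# --------------------------------------------------------------------------


@dataclass
class SeasonMetrics:
    """Per station-season totals of the four models."""

    station_id: str
    season_year: int
    chill_utah: float = 0.0
    chill_portions: float = 0.0
    gdh_richardson: float = 0.0
    gdh_anderson: float = 0.0
    hours_used: dict = field(default_factory=dict)  # window kind -> present hours
    complete: bool = True

    def as_dict(self) -> dict:
        return {
            "station_id": self.station_id,
            "season_year": self.season_year,
            "chill_utah": self.chill_utah,
            "chill_portions": self.chill_portions,
            "gdh_richardson": self.gdh_richardson,
            "gdh_anderson": self.gdh_anderson,
            "hours_chill": self.hours_used.get("chill", 0),
            "hours_heat": self.hours_used.get("heat", 0),
            "complete": self.complete,
        }


#: a season counts toward station means only if both windows reach this coverage
SEASON_COMPLETENESS_FRACTION = 0.90


def accumulate_window(series: HourlyStationSeries, window: SeasonWindow) -> dict:
    """Kernel sums over the hours of ``series`` inside ``window``."""
    m = window.hour_mask(series.times)
    temps = series.temps[m]
    present = np.isfinite(temps)
    temps = temps[present]
    out = {"hours_used": int(temps.size)}
    if window.kind == "chill":
        out["chill_utah"] = float(utah_hour(temps).sum()) if temps.size else 0.0
        out["chill_portions"] = dynamic_portions(temps)
    else:
        out["gdh_richardson"] = float(gdh_richardson_hour(temps).sum()) if temps.size else 0.0
        out["gdh_anderson"] = float(gdh_anderson_hour(temps).sum()) if temps.size else 0.0
    return out


def accumulate_season(series: HourlyStationSeries, season_year: int) -> SeasonMetrics:
    """Chill and heat totals of one season (chill Nov–Feb, heat Jan–8 Apr).

    A window that is not fully covered is still accumulated over the hours
    present; the metrics are flagged ``complete=False`` when either window
    has less than 90 % of its hours, so incomplete seasons can be excluded
    from station climatologies without raising.
    """
    chill_w = SeasonWindow.chill(season_year)
    heat_w = SeasonWindow.heat(season_year)
    chill = accumulate_window(series, chill_w)
    heat = accumulate_window(series, heat_w)
    complete = (
        chill["hours_used"] >= SEASON_COMPLETENESS_FRACTION * chill_w.n_hours
        and heat["hours_used"] >= SEASON_COMPLETENESS_FRACTION * heat_w.n_hours
    )
    return SeasonMetrics(
        station_id=series.station_id,
        season_year=season_year,
        chill_utah=chill["chill_utah"],
        chill_portions=chill["chill_portions"],
        gdh_richardson=heat["gdh_richardson"],
        gdh_anderson=heat["gdh_anderson"],
        hours_used={"chill": chill["hours_used"], "heat": heat["hours_used"]},
        complete=complete,
    )


def season_years_covered(series: HourlyStationSeries) -> list[int]:
    """Candidate season years: every year y with any record in chill(y) or heat(y)."""
    years = series.years
    if years.size == 0:
        return []
    return list(range(int(years.min()) - 1, int(years.max()) + 1))


def accumulate_all_seasons(
    series: HourlyStationSeries, season_years: list[int] | None = None
) -> list[SeasonMetrics]:
    if season_years is None:
        season_years = season_years_covered(series)
    out = []
    for y in season_years:
        m = accumulate_season(series, y)
        if m.hours_used["chill"] or m.hours_used["heat"]:
            out.append(m)
    return out


def station_mean_metrics(metrics: list[SeasonMetrics]) -> dict | None:
    """Mean of complete seasons per station; None if no complete season."""
    rows = [m for m in metrics if m.complete]
    if not rows:
        return None
    return {
        "station_id": rows[0].station_id,
        "n_seasons": len(rows),
        "chill_utah": float(np.mean([m.chill_utah for m in rows])),
        "chill_portions": float(np.mean([m.chill_portions for m in rows])),
        "gdh_richardson": float(np.mean([m.gdh_richardson for m in rows])),
        "gdh_anderson": float(np.mean([m.gdh_anderson for m in rows])),
    }
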