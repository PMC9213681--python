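"""Scenario runs: grid matching, per-GCM metric stacks, ensemble averages.

For each future scenario (horizon × pathway) every station is matched to
its nearest projection grid point by great-circle distance; each GCM's
daily Tmin/Tmax at that point is reconstructed to hourly temperatures,
seasonal chill/heat metrics and weekly event probabilities are computed,
metrics are averaged over season-years *within* each GCM (per-GCM
climatology first) and finally averaged across GCMs with equal weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chill_heat import accumulate_all_seasons, station_mean_metrics
from .event_metrics import FROST_WEEKS, HEAT_WEEKS, station_event_tables
from .hourly_curve import idealize_projection
from .types import DailyProjectionSeries, HourlyStationSeries

EARTH_RADIUS_KM = 6371.0

METRIC_FIELDS = ("chill_utah", "chill_portions", "gdh_richardson", "gdh_anderson")

VALID_SCENARIOS = (("2035", "RCP4.5"), ("2035", "RCP8.5"), ("2055", "RCP4.5"), ("2055", "RCP8.5"))


@dataclass(frozen=True)
class ScenarioKey:
    horizon: str
    rcp: str

    def __post_init__(self) -> None:
        if (self.horizon, self.rcp) not in VALID_SCENARIOS:
            raise ValueError(f"invalid scenario {(self.horizon, self.rcp)}")

    @property
    def label(self) -> str:
        return f"{self.horizon}_{self.rcp}"


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance on a spherical earth (km), vectorized."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlmb = np.deg2rad(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


@dataclass(frozen=True)
class GridMatch:
    station_id: str
    grid_id: str
    distance_km: float


def match_stations_to_grid(
    stations: list[HourlyStationSeries],
    grid_points: list[tuple[str, float, float]],
) -> tuple[list[GridMatch], dict]:
    """Nearest grid point per station plus distance summary statistics."""
    if not grid_points:
        raise ValueError("empty projection grid")
    gids = [g[0] for g in grid_points]
    glat = np.array([g[1] for g in grid_points])
    glon = np.array([g[2] for g in grid_points])
    matches = []
    for st in stations:
        d = haversine_km(st.lat, st.lon, glat, glon)
        k = int(np.argmin(d))
        matches.append(GridMatch(st.station_id, gids[k], float(d[k])))
    dists = np.array([m.distance_km for m in matches])
    stats = {
        "max_km": float(dists.max()),
        "min_km": float(dists.min()),
        "mean_km": float(dists.mean()),
    }
    return matches, stats


@dataclass
class EnsembleMetrics:
    """Per-station scenario result: per-GCM climatologies and their mean."""

    station_id: str
    scenario: ScenarioKey
    grid_id: str
    distance_km: float
    per_gcm: dict[str, dict] = field(default_factory=dict)  # gcm -> metric means
    ensemble_mean: dict = field(default_factory=dict)
    frost_prob: dict[int, float] = field(default_factory=dict)  # ensemble-averaged
    heat_prob: dict[int, float] = field(default_factory=dict)


def _ensemble_average(per_gcm: dict[str, dict], statistic: str = "mean") -> dict:
    fn = np.mean if statistic == "mean" else np.median
    out = {}
    for f in METRIC_FIELDS:
        out[f] = float(fn([v[f] for v in per_gcm.values()]))
    return out


def run_scenario(
    stations: list[HourlyStationSeries],
    projections: list[DailyProjectionSeries],
    scenario: ScenarioKey,
    gcm_names: tuple[str, ...] | None = None,
    statistic: str = "mean",
) -> list[EnsembleMetrics]:
    """Full metric stack per GCM and station, then ensemble-averaged.

    ``projections`` may mix scenarios; only series matching ``scenario``
    are used. A configured GCM with no series at a matched grid point is a
    hard error listing the gaps.
    """
    sel = [p for p in projections if (p.horizon, p.rcp) == (scenario.horizon, scenario.rcp)]
    if not sel:
        raise ValueError(f"no projections for scenario {scenario.label}")
    if gcm_names is None:
        gcm_names = tuple(sorted({p.gcm for p in sel}))

    by_grid: dict[str, dict[str, DailyProjectionSeries]] = {}
    coords: dict[str, tuple[float, float]] = {}
    for p in sel:
        by_grid.setdefault(p.grid_id, {})[p.gcm] = p
        coords[p.grid_id] = (p.lat, p.lon)
    grid_points = [(gid, lat, lon) for gid, (lat, lon) in sorted(coords.items())]
    matches, _ = match_stations_to_grid(stations, grid_points)

    missing = []
    for m in matches:
        have = by_grid[m.grid_id]
        missing.extend(
            f"{m.grid_id}:{g}" for g in gcm_names if g not in have
        )
    if missing:
        raise ValueError(
            f"scenario {scenario.label}: missing GCM series for {sorted(set(missing))}"
        )

    results = []
    for st, m in zip(stations, matches):
        per_gcm: dict[str, dict] = {}
        frost_acc: list[dict[int, float]] = []
        heat_acc: list[dict[int, float]] = []
        for gcm in gcm_names:
            proj = by_grid[m.grid_id][gcm]
            hourly = idealize_projection(proj)
            seasons = [s for s in accumulate_all_seasons(hourly) if s.complete]
            means = station_mean_metrics(seasons)
            if means is None:
                raise ValueError(
                    f"{m.grid_id}/{gcm}: no complete season in projection series"
                )
            per_gcm[gcm] = {f: means[f] for f in METRIC_FIELDS}
            n_years = len(seasons)
            tables = station_event_tables(hourly, n_years=n_years)
            frost_acc.append(tables["frost"].entries)
            heat_acc.append(tables["abnormal_heat"].entries)
        results.append(
            EnsembleMetrics(
                station_id=st.station_id,
                scenario=scenario,
                grid_id=m.grid_id,
                distance_km=m.distance_km,
                per_gcm=per_gcm,
                ensemble_mean=_ensemble_average(per_gcm, statistic),
                frost_prob={
                    w: float(np.mean([t[w] for t in frost_acc])) for w in FROST_WEEKS
                },
                heat_prob={
                    w: float(np.mean([t[w] for t in heat_acc])) for w in HEAT_WEEKS
                },
            )
        )
    return results


def chill_delta(
    current_means: dict[str, dict],
    future: list[EnsembleMetrics],
) -> pd.DataFrame:
    """Per-station chill lost (portions) and heat gained (Anderson GDH).

    ``current_means`` maps station_id to the observed-climate metric means;
    chill lost = current − future ensemble portions, heat gained = future −
    current GDH, so both are positive under warming.
    """
    rows = []
    for em in future:
        cur = current_means.get(em.station_id)
        if cur is None:
            continue
        rows.append(
            {
                "station_id": em.station_id,
                "scenario": em.scenario.label,
                "chill_lost_portions": cur["chill_portions"] - em.ensemble_mean["chill_portions"],
                "heat_gained_gdh": em.ensemble_mean["gdh_anderson"] - cur["gdh_anderson"],
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------


def read_projection_csv(path: str | Path) -> list[DailyProjectionSeries]:
    df = pd.read_csv(path, dtype={"grid_id": str, "gcm": str, "horizon": str, "rcp": str})
    out = []
    keys = ["grid_id", "gcm", "horizon", "rcp"]
    for (gid, gcm, hor, rcp), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("date")
        out.append(
            DailyProjectionSeries(
                grid_id=gid,
                lat=float(grp["lat"].iloc[0]),
                lon=float(grp["lon"].iloc[0]),
                gcm=gcm,
                horizon=str(hor),
                rcp=rcp,
                dates=grp["date"].to_numpy(dtype="datetime64[D]"),
                tmin=grp["tmin_c"].to_numpy(dtype=float),
                tmax=grp["tmax_c"].to_numpy(dtype=float),
            )
        )
    return out


def ensemble_to_frame(results: list[EnsembleMetrics]) -> pd.DataFrame:
    """Scenario results as one row per station with per-GCM columns."""
    rows = []
    for em in results:
        row = {
            "station_id": em.station_id,
            "scenario": em.scenario.label,
            "grid_id": em.grid_id,
            "distance_km": em.distance_km,
        }
        for f in METRIC_FIELDS:
            row[f"ensemble_{f}"] = em.ensemble_mean[f]
        for gcm in sorted(em.per_gcm):
            for f in METRIC_FIELDS:
                row[f"{gcm}:{f}"] = em.per_gcm[gcm][f]
        rows.append(row)
    return pd.DataFrame(rows)
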