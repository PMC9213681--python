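"""Station classification, inter-model agreement, and IDW surfaces.

Stations are classified by their current-climate mean chill portions into
low (<60), medium ([60, 80]) and high (>80) accumulation classes. Station
metrics are interpolated onto a regular ~5 km lat/lon grid with inverse
distance weighting (power 2 by default), valid only within 50 km of the
nearest station.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .projection import haversine_km

CHILL_CLASS_BOUNDS = (60.0, 80.0)  # low < 60 <= medium <= 80 < high
IDW_POWER = 2.0
MASK_RADIUS_KM = 50.0
GRID_CELL_DEG = 0.05  # ~5 km


def classify_station(mean_portions: float, bounds: tuple[float, float] = CHILL_CLASS_BOUNDS) -> str:
    """Chill class of a station mean: 'low' (<60), 'medium' ([60,80]), 'high' (>80)."""
    lo, hi = bounds
    if mean_portions < lo:
        return "low"
    if mean_portions <= hi:
        return "medium"
    return "high"


# --------------------------------------------------------------------------
# Inverse distance weighting
# --------------------------------------------------------------------------


@dataclass
class ScenarioSurface:
    """IDW-interpolated metric values on a regular lat/lon grid."""

    lats: np.ndarray  # cell-center latitudes (n_lat,)
    lons: np.ndarray  # cell-center longitudes (n_lon,)
    values: np.ndarray  # (n_lat, n_lon), NaN where masked
    mask: np.ndarray  # True where valid (within mask_radius of a station)
    idw_power: float = IDW_POWER
    mask_radius_km: float = MASK_RADIUS_KM
    metric: str = ""
    scenario: str = ""

    def to_frame(self) -> pd.DataFrame:
        LA, LO = np.meshgrid(self.lats, self.lons, indexing="ij")
        return pd.DataFrame(
            {
                "lat": LA.ravel(),
                "lon": LO.ravel(),
                "value": self.values.ravel(),
                "masked": ~self.mask.ravel(),
            }
        )

    def to_geojson(self, path: str | Path) -> None:
        """Valid cells as a GeoJSON FeatureCollection of points."""
        feats = []
        for i, la in enumerate(self.lats):
            for j, lo in enumerate(self.lons):
                if not self.mask[i, j]:
                    continue
                feats.append(
                    {
                        "type": "Feature",
                        "geometry": {"type": "Point", "coordinates": [round(float(lo), 6), round(float(la), 6)]},
                        "properties": {"value": round(float(self.values[i, j]), 6)},
                    }
                )
        obj = {
            "type": "FeatureCollection",
            "properties": {"metric": self.metric, "scenario": self.scenario},
            "features": feats,
        }
        Path(path).write_text(json.dumps(obj, sort_keys=True))


def regular_grid(
    bbox: tuple[float, float, float, float], cell_deg: float = GRID_CELL_DEG
) -> tuple[np.ndarray, np.ndarray]:
    """Cell-center coordinates of a regular grid covering the bbox."""
    lat0, lat1, lon0, lon1 = bbox
    lats = np.arange(lat0, lat1 + cell_deg / 2, cell_deg)
    lons = np.arange(lon0, lon1 + cell_deg / 2, cell_deg)
    return lats, lons


def idw_surface(
    station_lats: np.ndarray,
    station_lons: np.ndarray,
    values: np.ndarray,
    grid: tuple[np.ndarray, np.ndarray],
    power: float = IDW_POWER,
    mask_km: float = MASK_RADIUS_KM,
    metric: str = "",
    scenario: str = "",
    coincident_tol_km: float = 1e-6,
) -> ScenarioSurface:
    """Inverse-distance-weighted surface of station values.

    Cell value = Σ wᵢ vᵢ / Σ wᵢ with wᵢ = dᵢ^(−power) over *all* stations;
    a cell within ``coincident_tol_km`` of a station takes that station's
    value exactly (coincident stations with differing values are averaged
    with a warning); cells farther than ``mask_km`` from every station are
    masked and carry NaN.
    """
    slat = np.asarray(station_lats, dtype=float)
    slon = np.asarray(station_lons, dtype=float)
    vals = np.asarray(values, dtype=float)
    if slat.size == 0:
        raise ValueError("idw_surface requires at least one station")
    if power <= 0:
        raise ValueError("power must be > 0")
    lats, lons = grid
    LA, LO = np.meshgrid(lats, lons, indexing="ij")
    cell_lat = LA.ravel()
    cell_lon = LO.ravel()

    # (n_cells, n_stations) distance matrix
    d = haversine_km(cell_lat[:, None], cell_lon[:, None], slat[None, :], slon[None, :])
    nearest = d.min(axis=1)
    valid = nearest <= mask_km

    out = np.full(cell_lat.size, np.nan)
    at_station = d <= coincident_tol_km
    exact = at_station.any(axis=1)
    for i in np.flatnonzero(exact & valid):
        hit = vals[at_station[i]]
        if hit.size > 1 and np.ptp(hit) > 0:
            import warnings

            warnings.warn(
                "coincident stations with differing values averaged", stacklevel=2
            )
        out[i] = hit.mean()
    rest = valid & ~exact
    if rest.any():
        w = d[rest] ** (-power)
        out[rest] = (w * vals[None, :]).sum(axis=1) / w.sum(axis=1)

    n_lat, n_lon = lats.size, lons.size
    return ScenarioSurface(
        lats=lats,
        lons=lons,
        values=out.reshape(n_lat, n_lon),
        mask=valid.reshape(n_lat, n_lon),
        idw_power=power,
        mask_radius_km=mask_km,
        metric=metric,
        scenario=scenario,
    )


# --------------------------------------------------------------------------
# Agreement statistics and class summaries
# --------------------------------------------------------------------------


def model_agreement(x: np.ndarray, y: np.ndarray) -> dict:
    """OLS coefficient of determination and Pearson r on paired station means."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("model_agreement needs >= 3 paired finite values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in agreement inputs")
    r, _p = stats.pearsonr(x, y)
    return {"r2": float(r) ** 2, "pearson_r": float(r), "n": int(x.size)}


def class_summary(
    classes: list[str] | np.ndarray,
    values: np.ndarray,
    station_ids: list[str] | None = None,
    scenario: str = "",
) -> pd.DataFrame:
    """Boxplot-style summary per chill class: quartiles, whiskers, outliers.

    Whiskers follow the Tukey convention: most extreme data point within
    1.5×IQR of the nearest quartile; values beyond are listed as outliers.
    """
    classes = np.asarray(classes)
    values = np.asarray(values, dtype=float)
    if station_ids is None:
        station_ids = [f"#{i}" for i in range(values.size)]
    rows = []
    for cls in ("low", "medium", "high"):
        m = classes == cls
        if not m.any():
            continue
        v = values[m]
        ids = np.asarray(station_ids)[m]
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        out_mask = (v < lo_fence) | (v > hi_fence)
        rows.append(
            {
                "chill_class": cls,
                "scenario": scenario,
                "n": int(v.size),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "whisker_low": float(inside.min()),
                "whisker_high": float(inside.max()),
                "outliers": ";".join(sorted(ids[out_mask])),
            }
        )
    return pd.DataFrame(rows)
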