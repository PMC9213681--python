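"""End-to-end orchestration: simulate → qc → metrics → events → project →
surface → report, with a validated YAML configuration and a reproducible
run manifest.

The default configuration carries every analysis constant (frost −1 °C /
3 h; abnormal heat 25 °C / 3 h; chill window 1 Nov–28 Feb; heat window
1 Jan–8 Apr; frost weeks 2–10; heat weeks 49–8; 50 km IDW mask; 10 %
probability cutoff) plus the synthetic-network and scenario specs. Given
fixed seeds, two runs produce byte-identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chill_heat import accumulate_all_seasons, station_mean_metrics
from .event_metrics import (
    EventDefinition,
    detect_events,
    events_to_frame,
    threshold_mask,
    weekly_probabilities,
)
from .projection import ScenarioKey, chill_delta, ensemble_to_frame, run_scenario
from .spatial import class_summary, classify_station, idw_surface, model_agreement, regular_grid
from .station_qc import screen_station, write_station_csv
from .synthetic_weather import (
    ClimateArchetype,
    DEFAULT_ARCHETYPES,
    SyntheticNetworkSpec,
    WarmingScenarioSpec,
    GCM_NAMES,
    generate_projection_ensemble,
    generate_station_network,
    write_projection_csv,
)

log = logging.getLogger("agrochill")

FLOAT_FMT = "%.6f"

DEFAULT_CONFIG: dict = {
    "network": {
        "n_stations": 12,
        "bbox": [36.5, 42.5, -6.5, 1.5],
        "archetype_mix": [1 / 3, 1 / 3, 1 / 3],
        "years": [2000, 2020],
        "seed": 42,
        "climate_jitter": 0.5,
    },
    # null -> the shipped archetype defaults
    "archetypes": None,
    "qc": {"min_years": 5, "min_fraction": 0.90},
    "events": {
        "frost_threshold_c": -1.0,
        "frost_min_hours": 3,
        "heat_threshold_c": 25.0,
        "heat_min_hours": 3,
        "frost_weeks": list(range(2, 11)),
        "heat_weeks": [49, 50, 51, 52, 1, 2, 3, 4, 5, 6, 7, 8],
        "probability_cutoff": 0.10,
    },
    "scenarios": {
        "list": [["2035", "RCP4.5"], ["2035", "RCP8.5"], ["2055", "RCP4.5"], ["2055", "RCP8.5"]],
        "offsets": {"2035_RCP4.5": 1.0, "2035_RCP8.5": 1.4, "2055_RCP4.5": 1.8, "2055_RCP8.5": 2.5},
        "ensemble_size": 11,
        "gcm_spread_sd": 0.3,
        "gcms": list(GCM_NAMES),
        "statistic": "mean",
        "seed": 7,
    },
    "idw": {"power": 2.0, "mask_km": 50.0, "cell_deg": 0.05},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


class RunConfig:
    """Validated pipeline configuration (defaults merged with overrides)."""

    def __init__(self, overrides: dict | None = None):
        self.data = _deep_merge(DEFAULT_CONFIG, overrides or {})
        self.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        d = self.data
        net = d["network"]
        SyntheticNetworkSpec(
            n_stations=int(net["n_stations"]),
            bbox=tuple(net["bbox"]),
            archetype_mix=tuple(net["archetype_mix"]),
            years=tuple(net["years"]),
            seed=int(net["seed"]),
            climate_jitter=float(net["climate_jitter"]),
        )
        if not 0 < d["qc"]["min_fraction"] <= 1:
            raise ValueError("qc.min_fraction must be in (0, 1]")
        if d["qc"]["min_years"] < 1:
            raise ValueError("qc.min_years must be >= 1")
        sc = d["scenarios"]
        if sc["ensemble_size"] < 1:
            raise ValueError("scenarios.ensemble_size must be >= 1")
        if len(sc["gcms"]) < sc["ensemble_size"]:
            raise ValueError("scenarios.gcms shorter than ensemble_size")
        for hor, rcp in sc["list"]:
            key = f"{hor}_{rcp}"
            if key not in sc["offsets"]:
                raise ValueError(f"no warming offset configured for scenario {key}")
        if d["idw"]["power"] <= 0:
            raise ValueError("idw.power must be > 0")
        if d["idw"]["mask_km"] <= 0:
            raise ValueError("idw.mask_km must be > 0")

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.data, sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()

    def network_spec(self) -> SyntheticNetworkSpec:
        net = self.data["network"]
        return SyntheticNetworkSpec(
            n_stations=int(net["n_stations"]),
            bbox=tuple(net["bbox"]),
            archetype_mix=tuple(net["archetype_mix"]),
            years=tuple(net["years"]),
            seed=int(net["seed"]),
            climate_jitter=float(net["climate_jitter"]),
        )

    def archetypes(self) -> tuple[ClimateArchetype, ...]:
        raw = self.data["archetypes"]
        if raw is None:
            return DEFAULT_ARCHETYPES
        return tuple(ClimateArchetype(**a) for a in raw)

    def scenario_specs(self) -> list[WarmingScenarioSpec]:
        sc = self.data["scenarios"]
        out = []
        for hor, rcp in sc["list"]:
            out.append(
                WarmingScenarioSpec(
                    horizon=str(hor),
                    rcp=rcp,
                    mean_offset=float(sc["offsets"][f"{hor}_{rcp}"]),
                    gcm_spread_sd=float(sc["gcm_spread_sd"]),
                    ensemble_size=int(sc["ensemble_size"]),
                    seed=int(sc["seed"]),
                )
            )
        return out

    def event_definitions(self) -> tuple[EventDefinition, EventDefinition]:
        ev = self.data["events"]
        frost = EventDefinition(
            kind="frost",
            threshold_c=float(ev["frost_threshold_c"]),
            direction="below",
            min_consecutive_hours=int(ev["frost_min_hours"]),
        )
        heat = EventDefinition(
            kind="abnormal_heat",
            threshold_c=float(ev["heat_threshold_c"]),
            direction="above",
            min_consecutive_hours=int(ev["heat_min_hours"]),
        )
        return frost, heat


def _write_csv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False, float_format=FLOAT_FMT, date_format="%Y-%m-%dT%H:%M:%S")
    return len(df)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage and write the outputs plus a JSON manifest.

    Returns the manifest dict (also written to ``manifest.json``): config
    hash, package version, seeds, and per-stage output row counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash,
        "version": __version__,
        "seeds": {
            "network": config.data["network"]["seed"],
            "scenarios": config.data["scenarios"]["seed"],
        },
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()

        def done(rows: dict):
            log.info("stage %-9s %6.2fs %s", name, time.perf_counter() - t0, rows)
            manifest["stages"][name] = rows

        return done

    # -- simulate -----------------------------------------------------------
    done = stage("simulate")
    stations = generate_station_network(config.network_spec(), config.archetypes())
    write_station_csv(stations, outdir / "stations.csv")
    scenario_specs = config.scenario_specs()
    gcms = tuple(config.data["scenarios"]["gcms"][: config.data["scenarios"]["ensemble_size"]])
    projections = {}
    for spec in scenario_specs:
        projections[spec.label] = generate_projection_ensemble(stations, spec, gcms)
    all_proj = [p for plist in projections.values() for p in plist]
    write_projection_csv(all_proj, outdir / "projections.csv")
    done({"stations": len(stations), "projection_series": len(all_proj)})

    # -- qc -----------------------------------------------------------------
    done = stage("qc")
    qc = config.data["qc"]
    reports = [
        screen_station(s, min_years=qc["min_years"], min_fraction=qc["min_fraction"])
        for s in stations
    ]
    qc_df = pd.DataFrame([r.as_row() for r in reports])
    _write_csv(qc_df, outdir / "qc_report.csv")
    retained = [s for s, r in zip(stations, reports) if r.retained]
    retained_reports = {r.station_id: r for r in reports if r.retained}
    done({"stations_screened": len(stations), "stations_retained": len(retained)})
    if not retained:
        raise RuntimeError("qc: no station passed completeness screening")

    # -- metrics (current climate) ------------------------------------------
    done = stage("metrics")
    season_rows = []
    current_means: dict[str, dict] = {}
    for s in retained:
        metrics = accumulate_all_seasons(s)
        season_rows.extend(m.as_dict() for m in metrics)
        means = station_mean_metrics(metrics)
        if means is not None:
            means["lat"], means["lon"] = s.lat, s.lon
            means["archetype"] = s.archetype or ""
            current_means[s.station_id] = means
    season_df = pd.DataFrame(season_rows)
    season_df.insert(1, "scenario", "current")
    season_df.insert(2, "gcm", "observed")
    _write_csv(season_df, outdir / "season_metrics.csv")
    means_df = pd.DataFrame(list(current_means.values()))
    means_df["chill_class"] = [
        classify_station(v) for v in means_df["chill_portions"]
    ]
    _write_csv(means_df, outdir / "station_means.csv")
    done({"season_rows": len(season_df), "stations_with_means": len(means_df)})

    # -- events (current climate) -------------------------------------------
    done = stage("events")
    frost_defn, heat_defn = config.event_definitions()
    ev_cfg = config.data["events"]
    event_frames, prob_rows, sig_rows = [], [], []
    for s in retained:
        n_years = len(retained_reports[s.station_id].complete_years)
        for defn, weeks in (
            (frost_defn, tuple(ev_cfg["frost_weeks"])),
            (heat_defn, tuple(ev_cfg["heat_weeks"])),
        ):
            evs = detect_events(s, defn)
            event_frames.append(events_to_frame(evs))
            table = weekly_probabilities(evs, n_years, weeks, s.station_id, defn.kind)
            prob_rows.extend(table.as_rows())
            sig_rows.extend(
                threshold_mask(table, ev_cfg["probability_cutoff"]).as_rows()
            )
    event_frames = [f for f in event_frames if not f.empty] or event_frames[:1]
    events_df = pd.concat(event_frames, ignore_index=True)
    _write_csv(events_df, outdir / "events.csv")
    prob_df = pd.DataFrame(prob_rows)
    _write_csv(prob_df, outdir / "weekly_probabilities.csv")
    sig_cols = ["station_id", "kind", "week", "probability", "n_years"]
    sig_df = pd.DataFrame(sig_rows, columns=sig_cols)
    _write_csv(sig_df, outdir / "weekly_probabilities_significant.csv")
    done({"event_runs": len(events_df), "probability_rows": len(prob_df)})

    # -- project (future scenarios) ------------------------------------------
    done = stage("project")
    scen_frames, delta_frames = [], []
    ensembles = {}
    for spec in scenario_specs:
        key = ScenarioKey(spec.horizon, spec.rcp)
        res = run_scenario(
            retained,
            projections[spec.label],
            key,
            gcm_names=gcms,
            statistic=config.data["scenarios"]["statistic"],
        )
        ensembles[spec.label] = res
        scen_frames.append(ensemble_to_frame(res))
        delta_frames.append(chill_delta(current_means, res))
    scen_df = pd.concat(scen_frames, ignore_index=True)
    _write_csv(scen_df, outdir / "scenario_metrics.csv")
    delta_df = pd.concat(delta_frames, ignore_index=True)
    _write_csv(delta_df, outdir / "chill_delta.csv")
    done({"scenario_rows": len(scen_df), "delta_rows": len(delta_df)})

    # -- surface --------------------------------------------------------------
    done = stage("surface")
    idw = config.data["idw"]
    grid = regular_grid(tuple(config.data["network"]["bbox"]), idw["cell_deg"])
    slat = np.array([current_means[s.station_id]["lat"] for s in retained])
    slon = np.array([current_means[s.station_id]["lon"] for s in retained])
    surface_rows = 0
    surf_frames = []
    for label, vals in [
        ("current", [current_means[s.station_id]["chill_portions"] for s in retained])
    ] + [
        (lbl, [em.ensemble_mean["chill_portions"] for em in res])
        for lbl, res in ensembles.items()
    ]:
        surf = idw_surface(
            slat, slon, np.asarray(vals), grid,
            power=idw["power"], mask_km=idw["mask_km"],
            metric="chill_portions", scenario=label,
        )
        f = surf.to_frame()
        f.insert(0, "scenario", label)
        surf_frames.append(f[~f["masked"]])
        surf.to_geojson(outdir / f"surface_chill_portions_{label}.geojson")
        surface_rows += int((~f["masked"]).sum())
    _write_csv(pd.concat(surf_frames, ignore_index=True), outdir / "surfaces.csv")
    done({"valid_cells": surface_rows})

    # -- report ----------------------------------------------------------------
    done = stage("report")
    ids = [s.station_id for s in retained]
    classes = [classify_station(current_means[i]["chill_portions"]) for i in ids]
    summaries = [
        class_summary(
            classes,
            np.array([current_means[i]["chill_portions"] for i in ids]),
            ids,
            scenario="current",
        )
    ]
    for lbl, res in ensembles.items():
        summaries.append(
            class_summary(
                classes,
                np.array([em.ensemble_mean["chill_portions"] for em in res]),
                ids,
                scenario=lbl,
            )
        )
    summary_df = pd.concat(summaries, ignore_index=True)
    _write_csv(summary_df, outdir / "class_summaries.csv")

    report = {
        "n_stations_retained": len(retained),
        "class_counts": {c: int(np.sum(np.array(classes) == c)) for c in ("low", "medium", "high")},
    }
    if len(ids) >= 3:
        chill_x = [current_means[i]["chill_utah"] for i in ids]
        chill_y = [current_means[i]["chill_portions"] for i in ids]
        heat_x = [current_means[i]["gdh_richardson"] for i in ids]
        heat_y = [current_means[i]["gdh_anderson"] for i in ids]
        report["utah_vs_dynamic"] = model_agreement(chill_x, chill_y)
        report["richardson_vs_anderson"] = model_agreement(heat_x, heat_y)
        if not delta_df.empty:
            last = delta_df[delta_df["scenario"] == scenario_specs[-1].label]
            if len(last) >= 3:
                agr = model_agreement(
                    last["chill_lost_portions"].to_numpy(),
                    last["heat_gained_gdh"].to_numpy(),
                )
                report["chill_loss_vs_heat_gain"] = agr
    (outdir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2))
    done({"classes": report["class_counts"]})

    manifest["outputs"] = sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json")
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
    return manifest
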