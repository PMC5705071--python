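"""End-to-end pipeline driver.

Chains seascape synthesis -> spawning-event dispersal -> scenario network
assembly -> the three criteria (key sources, thermal refugia, low COTS
risk) -> robust-source integration and reach analysis, from one
RunConfig and one seed.  All stage seeds are derived deterministically
from the run seed, so identical (config, seed) gives identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from reefsources import io as rio
from reefsources import __version__
from reefsources.config import RunConfig, config_to_dict
from reefsources.connectivity import (CompetencyCurve, ConnectivityNetwork,
                                      assemble_all, scenario_manifest,
                                      supply_metrics)
from reefsources.cots_risk import (classify_supply, contingency_stats,
                                   external_supply_matrix, selected_threshold,
                                   sweep_thresholds)
from reefsources.dispersal import ArrestTable, run_event
from reefsources.pipeline import (notake_overlap, reach_curves, robust_sources)
from reefsources.source_metrics import identify_key_sources, network_metrics
from reefsources.synth.climate import ThermalEvent, build_sst
from reefsources.synth.currents import build_currents
from reefsources.synth.seascape import (PlantedTruth, Seascape, build_reefs,
                                        planted_centroids)
from reefsources.synth.surveys import build_surveys
from reefsources.thermal import classify_thermal

__all__ = ["RunResult", "run_pipeline", "derive_seed"]


def derive_seed(seed: int, *labels) -> int:
    """Deterministic child seed (< 2**31) from a run seed and stage labels."""
    digest = hashlib.sha256(
        ("|".join([str(seed), *map(str, labels)])).encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunResult:
    seascape: Seascape
    truth: PlantedTruth | None
    arrest_tables: list[ArrestTable]
    networks: list[ConnectivityNetwork]
    criteria: pd.DataFrame          # per-reef flags incl. is_robust_source
    key_sources: pd.DataFrame
    thermal_events: list[int]
    sweep: pd.DataFrame
    contingency: object
    surveys: pd.DataFrame
    reach: pd.DataFrame
    notake_fraction: float

    @property
    def robust_ids(self) -> set[str]:
        return set(self.criteria.index[self.criteria["is_robust_source"]])

    def jaccard_vs_truth(self) -> float | None:
        if self.truth is None:
            return None
        found = self.robust_ids
        planted = set(self.truth.robust_ids)
        union = found | planted
        return len(found & planted) / len(union) if union else 1.0


def _thermal_event_plan(cfg: RunConfig, seascape: Seascape,
                        truth: PlantedTruth | None,
                        seed: int) -> tuple[ThermalEvent, ...]:
    """Planted warming-event years; in truth mode the hotspot footprint
    excludes refuge holes around the planted robust reefs."""
    if cfg.climate.events:
        return cfg.climate.events
    rng = np.random.default_rng(derive_seed(seed, "thermal-years"))
    n_ev = min(cfg.n_thermal_events, cfg.climate.n_years)
    years = sorted(rng.choice(cfg.climate.n_years, size=n_ev, replace=False))
    holes: tuple[tuple[float, float, float], ...] = ()
    if truth is not None:
        r = cfg.seascape.planted.refuge_radius_km
        holes = tuple((x, y, r) for x, y in planted_centroids(seascape, truth))
    return tuple(ThermalEvent(year=int(y), refuge_holes=holes) for y in years)


def run_pipeline(cfg: RunConfig, seed: int,
                 outdir: str | Path | None = None) -> RunResult:
    """Execute the full analysis; optionally write the report bundle."""
    cfg.validate()

    seascape, truth = build_reefs(cfg.seascape, derive_seed(seed, "seascape"))
    span_needed = (cfg.events.release_times()[-1]
                   + cfg.dispersal.max_days * 24.0)
    field = build_currents(seascape, cfg.currents,
                           derive_seed(seed, "currents"),
                           min_span_hours=span_needed)

    tables = [
        run_event(seascape, field, event_id=f"E{i:02d}",
                  release_time_hours=t0, params=cfg.dispersal,
                  seed=derive_seed(seed, "event", i))
        for i, t0 in enumerate(cfg.events.release_times())
    ]

    curves = [CompetencyCurve(shape=k, mortality=cfg.curves.mortality)
              for k in cfg.curves.shapes]
    networks = assemble_all(tables, curves)
    regions = seascape.regions

    all_metrics = pd.concat(
        [network_metrics(net, regions) for net in networks], ignore_index=True)
    key = identify_key_sources(all_metrics, regions)

    climate_cfg = dataclasses.replace(
        cfg.climate,
        events=_thermal_event_plan(cfg, seascape, truth, seed))
    sst = build_sst(seascape, climate_cfg, derive_seed(seed, "sst"))
    thermal = classify_thermal(sst, seascape)

    supply = external_supply_matrix(networks)
    mean_supply = supply.mean(axis=0)
    if truth is not None:
        gen_cls = classify_supply(supply, truth.supply_percentile)
        surveys = build_surveys(mean_supply, cfg.surveys,
                                derive_seed(seed, "surveys"),
                                truth=truth, high_class=gen_cls.high)
    else:
        surveys = build_surveys(mean_supply, cfg.surveys,
                                derive_seed(seed, "surveys"))
    sweep = sweep_thresholds(supply, surveys)
    p_star = selected_threshold(sweep)
    cls = classify_supply(supply, float(p_star))
    stats = contingency_stats(
        classify_supply(supply, float(p_star),
                        reefs=[r for r in surveys["reef_id"]
                               if r in supply.columns]).high,
        surveys)

    retention = pd.concat(
        [supply_metrics(net)["local_retention"] for net in networks],
        axis=1).mean(axis=1)
    criteria = robust_sources(key["is_key_source"], thermal.refuge,
                              cls.low, local_retention=retention)
    robust = set(criteria.index[criteria["is_robust_source"]])

    reach = reach_curves(tables, list(supply.columns), robust,
                         durations=list(cfg.reach.durations_days),
                         steps=list(cfg.reach.steps),
                         max_days=cfg.dispersal.max_days)
    nt_frac = notake_overlap(robust, seascape)

    result = RunResult(seascape=seascape, truth=truth, arrest_tables=tables,
                       networks=networks, criteria=criteria, key_sources=key,
                       thermal_events=thermal.event_years, sweep=sweep,
                       contingency=stats, surveys=surveys, reach=reach,
                       notake_fraction=nt_frac)
    if outdir is not None:
        _write_bundle(result, cfg, seed, Path(outdir))
    return result


def _write_bundle(res: RunResult, cfg: RunConfig, seed: int, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    rio.write_seascape(res.seascape, outdir / "seascape.geojson")
    res.criteria.rename_axis("reef_id").to_csv(outdir / "criteria.csv")
    res.key_sources.rename_axis("reef_id").to_csv(outdir / "key_sources.csv")
    res.sweep.to_csv(outdir / "threshold_sweep.csv", index=False)
    res.surveys.to_csv(outdir / "surveys.csv", index=False)
    res.reach.to_csv(outdir / "reach_curves.csv", index=False)
    scenario_manifest(res.networks).to_csv(outdir / "scenario_manifest.csv",
                                           index=False)
    pd.concat([n.to_edgelist() for n in res.networks], ignore_index=True
              ).to_csv(outdir / "networks.csv", index=False)
    for t in res.arrest_tables:
        rio.write_arrests(t, outdir / f"arrests_{t.event_id}.csv")

    robust_layer = {
        "type": "FeatureCollection",
        "features": [f for f in rio.seascape_to_geojson(res.seascape)["features"]
                     if f["properties"]["id"] in res.robust_ids],
    }
    (outdir / "robust_sources.geojson").write_text(json.dumps(robust_layer))

    cfg_doc = json.dumps(config_to_dict(cfg), sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg_doc.encode()).hexdigest(),
        "n_reefs": len(res.seascape.reefs),
        "n_networks": len(res.networks),
        "thermal_event_years": res.thermal_events,
        "selected_percentile": selected_threshold(res.sweep),
        "n_robust_sources": len(res.robust_ids),
        "notake_overlap": res.notake_fraction,
        "jaccard_vs_truth": res.jaccard_vs_truth(),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
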