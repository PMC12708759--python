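"""End-to-end orchestration of the analysis on synthetic inputs.

Stages: synthetic generation -> anomalies -> coastal-band series ->
extreme events -> lag composites with bootstrap masks -> heat-budget
composite and flux/depth decomposition -> climate indices and sliding
correlations -> filtered Hovmoeller.  Every intermediate is serialized
eagerly and hashed into a manifest; identical config + seed yields
identical manifest hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anomalies, composites, events as events_mod, heat_budget, indices, synth, waves
from .errors import ConfigError
from .grids import get_region, meridional_coast_path, region_mask, write_field


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("pipeline config must be a mapping")
    return cfg


def default_config() -> dict:
    return {
        "synthetic": {
            "n_years": 21,
            "seed": 7,
            "events": [
                {"start": 26, "duration": 3, "sign": -1, "amplitude": 6.0},
                {"start": 86, "duration": 3, "sign": -1, "amplitude": 6.0},
                {"start": 146, "duration": 4, "sign": -1, "amplitude": 5.0},
                {"start": 194, "duration": 3, "sign": 1, "amplitude": 6.0},
            ],
            "wave": {"speed": 5.0, "amplitude": 6.0, "start_month": 24},
        },
        "events": {"k": 0.8, "min_duration": 2, "season": "MAM"},
        "composite": {"lags": [-3, 3], "n_resamples": 2000, "alpha": 0.05},
        "waves": {"cutoff_years": 10.0, "band_width": 1.0},
        "region": "CDNI",
    }


def run_pipeline(config: dict, outdir) -> dict:
    """Execute every stage; returns the manifest dict (also written)."""
    t0 = _time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name, **params):
        log.append({"stage": name, **params})

    syn_cfg = dict(config.get("synthetic", {}))
    seed = int(syn_cfg.get("seed", 0))
    scfg = synth.SyntheticConfig(**syn_cfg)

    # --- synthetic fields -------------------------------------------------
    fields, truth = synth.generate_fields(scfg)
    for name, f in fields.items():
        write_field(f, outdir / f"{name}.nc")
    (outdir / "truth.json").write_text(truth.to_json())
    stage("synth", seed=seed, n_years=scfg.n_years)

    # --- anomalies and coastal series ------------------------------------
    region = get_region(config.get("region", "CDNI"))
    npp_anom = anomalies.detrended_anomalies(fields["npp"])
    sel = region_mask(fields["npp"], region)
    from .grids import area_mean

    cdni = area_mean(npp_anom, sel)
    cdni.rename("nppa").to_csv(outdir / "cdni_nppa.csv")
    stage("anomalies", region=region.name)

    # --- events -----------------------------------------------------------
    ev_cfg = config.get("events", {})
    evset = events_mod.detect_extreme_events(
        cdni, k=float(ev_cfg.get("k", 0.8)),
        min_duration=int(ev_cfg.get("min_duration", 2)),
    )
    season = ev_cfg.get("season", "MAM")
    ev_season = events_mod.filter_by_peak_season(evset, season)
    events_mod.event_summary(evset).to_csv(outdir / "events.csv", index=False)
    events_mod.event_summary(ev_season).to_csv(
        outdir / "events_season.csv", index=False
    )
    stage("events", n_total=len(evset), n_season=len(ev_season), season=season)

    # --- composites -------------------------------------------------------
    comp_cfg = config.get("composite", {})
    lag_lo, lag_hi = comp_cfg.get("lags", [-3, 3])
    lags = range(int(lag_lo), int(lag_hi) + 1)
    manifest_comp = {}
    peaks = [e.peak for e in (ev_season if len(ev_season) else evset)]
    if peaks:
        comp = composites.composite_at_lags(cdni, peaks, lags)
        comp = composites.bootstrap_significance(
            cdni, comp,
            n_resamples=int(comp_cfg.get("n_resamples", 10_000)),
            alpha=float(comp_cfg.get("alpha", 0.05)),
            seed=seed,
        )
        comp.to_frame().to_csv(outdir / "composite_nppa.csv", index=False)
        manifest_comp = {"n_events": comp.n_events}
    stage("composite", **manifest_comp)

    # --- heat budget ------------------------------------------------------
    budget, _ = synth.generate_budget(scfg)
    budget.terms.to_frame().to_csv(outdir / "budget_terms.csv")
    if peaks:
        term_comp = {}
        for name in ("tot",) + heat_budget.RHS_TERMS:
            s = anomalies.anomaly_series(getattr(budget.terms, name))
            c = composites.composite_at_lags(s, peaks, lags)
            term_comp[name] = c.mean
        pd.DataFrame(term_comp, index=list(lags)).rename_axis("lag").to_csv(
            outdir / "budget_composite.csv"
        )
        at_peak = {
            n: float(v[list(lags).index(0)]) for n, v in term_comp.items() if n != "tot"
        }
        try:
            heat_budget.contribution_percentages(at_peak).to_csv(
                outdir / "budget_contributions.csv", index=False
            )
        except Exception:
            pass
    decomp = heat_budget.decompose_qnet(budget.q, budget.h)
    decomp.to_frame().to_csv(outdir / "qnet_decomposition.csv")
    stage("budget", closure=float(heat_budget.closure_residual(budget.terms).abs().max()))

    # --- indices ----------------------------------------------------------
    sst_anom = anomalies.detrended_anomalies(fields["sst"])
    sst_cdni = area_mean(sst_anom, sel)
    idx_rows = anomalies.seasonal_mean(sst_cdni, "MAM")
    npp_mam = anomalies.seasonal_mean(cdni, "MAM")
    pd.DataFrame({"sst_mam": idx_rows, "nppa_mam": npp_mam}).to_csv(
        outdir / "indices_annual.csv"
    )
    stats = indices.compare_series(sst_cdni, cdni)
    rcrit = indices.critical_r(20, 0.05)
    (outdir / "correlation_stats.json").write_text(
        json.dumps({"sst_vs_npp": stats, "critical_r_dof20": rcrit}, indent=2)
    )
    stage("indices", critical_r=rcrit)

    # --- waves ------------------------------------------------------------
    w_cfg = config.get("waves", {})
    sla_anom = anomalies.detrended_anomalies(fields["sla"])
    lats = sla_anom.lat[(sla_anom.lat >= 0) & (sla_anom.lat <= scfg.lat_max)]
    path = meridional_coast_path(lats, coast_lon=scfg.coast_lon, offset=-0.5)
    hov = waves.build_hovmoeller(
        sla_anom, path, band_width=float(w_cfg.get("band_width", 1.0))
    )
    hov_f = waves.filter_hovmoeller(
        hov, cutoff_period_years=float(w_cfg.get("cutoff_years", 10.0))
    )
    hov_f.to_frame().to_csv(outdir / "hovmoeller_sla.csv")
    stage("waves", n_positions=len(hov_f.positions))

    # --- manifest ---------------------------------------------------------
    artifacts = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": _jsonable(config),
        "seed": seed,
        "stages": log,
        "artifacts": {a: _sha256(outdir / a) for a in artifacts},
        "wall_seconds": round(_time.time() - t0, 3),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
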