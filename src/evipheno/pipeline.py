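"""End-to-end orchestration: preprocess -> phenology -> compare -> drivers -> trends -> EVI models.

A pipeline run is driven by a single YAML config mapping sites to their EVI
(or reflectance) and daily-climate CSVs plus every tunable of the underlying
stages.  All products are written as CSV/JSON into the output directory
together with a manifest (config hash, seed, package version, completed
stages) so a run is reproducible and auditable.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .series import EviSeries, read_index_csv, write_series_csv
from .evi import (
    SmoothingParams,
    average_pixels,
    bise_correct,
    fft_smooth,
    monthly_mean_evi,
    read_reflectance_csv,
)
from .phenology import (
    METRIC_COLUMNS,
    DetectionParams,
    compare_sites,
    extract_all_metrics,
)
from .climate import (
    aggregate_monthly,
    compare_models,
    enumerate_windows,
    mean_event_month,
    mlr_evi_model,
    predictor_matrix,
    rf_evi_model,
    stepwise_mlr,
    trend_fit,
)

logger = logging.getLogger(__name__)

STAGES = ("preprocess", "phenology", "compare", "drivers", "trends", "evimodel")


@dataclass
class SiteConfig:
    site_id: str
    evi_csv: str | None = None
    reflectance_csv: str | None = None
    climate_csv: str | None = None


@dataclass
class PipelineConfig:
    """Everything a run needs; every stage tunable appears exactly once."""

    sites: list[SiteConfig]
    outdir: str
    seed: int = 0
    smoothing: SmoothingParams = field(default_factory=SmoothingParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    rain_day_min: float = 1.0
    stepwise_top_k: int = 10
    stepwise_p_enter: float = 0.05
    stepwise_p_remove: float = 0.10
    vif_limit: float = 10.0
    rf_n_trees_grid: tuple = (250, 500)
    rf_leaf_grid: tuple = (1, 3, 5)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sites = [SiteConfig(**s) for s in raw.pop("sites")]
        smoothing = SmoothingParams(**raw.pop("smoothing", {}))
        det = raw.pop("detection", {})
        for key in ("spring_search_window", "autumn_search_window"):
            if key in det:
                det[key] = tuple(det[key])
        detection = DetectionParams(**det)
        for key in ("rf_n_trees_grid", "rf_leaf_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sites=sites, smoothing=smoothing, detection=detection, **raw)

    def validate(self) -> None:
        if not self.sites:
            raise ValueError("config lists no sites")
        for s in self.sites:
            if not (s.evi_csv or s.reflectance_csv):
                raise ValueError(f"site {s.site_id}: no EVI or reflectance input")
            for p in (s.evi_csv, s.reflectance_csv, s.climate_csv):
                if p is not None and not Path(p).exists():
                    raise ValueError(f"site {s.site_id}: missing input file {p}")

    def hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _nan_to_none(obj):
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, dict):
        return {k: _nan_to_none(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_nan_to_none(v) for v in obj]
    return obj


def _preprocess_site(site: SiteConfig, params: SmoothingParams) -> EviSeries:
    if site.evi_csv:
        pixels = read_index_csv(site.evi_csv)
    else:
        pixels = read_reflectance_csv(site.reflectance_csv)
    pixels = {k: v for k, v in pixels.items() if k[0] == site.site_id} or pixels
    corrected = [bise_correct(s, params) for s in pixels.values()]
    site_mean = corrected[0] if len(corrected) == 1 else average_pixels(corrected)
    return fft_smooth(site_mean, params)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, writing CSV/JSON products and a manifest.

    Any stage failure aborts with the stage name and the offending input in
    the exception message.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    completed = []
    smoothed: dict[str, EviSeries] = {}
    metrics: dict[str, pd.DataFrame] = {}
    monthly_climate: dict[str, pd.DataFrame] = {}

    stage = "preprocess"
    try:
        for site in config.sites:
            smoothed[site.site_id] = _preprocess_site(site, config.smoothing)
            if site.climate_csv:
                daily = pd.read_csv(site.climate_csv, parse_dates=["date"])
                monthly_climate[site.site_id] = aggregate_monthly(
                    daily, rain_day_min=config.rain_day_min
                )
        write_series_csv(outdir / "smoothed_series.csv", list(smoothed.values()))
        completed.append(stage)

        stage = "phenology"
        for sid, series in smoothed.items():
            metrics[sid] = extract_all_metrics(series, config.detection)
        pd.concat(metrics.values(), ignore_index=True).to_csv(
            outdir / "phenology_metrics.csv", index=False
        )
        completed.append(stage)

        stage = "compare"
        if len(config.sites) >= 2:
            a, b = config.sites[0].site_id, config.sites[1].site_id
            comparison = compare_sites(metrics[a], metrics[b])
            comparison.insert(0, "site_a", a)
            comparison.insert(1, "site_b", b)
            comparison.to_csv(outdir / "site_comparison.csv", index=False)
        completed.append(stage)

        stage = "drivers"
        specs = enumerate_windows()
        drivers: dict[str, dict] = {}
        for sid, table in metrics.items():
            if sid not in monthly_climate:
                continue
            drivers[sid] = {}
            tbl = table.set_index("year")
            for metric in METRIC_COLUMNS:
                y = tbl[metric].astype(float)
                if y.notna().sum() < 5:
                    continue
                if metric in ("max_evi", "min_evi"):
                    anchor_col = {"max_evi": "max_date", "min_evi": "min_date"}[metric]
                    offset, month = mean_event_month(tbl[anchor_col])
                elif metric in ("sdd", "ard", "dpd"):
                    end_col = {"sdd": "sde", "ard": "are", "dpd": "dpe"}[metric]
                    offset, month = mean_event_month(tbl[end_col])
                else:
                    offset, month = mean_event_month(y)
                anchors = [(int(yr) + offset, month) for yr in tbl.index]
                X = predictor_matrix(monthly_climate[sid], specs, anchors, index=tbl.index)
                res = stepwise_mlr(
                    y, X, response_name=metric, top_k=config.stepwise_top_k,
                    p_enter=config.stepwise_p_enter, p_remove=config.stepwise_p_remove,
                    vif_limit=config.vif_limit,
                )
                drivers[sid][metric] = {
                    "selected": res.selected,
                    "coefficients": res.coefficients,
                    "r2": res.r2,
                    "p": res.model_p,
                    "dropped_collinear": res.dropped_collinear,
                }
        (outdir / "drivers.json").write_text(json.dumps(_nan_to_none(drivers), indent=2))
        completed.append(stage)

        stage = "trends"
        trend_rows = []
        for sid, table in metrics.items():
            tbl = table.set_index("year")
            for metric in METRIC_COLUMNS:
                v = tbl[metric].astype(float)
                if v.notna().sum() < 3:
                    continue
                t = trend_fit(v, name=metric)
                trend_rows.append({"site": sid, "metric": metric, "slope": t.slope,
                                   "intercept": t.intercept, "p": t.p,
                                   "n_years": t.n_years})
        pd.DataFrame(trend_rows).to_csv(outdir / "trends.csv", index=False)
        completed.append(stage)

        stage = "evimodel"
        evimodels: dict[str, dict] = {}
        for sid, series in smoothed.items():
            if sid not in monthly_climate:
                continue
            mevi = monthly_mean_evi(series)
            mlr = mlr_evi_model(mevi, monthly_climate[sid])
            rf = rf_evi_model(mevi, monthly_climate[sid], seed=config.seed,
                              n_trees_grid=config.rf_n_trees_grid,
                              leaf_grid=config.rf_leaf_grid)
            evimodels[sid] = compare_models(mlr, rf)
            evimodels[sid]["rf_best_params"] = rf.best_params
            evimodels[sid]["rf_split_sizes"] = list(rf.split_sizes)
        (outdir / "evi_models.json").write_text(json.dumps(_nan_to_none(evimodels), indent=2))
        completed.append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": completed,
        "sites": [s.site_id for s in config.sites],
        "products": sorted(p.name for p in outdir.iterdir() if p.suffix in (".csv", ".json")),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def report(outdir) -> str:
    """Human-readable summary rendered from the written products only."""
    outdir = Path(outdir)
    lines = []
    warn = lines.append
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"pipeline run {manifest['config_hash']} "
                     f"(seed {manifest['seed']}, v{manifest['version']})")
        lines.append(f"completed stages: {', '.join(manifest['stages'])}")
    else:
        warn("WARNING: no manifest found; partial report")

    comp_path = outdir / "site_comparison.csv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path)
        lines.append("")
        lines.append(f"site comparison ({comp['site_a'][0]} - {comp['site_b'][0]}):")
        lines.append(f"{'metric':>10} {'mean_a':>8} {'mean_b':>8} {'diff':>8} {'p':>8}")
        for _, r in comp.iterrows():
            p = "   --" if pd.isna(r["p"]) else f"{r['p']:8.3g}"
            lines.append(f"{r['metric']:>10} {r['mean_a']:8.3g} {r['mean_b']:8.3g} "
                         f"{r['difference']:8.3g} {p:>8}")

    drv_path = outdir / "drivers.json"
    if drv_path.exists():
        drivers = json.loads(drv_path.read_text())
        lines.append("")
        lines.append("climate drivers (stepwise MLR):")
        for sid, table in drivers.items():
            for metric, res in table.items():
                sel = ", ".join(res["selected"]) if res["selected"] else "none selected"
                r2 = res["r2"] if res["r2"] is not None else float("nan")
                lines.append(f"  {sid}/{metric}: {sel} (R2={r2:.2f})")

    trends_path = outdir / "trends.csv"
    if trends_path.exists():
        trends = pd.read_csv(trends_path)
        sig = trends[trends["p"] < 0.05]
        lines.append("")
        lines.append(f"interannual trends: {len(sig)}/{len(trends)} significant at p<0.05")
        for _, r in sig.iterrows():
            lines.append(f"  {r['site']}/{r['metric']}: {r['slope']:+.2f}/yr (p={r['p']:.3g})")

    evi_path = outdir / "evi_models.json"
    if evi_path.exists():
        models = json.loads(evi_path.read_text())
        lines.append("")
        lines.append("monthly-EVI models (MLR vs random forest):")
        for sid, m in models.items():
            lines.append(f"  {sid}: MLR R2={m['mlr_r2']:.2f} RMSE={m['mlr_rmse']:.3f} "
                         f"[{', '.join(m['mlr_selected'])}]")
            lines.append(f"  {sid}: RF  R2(test)={m['rf_r2_test']:.2f} "
                         f"RMSE(test)={m['rf_rmse_test']:.3f}; "
                         f"MLR predictors in RF top-10: {m['overlap_count']}")
    return "\n".join(lines)
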