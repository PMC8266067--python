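"""End-to-end orchestration: inputs -> gridding -> PCS -> regressions -> summaries.

A single :class:`PipelineConfig` drives the whole analysis.  Every stochastic
step (null model, subsampling) derives its stream from the master seed, so a
rerun with the same configuration and inputs is byte-identical apart from
timestamps in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from paleopcs import grid as grid_mod
from paleopcs import deglaciation as deglac_mod
from paleopcs import stationarity as stat_mod
from paleopcs.pcs import ses_pcs
from paleopcs.spatial import idw_interpolate
from paleopcs.tree import (bladj_date, cophenetic_distances, merge_taxa,
                           prune_clade, read_node_ages, read_tree)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sites: str = "sites.csv"
    climate: str = "climate.csv"
    ice: str = "ice.csv"
    tree: str = "tree.nwk"
    node_ages: str = "node_ages.csv"
    output_dir: str = "results"
    grid_resolution: float = 0.5
    quality_threshold: float = 0.75
    null_runs: int = 999
    trial_swaps: int = 1000
    null_model: str = "independentswap"
    distances_km: list = field(default_factory=lambda: [120.0, 360.0, 480.0])
    min_sites_per_slice: int = 10
    equal_n: int | None = None  # equal-sample-size sensitivity, rows per slice
    alpha: float = 0.05
    seed: int = 0
    merge_groups: list = field(default_factory=list)  # [[members...], name]
    prune_tips: list = field(default_factory=list)
    variables: list = field(default_factory=lambda: list(grid_mod.CLIMATE_VARIABLES))
    include_deglac_variable: bool = True
    metrics: list = field(default_factory=lambda: ["nri", "nti"])
    idw_power: float = 2.0
    record_start_ka: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(cfg) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)

    def validate(self) -> None:
        if not 0 <= self.quality_threshold <= 1:
            raise ValueError("quality_threshold must be in [0, 1]")
        if self.grid_resolution <= 0 or self.null_runs < 1:
            raise ValueError("invalid grid resolution or null run count")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Schema, range and cross-file consistency checks (report only)."""
    issues: list[str] = []
    try:
        sites = pd.read_csv(config.sites)
    except Exception as exc:
        return [f"sites: unreadable ({exc})"]
    for col in grid_mod.SITE_COLUMNS:
        if col not in sites.columns:
            issues.append(f"sites: missing column {col!r}")
    if "rel_abund" in sites.columns:
        bad = sites.index[sites["rel_abund"] < 0]
        for i in bad:
            issues.append(f"sites row {i}: negative abundance")
    if {"lon", "lat"} <= set(sites.columns):
        if ((sites["lon"].abs() > 180) | (sites["lat"].abs() > 90)).any():
            issues.append("sites: coordinates out of range")
    try:
        tree = _prepare_tree(config)
        tree_taxa = set(tree.tip_labels)
        if "taxon" in sites.columns:
            missing = sorted(set(sites["taxon"]) - tree_taxa)
            for t in missing:
                issues.append(f"taxon {t!r} in sites but not in tree")
    except Exception as exc:
        issues.append(f"tree: {exc}")
    try:
        climate = pd.read_csv(config.climate)
        if {"cell_lon", "cell_lat"} <= set(climate.columns) and not sites.empty:
            res = config.grid_resolution
            site_cells = set(zip(np.floor(sites["lon"] / res) * res,
                                 np.floor(sites["lat"] / res) * res,
                                 sites["time_ka"]))
            clim_cells = set(zip(climate["cell_lon"], climate["cell_lat"],
                                 climate["time_ka"]))
            orphans = site_cells - clim_cells
            if orphans:
                issues.append(f"{len(orphans)} site cells lack climate rows")
    except Exception as exc:
        issues.append(f"climate: {exc}")
    return issues


def _prepare_tree(config: PipelineConfig):
    tree = read_tree(config.tree)
    if config.merge_groups:
        groups = [(members, name) for members, name in config.merge_groups]
        tree = merge_taxa(tree, groups)
    ages = read_node_ages(config.node_ages)
    if not tree.is_fully_dated():
        tree = bladj_date(tree, ages)
    else:
        # fully dated input: BLADJ is a no-op but validates consistency
        tree = bladj_date(tree, {k: v for k, v in ages.items()
                                 if k in {n.label for n in tree.preorder()}})
    if config.prune_tips:
        tree = prune_clade(tree, config.prune_tips)
    return tree


def compute_pcs(gridded: pd.DataFrame, D: pd.DataFrame,
                config: PipelineConfig) -> pd.DataFrame:
    """NRI/NTI per (cell, slice): one null per time slice (taxon pools are
    contemporaneous; cross-slice swaps would mix non-coexisting taxa)."""
    ss = np.random.SeedSequence(config.seed)
    slices = sorted(gridded["time_ka"].unique())
    streams = dict(zip(slices, ss.spawn(len(slices))))
    pieces = []
    for t in slices:
        mat = grid_mod.occurrence_matrix(gridded, t, taxa=list(D.index))
        if mat.empty:
            continue
        res = ses_pcs(mat, D, n_runs=config.null_runs,
                      n_trial_swaps=config.trial_swaps, seed=streams[t],
                      null_model=config.null_model)
        res = res.reset_index()
        res["time_ka"] = t
        res["seed"] = config.seed
        pieces.append(res)
    pcs = pd.concat(pieces, ignore_index=True)
    return pcs


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns paths of the written result files."""
    config.validate()
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {},
                      "inputs": {}, "started": time.strftime("%FT%T")}
    for key in ("sites", "climate", "ice", "tree", "node_ages"):
        p = Path(getattr(config, key))
        if p.exists():
            manifest["inputs"][key] = hashlib.sha256(p.read_bytes()).hexdigest()

    # --- phylogeny ---------------------------------------------------------
    tree = _prepare_tree(config)
    D = cophenetic_distances(tree)
    manifest["stages"]["tree"] = {"n_tips": tree.n_tips}

    # --- sites -> grid -----------------------------------------------------
    sites = pd.read_csv(config.sites)
    n_in = sites["site_id"].nunique()
    sites = grid_mod.filter_by_quality(sites, config.quality_threshold)
    gridded = grid_mod.grid_sites(sites, config.grid_resolution)
    manifest["stages"]["grid"] = {
        "n_sites_in": int(n_in),
        "n_sites_kept": int(sites["site_id"].nunique()),
        "n_cells": int(gridded.groupby(["cell_lon", "cell_lat"]).ngroups),
    }

    # --- ice / DEGLAC ------------------------------------------------------
    ice_raw = pd.read_csv(config.ice)
    if "age_ka" in ice_raw.columns:
        slices = sorted(gridded["time_ka"].unique())
        masks = deglac_mod.align_ice_to_slices(ice_raw, slices)
    else:
        masks = ice_raw
    masks, n_conflicts = deglac_mod.reclassify_conflicts(masks, gridded)
    ice = deglac_mod.time_since_deglaciation(masks, config.record_start_ka)
    manifest["stages"]["ice"] = {"n_conflicts_reclassified": n_conflicts}

    # --- PCS ---------------------------------------------------------------
    pcs = compute_pcs(gridded, D, config)
    pcs_path = out / "pcs.csv"
    pcs.to_csv(pcs_path, index=False, float_format="%.10g")
    manifest["stages"]["pcs"] = {"n_rows": len(pcs)}

    # --- climate join and collinearity report ------------------------------
    climate = pd.read_csv(config.climate)
    retained_vars, corr = grid_mod.screen_collinearity(climate)
    data = pcs.merge(climate, on=["cell_lon", "cell_lat", "time_ka"], how="left")
    data = data.merge(ice[["cell_lon", "cell_lat", "time_ka", "deglac"]],
                      on=["cell_lon", "cell_lat", "time_ka"], how="left")
    manifest["stages"]["climate"] = {"retained_variables": retained_vars}

    variables = list(config.variables)
    if config.include_deglac_variable:
        variables = variables + ["deglac"]

    # --- model fits --------------------------------------------------------
    ss = np.random.SeedSequence(config.seed + 1)
    table1, table2, coef_rows = [], [], []
    for metric in config.metrics:
        metric_data = stat_mod.exclude_sparse_periods(
            data, config.min_sites_per_slice, value_col=metric)
        if config.equal_n:
            metric_data = stat_mod.equalize_sample_sizes(
                metric_data, config.equal_n, seed=ss.spawn(1)[0],
                value_col=metric)
        for variable in variables:
            for estimator in ("ols", "sar"):
                try:
                    fset = stat_mod.fit_model_set(
                        metric_data, metric, variable, estimator,
                        distances_km=config.distances_km)
                except (ValueError, KeyError) as exc:
                    log.warning("fit failed: %s %s %s: %s", metric, variable,
                                estimator, exc)
                    continue
                for form, res in fset["fits"].items():
                    p = res.params
                    table1.append({
                        "metric": metric, "estimator": estimator,
                        "variable": variable, "form": form,
                        "intercept": p["const"], "slope": p[variable],
                        "adj_r2": res.rsquared,
                        "llf": res.llf,
                        "lambda": getattr(res.fit, "lam", np.nan),
                        "moran_i": res.moran.I if res.moran else np.nan,
                        "distance_km": fset["distance_km"] or np.nan,
                        "n": res.n,
                    })
                selected, comps = stat_mod.select_form(fset["fits"],
                                                       config.alpha)
                for c in comps:
                    table2.append({
                        "metric": metric, "estimator": estimator,
                        "variable": variable,
                        "comparison": f"{c.smaller} vs {c.larger}",
                        "statistic": c.statistic,
                        "df": "/".join(str(d) for d in c.df), "p": c.p,
                        "selected": selected,
                    })
                changed = fset["fits"]["changed_relationship"]
                tc = stat_mod.extract_time_coefficients(changed)
                tc.insert(0, "variable", variable)
                tc.insert(0, "estimator", estimator)
                tc.insert(0, "metric", metric)
                coef_rows.append(tc)

    pd.DataFrame(table1).to_csv(out / "table1.csv", index=False,
                                float_format="%.10g")
    pd.DataFrame(table2).to_csv(out / "table2.csv", index=False,
                                float_format="%.10g")
    pd.concat(coef_rows, ignore_index=True).to_csv(
        out / "time_coefficients.csv", index=False, float_format="%.10g")

    # --- geographic trends -------------------------------------------------
    trend_rows = []
    for metric in config.metrics:
        for axis in ("lon", "lat"):
            try:
                fit = stat_mod.geographic_trend(pcs, metric, axis)
            except ValueError:
                continue
            coord = {"lon": "cell_lon", "lat": "cell_lat"}[axis]
            trend_rows.append({
                "metric": metric, "axis": axis,
                "slope": fit.params[coord], "r2": fit.rsquared,
                "p": fit.f_pvalue,
            })
    pd.DataFrame(trend_rows).to_csv(out / "geographic_trends.csv",
                                    index=False, float_format="%.10g")

    # --- deglaciation heatmaps ---------------------------------------------
    heat_rows = []
    for metric in config.metrics:
        raw = deglac_mod.deglac_heatmap(pcs, ice, value_col=metric)
        raw["metric"], raw["residualized"] = metric, 0
        heat_rows.append(raw)
        resid = deglac_mod.climate_residual_heatmap(pcs, climate, ice,
                                                    value_col=metric)
        resid["metric"], resid["residualized"] = metric, 1
        heat_rows.append(resid)
    pd.concat(heat_rows, ignore_index=True).to_csv(
        out / "heatmaps.csv", index=False, float_format="%.10g")

    # --- IDW surfaces (presentation only) ----------------------------------
    surf_rows = []
    all_cells = climate[["cell_lon", "cell_lat"]].drop_duplicates().to_numpy()
    for metric in config.metrics:
        for t, sl in pcs.loc[pcs[metric].notna()].groupby("time_ka"):
            pts = sl[["cell_lon", "cell_lat"]].to_numpy(dtype=float)
            vals = sl[metric].to_numpy(dtype=float)
            z = idw_interpolate(pts, vals, all_cells, power=config.idw_power)
            df = pd.DataFrame(all_cells, columns=["cell_lon", "cell_lat"])
            df["time_ka"], df["metric"], df["value"] = t, metric, z
            surf_rows.append(df)
    pd.concat(surf_rows, ignore_index=True).to_csv(
        out / "idw_surfaces.csv", index=False, float_format="%.10g")

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    manifest["results"] = {}
    for f in ["pcs.csv", "table1.csv", "table2.csv", "time_coefficients.csv",
              "geographic_trends.csv", "heatmaps.csv", "idw_surfaces.csv"]:
        manifest["results"][f] = hashlib.sha256(
            (out / f).read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return {"output_dir": str(out), "manifest": manifest}
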