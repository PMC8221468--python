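"""Five-stage pipeline orchestration driven by a single config mapping.

Stages: (1) ecosystem-service model calibration (optional — skipped when no
field-plot table is configured; the per-service index then comes from the
config), (2) trajectory clustering on the pre-intervention archive,
(3) cloud filtering and greenest-scene period assembly, (4) per-pixel BACI
contrasts, (5) grouped nonparametric comparisons and terrain regressions.

Every stage is a pure function of (inputs, config); the run manifest
records parameters, per-stage timings and sha256 hashes of the tabular
outputs so reruns can be checked for bit-identity.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baci as baci_mod
from . import esmodels, groupstats, scenesel, trajclust
from ._geotiff import read_geotiff, write_geotiff
from .rasterdata import (
    INTERVENTION_NAMES,
    InterventionMask,
    TerrainStack,
    load_field_plots,
    load_scene_stack,
    plots_to_pixels,
    rasterize_sites,
)

logger = logging.getLogger(__name__)

DEFAULT_SERVICES = {
    "erosion_prevention": "BSI",
    "forage_provision": "NBR",
    "iconic_species": "MSAVI",
}


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    p = Path(source)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    return yaml.safe_load(p.read_text())


def _require_paths(cfg: dict) -> dict:
    try:
        paths = cfg["paths"]
    except KeyError as exc:
        raise ConfigError("config lacks a 'paths' section") from exc
    for key in ("scenes", "sites", "out_dir"):
        if key not in paths:
            raise ConfigError(f"config paths lack {key!r}")
    for key, val in paths.items():
        if key != "out_dir" and not Path(val).exists():
            raise ConfigError(f"configured path {key} does not exist: {val}")
    if cfg.get("calibrate") and "plots" not in paths:
        raise ConfigError("calibration requested but no plots path configured")
    return paths


def _load_terrain(terrain_dir) -> TerrainStack:
    d = Path(terrain_dir)
    elevation, grid = read_geotiff(d / "elevation.tif")
    slope, _ = read_geotiff(d / "slope.tif")
    aspect, _ = read_geotiff(d / "aspect_class.tif")
    soil, _ = read_geotiff(d / "soil_parent.tif")
    classes_file = d / "soil_classes.json"
    classes = json.loads(classes_file.read_text()) if classes_file.exists() else []
    return TerrainStack(
        grid=grid,
        elevation=elevation.astype(float),
        slope=slope.astype(float),
        aspect_class=aspect.astype(np.int16),
        soil_parent=soil.astype(np.int16),
        soil_classes=classes,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config) -> dict:
    """Execute stages 1-5 and return the run manifest.

    Raises :class:`ConfigError` before any compute for configuration
    problems; :class:`DataError` for input-data problems. Partial outputs
    are retained on failure.
    """
    cfg = load_config(config)
    paths = _require_paths(cfg)
    out_dir = Path(paths["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "parameters": cfg, "outputs": {}}

    def _stage(name):
        logger.info("stage %s", name)
        manifest["stages"].append({"name": name, "t0": time.perf_counter()})

    def _done():
        s = manifest["stages"][-1]
        s["seconds"] = round(time.perf_counter() - s.pop("t0"), 3)

    try:
        stack = load_scene_stack(paths["scenes"], nodata=cfg.get("nodata"))
    except Exception as exc:
        raise DataError(f"loading scenes failed: {exc}") from exc
    terrain = _load_terrain(paths["terrain"]) if "terrain" in paths else None
    sites = _load_sites(paths["sites"], stack, cfg)

    services = cfg.get("services", dict(DEFAULT_SERVICES))

    # ---- stage 1: calibration (optional)
    _stage("calibrate")
    models = esmodels.published_models()
    if "plots" in paths:
        models = _calibrate(paths, stack, terrain, services, cfg, out_dir)
    for service, model in models.items():
        if service in services:
            services[service] = model.index
    _done()

    # ---- stage 2: trajectory clustering
    _stage("cluster")
    ccfg = cfg.get("cluster", {})
    pre_start = _as_date(ccfg.get("pre_start", "1989-01-01"))
    pre_end = _as_date(ccfg.get("pre_end", "1990-12-31"))
    thicket = sites.eligible_control | (sites.labels > 0)
    pre_stack = stack.between(pre_start, pre_end)
    cluster_index = ccfg.get("index", next(iter(services.values())))
    if len(pre_stack.scenes) < 2:
        raise DataError("fewer than 2 scenes in the pre-intervention window")
    traj = trajclust.build_trajectories(pre_stack, cluster_index, thicket)
    cluster_map = trajclust.isodata_cluster(
        traj,
        k=int(ccfg.get("k", 5)),
        max_iter=int(ccfg.get("max_iter", 50)),
        convergence=float(ccfg.get("convergence", 1.0)),
        seed=int(ccfg.get("seed", 0)),
        grid_shape=stack.grid.shape,
    )
    write_geotiff(out_dir / "clusters.tif", cluster_map.labels.astype(np.int16), stack.grid)
    pd.DataFrame(cluster_map.centroids).to_csv(out_dir / "cluster_centroids.csv", index=False)
    _done()

    # ---- stage 3: cloud filter + period specs
    _stage("select-scenes")
    filtered = scenesel.filter_clouds(stack, sites.eligible_control,
                                      float(cfg.get("cloud_threshold", 0.05)))
    pcfg = cfg.get("periods", {})
    specs = {}
    for code, start_year in sites.start_year.items():
        specs[code] = scenesel.build_period_spec(
            intervention=code,
            start_year=start_year,
            stack=scenesel.SceneStack(
                [s for s in filtered.scenes if s.date > _as_date(pcfg.get("annual_from", "2000-01-01"))],
                filtered.grid,
            ),
            index_names=sorted(set(services.values())),
            n_before=int(pcfg.get("n_before", 3)),
            area_mask=thicket,
        )
        specs[code].to_json(out_dir / f"periods_{code}.json")
    _done()

    # ---- stage 4: per-pixel BACI
    _stage("baci")
    bcfg = cfg.get("baci", {})
    tables = []
    for service, index_name in sorted(services.items()):
        for code, spec in sorted(specs.items()):
            res = baci_mod.run_baci(
                filtered, spec, cluster_map, sites, index_name,
                n_controls=int(bcfg.get("n_controls", 20)),
                seed=int(bcfg.get("seed", 0)),
                allow_fewer=bool(bcfg.get("allow_fewer", False)),
                p_method=bcfg.get("p_method", "rank"),
            )
            t = res.table.copy()
            t.insert(0, "service", service)
            tables.append(t)
            write_geotiff(out_dir / f"baci_{service}_{code}.tif",
                          res.contrast.astype(np.float64), stack.grid)
            counts = {
                name: int((res.reason == c).sum())
                for c, name in baci_mod.REASONS.items() if c > 0
            }
            counts["analyzed"] = len(res.table)
            logger.info("service %s intervention %s accounting: %s", service,
                        INTERVENTION_NAMES.get(code, code), counts)
    baci_table = pd.concat(tables, ignore_index=True)
    table_path = out_dir / "baci_table.csv"
    baci_table.to_csv(table_path, index=False)
    manifest["outputs"]["baci_table"] = {"path": str(table_path), "sha256": _sha256(table_path)}
    _done()

    # ---- stage 5: grouped comparisons + terrain regressions
    _stage("compare")
    gcfg = cfg.get("compare", {})
    seed = int(gcfg.get("seed", 0))
    alpha = float(gcfg.get("alpha", 0.05))
    comp_rows = []
    for service, sub in baci_table.groupby("service"):
        groups = _thinned_groups(sub, "intervention", stack.grid, seed)
        if len(groups) >= 2 and all(len(v) >= 3 for v in groups.values()):
            gc = groupstats.kruskal_games_howell(groups, by="intervention", alpha=alpha)
            g = gc.groups.copy()
            g.insert(0, "service", service)
            g["kruskal_p"] = gc.kruskal_p
            comp_rows.append(g)
    if comp_rows:
        comp = pd.concat(comp_rows, ignore_index=True)
        comp_path = out_dir / "comparison.csv"
        comp.to_csv(comp_path, index=False)
        manifest["outputs"]["comparison"] = {"path": str(comp_path), "sha256": _sha256(comp_path)}
    if terrain is not None:
        regs = []
        for service, sub in baci_table.groupby("service"):
            for cov in ("slope", "elevation"):
                r = groupstats.terrain_regression(sub, terrain, covariate=cov, seed=seed)
                r.insert(0, "service", service)
                regs.append(r)
        pd.concat(regs, ignore_index=True).to_csv(out_dir / "terrain_regressions.csv", index=False)
        if terrain.soil_classes:
            top = groupstats.top_soil_classes(terrain.soil_parent, sites.labels,
                                              terrain.soil_classes)
            (out_dir / "top_soil_classes.json").write_text(json.dumps(top, indent=2))
    _done()

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(_jsonable(manifest), indent=2))
    return manifest


def _as_date(v) -> dt.date:
    return v if isinstance(v, dt.date) else dt.date.fromisoformat(str(v))


def _load_sites(sites_path, stack, cfg) -> InterventionMask:
    thicket = None
    if cfg.get("thicket_mask"):
        arr, _ = read_geotiff(cfg["thicket_mask"])
        thicket = arr.astype(bool)
    try:
        return rasterize_sites(sites_path, stack.grid, thicket)
    except Exception as exc:
        raise DataError(f"rasterizing sites failed: {exc}") from exc


def _calibrate(paths, stack, terrain, services, cfg, out_dir):
    plots = load_field_plots(paths["plots"], stack.grid)
    cal_cfg = cfg.get("calibrate", {}) or {}
    cal_date = _as_date(cal_cfg.get("date", stack.dates[-1].isoformat()))
    scene = stack.scene_at(cal_date)
    px = plots_to_pixels(plots, stack.grid)
    from .indices import compute_index

    pred = {}
    for ix in sorted(set(services.values())):
        ir = compute_index(scene, ix)
        pred[ix] = ir.values[px.row, px.col]
    if terrain is not None:
        pred["Elevation"] = terrain.elevation[px.row, px.col]
        pred["Slope"] = terrain.slope[px.row, px.col]
    predictors = pd.DataFrame(pred)
    models = {}
    for service in services:
        ranked = esmodels.fit_candidates(plots, service, predictors)
        if not ranked:
            raise DataError(f"no candidate model for {service} passed screening")
        best = ranked[0]
        r2, std_rmse = esmodels.cross_validate(
            best, plots, predictors,
            repeats=int(cal_cfg.get("cv_repeats", 100)),
            seed=int(cal_cfg.get("seed", 0)),
        )
        best.diagnostics.update({"cv_r2": r2, "std_rmse": std_rmse})
        best.to_json(out_dir / f"model_{service}.json")
        models[service] = best
    return models


def _thinned_groups(table: pd.DataFrame, by: str, grid, seed: int) -> dict:
    groups = {}
    for g, sub in table.groupby(by):
        mask = np.zeros(grid.shape, dtype=bool)
        mask[sub.row.to_numpy(), sub.col.to_numpy()] = True
        pts = groupstats.thin_sample(mask, grid.pixel_size_m, seed=seed)
        if len(pts) == 0:
            continue
        lut = sub.set_index(["row", "col"]).contrast
        vals = lut.loc[list(map(tuple, pts))].dropna().to_numpy()
        if vals.size:
            groups[g] = vals
    return groups


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dt.date):
        return obj.isoformat()
    if isinstance(obj, Path):
        return str(obj)
    return obj
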