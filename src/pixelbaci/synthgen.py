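"""Synthetic Landsat-like landscapes with known truth.

The generator emulates the structure the BACI design assumes: a thicket
landscape stratified into K vegetation archetypes (banded index baselines),
a pre-intervention scene archive for trajectory clustering, annual
before/after scenes with a shared interannual (year) signal that affects
impact and control pixels identically — the confound the contrast must
cancel — pixel-level Gaussian noise, cloud blobs, optional SLC-off
diagonal stripes, and an additive post-intervention index effect delta on
impact pixels.

Reflectance bands are back-solved so the target index trajectory is
achieved exactly (one index at a time; uninvolved bands held at fixed
plausible constants), so every downstream stage sees physically shaped
inputs while the truth stays analytic: E[contrast] = -delta.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from ._geotiff import GridSpec
from .rasterdata import (
    Scene,
    SceneStack,
    TerrainStack,
    rasterize_sites,
    write_scene_stack,
)

#: fixed plausible reflectance for bands not involved in the back-solve
BAND_CONSTANTS = {
    "Blue": 0.05,
    "Green": 0.08,
    "Red": 0.10,
    "NIR": 0.30,
    "SWIR1": 0.25,
    "SWIR2": 0.12,
}

SOIL_CLASSES = [
    "alluvium",
    "black shale",
    "brownish quartzitic sandstone",
    "enon conglomerate",
    "feldspathic sandstone",
    "terrace gravel",
    "whitish quartzitic sandstone",
]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic landscape.

    Defaults mirror the reference application's scale where it is stated:
    30 m pixels, five vegetation archetypes, a ten-scene pre-intervention
    archive, three before- and three after-years, 20-control BACI with
    pixel noise sigma = 0.02 and shared year effects N(0, 0.05), and an
    additive post-intervention effect of +0.1 index units on revegetation
    pixels.
    """

    n_rows: int = 100
    n_cols: int = 100
    index: str = "NBR"
    k_true: int = 5
    #: archetype baseline index levels, densest last; banded by row
    archetype_levels: tuple = (0.10, 0.23, 0.36, 0.49, 0.62)
    noise_sd: float = 0.02
    year_effect_sd: float = 0.05
    seasonal_offsets: tuple = (-0.02, 0.03)  # per within-year acquisition
    #: additive post-intervention index effect per intervention code
    delta: dict = field(default_factory=lambda: {1: 0.1, 2: 0.0, 3: 0.1})
    start_year: int = 2012
    pre_years: tuple = (1989, 1990)
    n_pre_scenes: int = 10
    before_years: tuple = (2009, 2010, 2011)
    after_years: tuple = (2017, 2018, 2019)
    #: column spans [start, stop) of the vertical intervention strips
    reveg_cols: tuple = (30, 40)
    exclusion_cols: tuple = (60, 70)
    cloud_frac: dict = field(default_factory=dict)  # scene position -> fraction
    slc_off_scenes: tuple = ()  # scene positions with diagonal gap stripes
    pixel_size_m: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if len(self.archetype_levels) != self.k_true:
            raise ValueError("archetype_levels must have k_true entries")


def _solve_bands(index: str, v: np.ndarray) -> dict[str, np.ndarray]:
    """Back-solve reflectance so the named index equals ``v`` exactly."""
    c = {k: np.full(v.shape, val) for k, val in BAND_CONSTANTS.items()}
    if index in ("NDVI", "NBR", "MSAVI"):
        if np.any(v >= 1.0) or np.any(v <= -1.0):
            bad = v[(v >= 1) | (v <= -1)]
            raise ValueError(f"target {index} outside (-1, 1): {bad[:3]}")
    if index == "NDVI":
        c["NIR"] = c["Red"] * (1 + v) / (1 - v)
    elif index == "NBR":
        c["NIR"] = c["SWIR2"] * (1 + v) / (1 - v)
    elif index == "MSAVI":
        # negative targets need a brighter red band: NIR >= 0 requires
        # Red >= (v^2 - v)/2, so lift Red adaptively where needed
        c["Red"] = np.maximum(c["Red"], (v**2 - v) / 2 + 0.02)
        c["NIR"] = (v - v**2 + 2 * c["Red"]) / (2 * (1 - v))
        if np.any(c["NIR"] < 0):
            raise ValueError("target MSAVI not attainable with non-negative NIR")
    elif index == "BSI":
        if np.any(np.abs(v) >= 1.0):
            raise ValueError("target BSI outside (-1, 1)")
        q = c["NIR"] + c["Blue"]
        c["SWIR1"] = q * (1 + v) / (1 - v) - c["Red"]
        if np.any(c["SWIR1"] < 0):
            raise ValueError("target BSI not attainable with non-negative SWIR1")
    else:
        raise ValueError(f"band back-solving not implemented for index {index!r}")
    return c


def _scene_dates(cfg: SynthConfig) -> list[tuple[dt.date, str]]:
    """(date, phase) list: 'pre' archive scenes then annual BACI scenes."""
    dates = []
    months = np.linspace(0, 20, cfg.n_pre_scenes)  # spread over two years
    for m in months:
        y = cfg.pre_years[0] + int(m) // 12
        mo = int(m) % 12 + 1
        dates.append((dt.date(y, mo, min(26, 28)), "pre"))
    for y in (*cfg.before_years, *cfg.after_years):
        for j, _ in enumerate(cfg.seasonal_offsets):
            dates.append((dt.date(y, 3 + 4 * j, 15), "annual"))
    return sorted(dates)


def _cloud_blob(valid: np.ndarray, area_mask: np.ndarray, frac: float, rng) -> None:
    """Grow a contiguous blob of exactly round(frac * area) invalid pixels
    inside ``area_mask``, BFS-ordered by distance from a random center."""
    n_target = int(round(frac * area_mask.sum()))
    if n_target == 0:
        return
    rows, cols = np.nonzero(area_mask)
    i = rng.integers(rows.size)
    cr, cc = rows[i], cols[i]
    d2 = (rows - cr) ** 2 + (cols - cc) ** 2
    order = np.argsort(d2, kind="stable")[:n_target]
    valid[rows[order], cols[order]] = False


def _slc_stripes(shape: tuple[int, int], period: int = 16, width: int = 2) -> np.ndarray:
    """Diagonal no-data stripes emulating the scan-line-corrector failure."""
    r, c = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((r + c) % period) < width


def generate_landscape(cfg: SynthConfig):
    """Build (SceneStack, TerrainStack, InterventionMask, truth record).

    The truth record carries the per-pixel archetype grid, the drawn year
    effects, the per-intervention deltas, the site polygons, and the scene
    phases — everything needed to verify downstream recovery.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = GridSpec(cfg.n_rows, cfg.n_cols, x0=500000.0, y0=6300000.0,
                    pixel_size_m=cfg.pixel_size_m)
    shape = grid.shape

    # banded archetypes, densest vegetation in band 0 (top rows)
    band_height = int(np.ceil(cfg.n_rows / cfg.k_true))
    archetype = np.minimum(
        np.arange(cfg.n_rows)[:, None] // band_height, cfg.k_true - 1
    ) * np.ones((1, cfg.n_cols), dtype=int)
    levels = np.asarray(cfg.archetype_levels)[::-1]  # band 0 = densest
    base = levels[archetype]

    # intervention site polygons (vertical strips spanning all rows)
    def _strip(cols):
        x_lo = grid.x0 + cols[0] * grid.pixel_size_m
        x_hi = grid.x0 + cols[1] * grid.pixel_size_m
        y_top, y_bot = grid.y0, grid.y0 - cfg.n_rows * grid.pixel_size_m
        ring = [[x_lo, y_bot], [x_hi, y_bot], [x_hi, y_top], [x_lo, y_top],
                [x_lo, y_bot]]
        return {"type": "Polygon", "coordinates": [ring]}

    features = [
        {"type": "Feature", "geometry": _strip(cfg.reveg_cols),
         "properties": {"intervention": "revegetation", "start_year": cfg.start_year}},
        {"type": "Feature", "geometry": _strip(cfg.exclusion_cols),
         "properties": {"intervention": "exclusion", "start_year": cfg.start_year}},
    ]
    sites = rasterize_sites(features, grid)
    delta_grid = np.zeros(shape)
    for code, d in cfg.delta.items():
        delta_grid[sites.labels == code] = d

    dates = _scene_dates(cfg)
    years = sorted({d.year for d, _ in dates})
    year_effects = {y: float(rng.normal(0.0, cfg.year_effect_sd)) for y in years}
    start_date = dt.date(cfg.start_year, 1, 1)

    scenes = []
    annual_pos = {}  # within-year acquisition position
    for pos, (date, phase) in enumerate(dates):
        j = annual_pos.get(date.year, 0)
        annual_pos[date.year] = j + 1
        seasonal = cfg.seasonal_offsets[j % len(cfg.seasonal_offsets)] if phase == "annual" else 0.0
        v = base + year_effects[date.year] + seasonal
        v = v + rng.normal(0.0, cfg.noise_sd, size=shape)
        if date >= start_date:
            v = v + delta_grid
        bands = _solve_bands(cfg.index, v)
        valid = np.ones(shape, dtype=bool)
        if pos in cfg.cloud_frac:
            _cloud_blob(valid, sites.eligible_control, cfg.cloud_frac[pos], rng)
        sensor = "L5" if phase == "pre" else "L8"
        if pos in cfg.slc_off_scenes:
            valid &= ~_slc_stripes(shape)
            sensor = "L7"
        scenes.append(Scene(date=date, bands=bands, valid_mask=valid, sensor=sensor))
    stack = SceneStack(scenes, grid)

    terrain = _generate_terrain(grid, rng)
    truth = {
        "archetype": archetype,
        "year_effects": year_effects,
        "delta": dict(cfg.delta),
        "delta_grid": delta_grid,
        "features": features,
        "phases": [phase for _, phase in dates],
        "pre_dates": [d for d, p in dates if p == "pre"],
        "annual_dates": [d for d, p in dates if p == "annual"],
        "start_date": start_date,
    }
    return stack, terrain, sites, truth


def _generate_terrain(grid: GridSpec, rng) -> TerrainStack:
    """Smooth valley-to-ridge elevation with derived slope/aspect and
    patchy soil parent material."""
    shape = grid.shape
    rough = rng.normal(0.0, 1.0, size=shape)
    smooth = ndimage.gaussian_filter(rough, sigma=8.0)
    ramp = np.linspace(0.0, 1.0, shape[0])[:, None]
    elevation = 380.0 + 300.0 * ramp + 60.0 * smooth
    gy, gx = np.gradient(elevation, grid.pixel_size_m)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    aspect_deg = (np.degrees(np.arctan2(gx, -gy))) % 360.0
    from .groupstats import aspect_classes

    aspect = aspect_classes(aspect_deg, slope)
    # soil patches: nearest of a handful of random seed points per class
    n_seeds = len(SOIL_CLASSES) * 2
    seeds = rng.integers(0, min(shape), size=(n_seeds, 2))
    seed_class = rng.integers(0, len(SOIL_CLASSES), size=n_seeds)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (rr[..., None] - seeds[:, 0]) ** 2 + (cc[..., None] - seeds[:, 1]) ** 2
    soil = seed_class[np.argmin(d2, axis=-1)].astype(np.int16)
    return TerrainStack(
        grid=grid,
        elevation=elevation,
        slope=np.clip(slope, 0, 90),
        aspect_class=aspect,
        soil_parent=soil,
        soil_classes=list(SOIL_CLASSES),
    )


#: per-indicator field-measurement noise (indicator units); chosen as
#: realistic plot-scale measurement error for cover percentages and biomass
FIELD_NOISE_SD = {"strvc_pct": 3.0, "gb_kg_m2": 1.0, "sbc_pct": 1.5}

#: index sampling ranges wide enough to emulate the purposive plot choice
#: ("large spread" of indicator values) while keeping every truth-model
#: indicator nonnegative, so the physical floor at 0 stays inactive for the
#: noiseless truth
FIELD_INDEX_RANGE = {"BSI": (-0.35, 0.45), "NBR": (-0.15, 0.65)}


def generate_field_plots(
    models: dict,
    n: int = 32,
    n_iconic: int = 20,
    noise_sd: dict | None = None,
    seed: int = 0,
    grid: GridSpec | None = None,
):
    """Simulate the field-plot table from generating-truth models.

    Returns (plots, predictors): the plot table with indicator columns
    (spekboom cover missing beyond ``n_iconic`` plots) and the co-located
    predictor table (index values + terrain). Indicators are truth-model
    evaluations plus Gaussian noise, floored at 0.
    """
    import pandas as pd

    if n < 10:
        raise ValueError("need n >= 10 plots")
    noise_sd = {**FIELD_NOISE_SD, **(noise_sd or {})}
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = GridSpec(100, 100, x0=500000.0, y0=6300000.0)
    rows = rng.integers(0, grid.n_rows, size=n)
    cols = rng.integers(0, grid.n_cols, size=n)
    x, y = grid.pixel_center(rows, cols)
    pred = {"Elevation": rng.uniform(380.0, 680.0, size=n),
            "Slope": rng.uniform(0.0, 35.0, size=n)}
    for ix, (lo, hi) in FIELD_INDEX_RANGE.items():
        pred[ix] = rng.uniform(lo, hi, size=n)
    # spekboom cover grows with elevation; plots are sampled so the cover
    # truth stays nonnegative (the physical floor at 0 never distorts it)
    lo = np.zeros(n)
    iconic = models.get("iconic_species")
    if iconic is not None and iconic.index == "MSAVI" and iconic.form == "linear":
        coef = dict(zip(iconic.predictors, iconic.coefficients))
        need = -(coef.get("Elevation", 0.0) * pred["Elevation"]
                 + coef["intercept"]) / coef["MSAVI"]
        lo = np.clip(need, 0.0, None) + 0.02
    pred["MSAVI"] = rng.uniform(lo, np.maximum(lo + 0.05, 0.9))
    predictors = pd.DataFrame(pred)

    def _truth(model):
        tv = {t: predictors[t].to_numpy() for t in model.terrain}
        return model.evaluate(predictors[model.index].to_numpy(), tv)

    from .rasterdata import SERVICE_INDICATORS

    plots = pd.DataFrame({"plot_id": [f"P{i+1:02d}" for i in range(n)], "x": x, "y": y})
    for service, model in models.items():
        col = SERVICE_INDICATORS[service]
        vals = _truth(model) + rng.normal(0.0, noise_sd[col], size=n)
        plots[col] = np.maximum(vals, 0.0)
    miss = rng.choice(n, size=n - n_iconic, replace=False)
    plots.loc[miss, "sbc_pct"] = np.nan
    return plots, predictors


def write_bundle(cfg: SynthConfig, out_dir) -> dict:
    """Materialize a landscape to the on-disk layout the pipeline consumes:
    scene GeoTIFFs, terrain GeoTIFFs, sites.geojson, truth.json."""
    out_dir = Path(out_dir)
    stack, terrain, sites, truth = generate_landscape(cfg)
    write_scene_stack(stack, out_dir / "scenes")
    tdir = out_dir / "terrain"
    tdir.mkdir(parents=True, exist_ok=True)
    from ._geotiff import write_geotiff

    write_geotiff(tdir / "elevation.tif", terrain.elevation, stack.grid)
    write_geotiff(tdir / "slope.tif", terrain.slope, stack.grid)
    write_geotiff(tdir / "aspect_class.tif", terrain.aspect_class.astype(np.int16), stack.grid)
    write_geotiff(tdir / "soil_parent.tif", terrain.soil_parent.astype(np.int16), stack.grid)
    (tdir / "soil_classes.json").write_text(json.dumps(terrain.soil_classes))
    (out_dir / "sites.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": truth["features"]})
    )
    serializable = {
        "year_effects": truth["year_effects"],
        "delta": truth["delta"],
        "start_date": truth["start_date"].isoformat(),
        "pre_dates": [d.isoformat() for d in truth["pre_dates"]],
        "annual_dates": [d.isoformat() for d in truth["annual_dates"]],
        "archetype_bands": "row-banded, densest at row 0",
    }
    (out_dir / "truth.json").write_text(json.dumps(serializable, indent=2))
    np.savetxt(out_dir / "archetype.csv", truth["archetype"], fmt="%d", delimiter=",")
    return {"out_dir": str(out_dir), "n_scenes": len(stack.scenes)}
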