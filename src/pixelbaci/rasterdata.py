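"""Data model and I/O for scenes, terrain, intervention sites and field plots.

Everything downstream (index computation, clustering, scene selection, the
BACI engine) operates on the shared grid contract defined here: a 30 m
metric raster grid with 0-based row/col indices, where a pixel's
representative point is its center.

File layout for a scene stack directory (single-band GeoTIFFs):

    <ISO date>_<Band>.tif   Band in {Blue, Green, Red, NIR, SWIR1, SWIR2}
    <ISO date>_mask.tif     uint8 validity mask (1 = valid), optional

Reflectance is a unitless surface-reflectance fraction. Values outside
[0, 1] (atmospheric-correction artifacts) are retained, not masked; they
are surfaced through :func:`qa_report` instead.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape

from ._geotiff import GridSpec, read_geotiff, write_geotiff

BANDS = ("Blue", "Green", "Red", "NIR", "SWIR1", "SWIR2")

#: Intervention label codes on the InterventionMask grid.
INTERVENTION_CODES = {
    "none": 0,
    "revegetation": 1,
    "exclusion": 2,
    "exclusion+revegetation": 3,
}
INTERVENTION_NAMES = {v: k for k, v in INTERVENTION_CODES.items()}


@dataclass
class Scene:
    """One acquisition date: co-registered reflectance bands plus validity.

    ``valid_mask`` is False where the pixel is cloud, an SLC-off gap, or
    nodata; reflectance must be finite wherever the mask is True.
    """

    date: dt.date
    bands: dict[str, np.ndarray]
    valid_mask: np.ndarray
    sensor: str = "unknown"

    def __post_init__(self):
        for name, arr in self.bands.items():
            if arr.shape != self.valid_mask.shape:
                raise ValueError(f"band {name} shape {arr.shape} != mask shape")


@dataclass
class SceneStack:
    """Dated, co-registered multi-band reflectance rasters on one grid."""

    scenes: list[Scene]
    grid: GridSpec

    def __post_init__(self):
        dates = [s.date for s in self.scenes]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("scene dates must be strictly increasing")
        for s in self.scenes:
            if s.valid_mask.shape != self.grid.shape:
                raise ValueError(
                    f"scene {s.date}: shape {s.valid_mask.shape} != grid {self.grid.shape}"
                )

    @property
    def dates(self) -> list[dt.date]:
        return [s.date for s in self.scenes]

    def scene_at(self, date: dt.date) -> Scene:
        for s in self.scenes:
            if s.date == date:
                return s
        raise KeyError(f"no scene for date {date}")

    def subset(self, dates) -> "SceneStack":
        dates = set(dates)
        return SceneStack([s for s in self.scenes if s.date in dates], self.grid)

    def between(self, start: dt.date, end: dt.date) -> "SceneStack":
        """Scenes with start <= date <= end."""
        return SceneStack(
            [s for s in self.scenes if start <= s.date <= end], self.grid
        )


@dataclass
class TerrainStack:
    """Static terrain layers on the shared grid."""

    grid: GridSpec
    elevation: np.ndarray  # m above sea level
    slope: np.ndarray  # degrees, in [0, 90]
    aspect_class: np.ndarray  # int codes, 0 = flat
    soil_parent: np.ndarray  # int codes into soil_classes
    soil_classes: list[str] = field(default_factory=list)

    def __post_init__(self):
        for name in ("elevation", "slope", "aspect_class", "soil_parent"):
            if getattr(self, name).shape != self.grid.shape:
                raise ValueError(f"terrain layer {name} not on the shared grid")
        if not np.all(np.isfinite(self.elevation)):
            raise ValueError("elevation must be finite")
        if np.any(self.slope < 0) or np.any(self.slope > 90):
            raise ValueError("slope must lie in [0, 90] degrees")

    def layer(self, name: str) -> np.ndarray:
        if name not in ("elevation", "slope"):
            raise KeyError(f"unknown terrain covariate {name!r}")
        return getattr(self, name)


@dataclass
class InterventionMask:
    """Per-pixel intervention label plus the control-eligible thicket area.

    Labels: 0 none, 1 revegetation, 2 livestock exclusion, 3 combination.
    ``start_year`` maps each present label to the year its intervention
    began. ``eligible_control`` marks thicket/shrubland pixels outside all
    interventions; labelled and eligible pixels are disjoint by construction.
    """

    labels: np.ndarray
    start_year: dict[int, int]
    eligible_control: np.ndarray

    def __post_init__(self):
        if np.any(self.labels[self.eligible_control] != 0):
            raise ValueError("intervened pixels cannot be control-eligible")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.start_year)
        if missing:
            raise ValueError(f"interventions without a start year: {sorted(missing)}")


class GridMismatchError(ValueError):
    pass


def _parse_scene_files(paths):
    """Group `<date>_<band>.tif` files by date; returns {date: {role: path}}."""
    groups: dict[dt.date, dict[str, Path]] = {}
    for p in map(Path, paths):
        stem = p.stem
        try:
            date_s, role = stem.rsplit("_", 1)
            date = dt.date.fromisoformat(date_s)
        except ValueError as exc:
            raise ValueError(f"cannot parse date from file name {p.name!r}") from exc
        if role not in BANDS and role != "mask":
            raise ValueError(f"unknown band role {role!r} in {p.name!r}")
        groups.setdefault(date, {})[role] = p
    return groups


def load_scene_stack(paths, nodata: float | None = None, sensor: str = "unknown") -> SceneStack:
    """Load single-band GeoTIFFs into a date-sorted :class:`SceneStack`.

    ``paths`` may be a directory or an iterable of files. Pixels equal to the
    ``nodata`` sentinel in any band are folded into the validity mask.
    """
    paths = Path(paths).glob("*.tif") if isinstance(paths, (str, Path)) else paths
    groups = _parse_scene_files(paths)
    if not groups:
        raise ValueError("no scene rasters found")
    scenes = []
    ref_grid = None
    ref_file = None
    for date in sorted(groups):
        roles = groups[date]
        bands = {}
        mask = None
        for role, p in sorted(roles.items()):
            arr, grid = read_geotiff(p)
            if ref_grid is None:
                ref_grid, ref_file = grid, p
            elif grid != ref_grid:
                raise GridMismatchError(
                    f"grid of {p.name} does not match {ref_file.name}: "
                    f"{grid} vs {ref_grid}"
                )
            if role == "mask":
                mask = arr.astype(bool)
            else:
                bands[role] = arr.astype(np.float64)
        if mask is None:
            mask = np.ones(ref_grid.shape, dtype=bool)
        for arr in bands.values():
            mask &= np.isfinite(arr)
            if nodata is not None:
                mask &= arr != nodata
        scenes.append(Scene(date=date, bands=bands, valid_mask=mask, sensor=sensor))
    return SceneStack(scenes, ref_grid)


def write_scene_stack(stack: SceneStack, out_dir) -> list[Path]:
    """Write each scene as one GeoTIFF per band plus a uint8 mask raster."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for scene in stack.scenes:
        for band, arr in scene.bands.items():
            p = out_dir / f"{scene.date.isoformat()}_{band}.tif"
            write_geotiff(p, arr.astype(np.float64), stack.grid)
            written.append(p)
        p = out_dir / f"{scene.date.isoformat()}_mask.tif"
        write_geotiff(p, scene.valid_mask.astype(np.uint8), stack.grid)
        written.append(p)
    return written


def qa_report(stack: SceneStack) -> pd.DataFrame:
    """Per-scene fraction of valid pixels with reflectance outside [0, 1].

    Out-of-range reflectance is an atmospheric-correction artifact; it is
    reported, never masked, so index values stay auditable.
    """
    rows = []
    for scene in stack.scenes:
        for band, arr in scene.bands.items():
            v = arr[scene.valid_mask]
            frac = float(np.mean((v < 0) | (v > 1))) if v.size else 0.0
            rows.append({"date": scene.date, "band": band, "out_of_range_frac": frac})
    return pd.DataFrame(rows)


def _coerce_features(polygons):
    """Accept a GeoJSON FeatureCollection dict/path or a feature list."""
    if isinstance(polygons, (str, Path)):
        polygons = json.loads(Path(polygons).read_text())
    if isinstance(polygons, dict):
        polygons = polygons.get("features", [])
    return polygons


def rasterize_sites(
    polygons, grid: GridSpec, thicket_mask: np.ndarray | None = None
) -> InterventionMask:
    """Burn intervention polygons into a label grid by pixel-center test.

    A pixel is labelled iff its center lies inside a polygon. Where a
    revegetation polygon overlaps a livestock-exclusion polygon, the overlap
    is labelled as the combined intervention (code 3) and inherits the
    earlier of the two start years. ``thicket_mask`` delineates the
    control-eligible thicket/shrubland area; it is an input, and defaults to
    the whole grid.
    """
    features = _coerce_features(polygons)
    labels = np.zeros(grid.shape, dtype=np.int16)
    start_year: dict[int, int] = {}
    rows, cols = np.mgrid[0 : grid.n_rows, 0 : grid.n_cols]
    px, py = grid.pixel_center(rows.ravel(), cols.ravel())
    for feat in features:
        props = feat.get("properties", {})
        itype = props.get("intervention")
        if itype not in ("revegetation", "exclusion"):
            raise ValueError(f"unknown intervention type {itype!r}")
        year = int(props["start_year"])
        code = INTERVENTION_CODES[itype]
        geom = shapely_shape(feat["geometry"])
        inside = shapely.contains_xy(geom, px, py).reshape(grid.shape)
        other = INTERVENTION_CODES["exclusion" if itype == "revegetation" else "revegetation"]
        combo = inside & np.isin(labels, (other, 3))
        plain = inside & ~combo
        labels[plain] = code
        labels[combo] = 3
        start_year[code] = min(start_year.get(code, year), year)
        if combo.any():
            prior = [start_year[c] for c in (1, 2, 3) if c in start_year]
            start_year[3] = min(prior + [year])
    if thicket_mask is None:
        thicket_mask = np.ones(grid.shape, dtype=bool)
    eligible = thicket_mask & (labels == 0)
    start_year = {c: y for c, y in start_year.items() if (labels == c).any()}
    return InterventionMask(labels=labels, start_year=start_year, eligible_control=eligible)


FIELD_PLOT_COLUMNS = ["plot_id", "x", "y", "strvc_pct", "gb_kg_m2", "sbc_pct"]

#: ecosystem-service indicator column per service name
SERVICE_INDICATORS = {
    "erosion_prevention": "strvc_pct",
    "forage_provision": "gb_kg_m2",
    "iconic_species": "sbc_pct",
}


def load_field_plots(csv_path, grid: GridSpec | None = None) -> pd.DataFrame:
    """Load the field-plot table; validate coordinates and non-negativity.

    Missing indicator values are permitted per indicator (spekboom cover was
    recorded on fewer plots than the other two indicators).
    """
    plots = pd.read_csv(csv_path)
    missing = set(FIELD_PLOT_COLUMNS) - set(plots.columns)
    if missing:
        raise ValueError(f"field-plot table missing columns: {sorted(missing)}")
    for col in ("strvc_pct", "gb_kg_m2", "sbc_pct"):
        if (plots[col].dropna() < 0).any():
            raise ValueError(f"negative indicator values in column {col}")
    if grid is not None:
        xmin, xmax = grid.x0, grid.x0 + grid.n_cols * grid.pixel_size_m
        ymin, ymax = grid.y0 - grid.n_rows * grid.pixel_size_m, grid.y0
        ok = plots.x.between(xmin, xmax) & plots.y.between(ymin, ymax)
        if not ok.all():
            bad = plots.loc[~ok, "plot_id"].tolist()
            raise ValueError(f"plots outside the grid extent: {bad}")
    return plots


def plots_to_pixels(plots: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Attach the (row, col) of the 30 m pixel containing each plot center.

    Plots are 900 m^2, i.e. one Landsat pixel, so the containing pixel's
    value is used directly with no areal averaging.
    """
    out = plots.copy()
    out["col"] = np.floor((out.x - grid.x0) / grid.pixel_size_m).astype(int)
    out["row"] = np.floor((grid.y0 - out.y) / grid.pixel_size_m).astype(int)
    return out
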