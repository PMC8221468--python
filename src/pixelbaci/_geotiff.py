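"""Minimal single-band GeoTIFF read/write built on tifffile.

Only the georeferencing subset this package needs is handled: a north-up
affine transform expressed through the ModelPixelScale and ModelTiepoint
tags, and a projected EPSG code in the GeoKeyDirectory. Rotated or sheared
transforms are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735

# GeoKey ids
_GT_MODEL_TYPE = 1024  # 1 = projected
_GT_RASTER_TYPE = 1025  # 1 = PixelIsArea
_PROJECTED_CS_TYPE = 3072  # EPSG code


@dataclass(frozen=True)
class GridSpec:
    """Shared grid contract: shape, north-up affine transform, projected CRS.

    ``x0, y0`` is the outer corner of the top-left pixel; pixel area is the
    half-open cell [x0, x0+px) x (y0-px, y0]; a pixel's representative point
    is its center.
    """

    n_rows: int
    n_cols: int
    x0: float
    y0: float
    pixel_size_m: float = 30.0
    epsg: int = 32735  # UTM 35S, metric

    def pixel_center(self, row, col):
        """Map (row, col) -> projected (x, y) of the pixel center."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.x0 + (col + 0.5) * self.pixel_size_m
        y = self.y0 - (row + 0.5) * self.pixel_size_m
        return x, y

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


def write_geotiff(path, array: np.ndarray, grid: GridSpec) -> None:
    """Write a single-band GeoTIFF; dtype is preserved."""
    array = np.ascontiguousarray(array)
    if array.shape != grid.shape:
        raise ValueError(f"array shape {array.shape} != grid shape {grid.shape}")
    px = float(grid.pixel_size_m)
    scale = (px, px, 0.0)
    tiepoint = (0.0, 0.0, 0.0, float(grid.x0), float(grid.y0), 0.0)
    # GeoKeyDirectory header: version 1.1.0, 3 keys
    geokeys = (
        1, 1, 0, 3,
        _GT_MODEL_TYPE, 0, 1, 1,
        _GT_RASTER_TYPE, 0, 1, 1,
        _PROJECTED_CS_TYPE, 0, 1, int(grid.epsg),
    )
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, scale, True),
        (_MODEL_TIEPOINT, "d", 6, tiepoint, True),
        (_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys, True),
    ]
    tifffile.imwrite(path, array, extratags=extratags)


def read_geotiff(path) -> tuple[np.ndarray, GridSpec]:
    """Read a single-band GeoTIFF written by :func:`write_geotiff` (or any
    north-up GeoTIFF using pixel-scale + tiepoint georeferencing)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        array = page.asarray()
        tags = page.tags
        try:
            scale = tags[_MODEL_PIXEL_SCALE].value
            tiepoint = tags[_MODEL_TIEPOINT].value
        except KeyError as exc:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags") from exc
        epsg = 0
        if _GEO_KEY_DIRECTORY in tags:
            gk = tags[_GEO_KEY_DIRECTORY].value
            for i in range(4, len(gk) - 3, 4):
                if gk[i] == _PROJECTED_CS_TYPE:
                    epsg = int(gk[i + 3])
    if abs(scale[0] - scale[1]) > 1e-9:
        raise ValueError(f"{path}: non-square pixels not supported")
    grid = GridSpec(
        n_rows=array.shape[0],
        n_cols=array.shape[1],
        x0=float(tiepoint[3]),
        y0=float(tiepoint[4]),
        pixel_size_m=float(scale[0]),
        epsg=epsg,
    )
    return array, grid
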