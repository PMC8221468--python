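"""Per-scene, per-pixel spectral indices.

Ten indices over the six Landsat reflective bands. Normalized-difference
indices lie in [-1, 1] wherever their denominator is nonzero; soil-adjusted
and enhanced indices carry coefficient sets that can be overridden.

Coefficient defaults: EVI gain G = 2.5 with L = 1, C1 = 6, C2 = 7.5; SAVI
uses the conventional L = 0.5 (configurable — the soil-adjustment literature
also uses L = 1).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .rasterdata import Scene

DEFAULT_COEFFS = {
    "savi_L": 0.5,
    "evi_G": 2.5,
    "evi_L": 1.0,
    "evi_C1": 6.0,
    "evi_C2": 7.5,
}

#: bands each index requires
INDEX_BANDS = {
    "NDVI": ("NIR", "Red"),
    "SAVI": ("NIR", "Red"),
    "MSAVI": ("NIR", "Red"),
    "EVI": ("NIR", "Red", "Blue"),
    "NPCRI": ("Red", "Blue"),
    "BSI": ("SWIR1", "Red", "NIR", "Blue"),
    "NBR": ("NIR", "SWIR2"),
    "NBR2": ("SWIR1", "SWIR2"),
    "NDMI": ("NIR", "SWIR1"),
    "NDWI": ("Green", "NIR"),
}

#: pure-ratio indices, invariant to scaling all bands by c > 0
SCALE_INVARIANT = ("NDVI", "NPCRI", "BSI", "NBR", "NBR2", "NDMI", "NDWI")

#: selection sense for greenest-scene picking: vegetation up, bare soil down
GREENEST_MODE = {name: "max" for name in INDEX_BANDS} | {"BSI": "min"}


@dataclass
class IndexRaster:
    """A spectral index evaluated on one scene."""

    name: str
    date: dt.date
    values: np.ndarray
    valid_mask: np.ndarray
    coeffs: dict = field(default_factory=dict)


def _normdiff(a, b):
    """(a - b)/(a + b); returns (values, zero-denominator mask)."""
    denom = a + b
    bad = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, (a - b) / np.where(bad, 1.0, denom))
    return out, bad


def compute_index(scene: Scene, name: str, coeffs: dict | None = None) -> IndexRaster:
    """Evaluate one index for one scene.

    Output pixels are invalid wherever any required band is invalid or the
    formula's denominator is zero (undefined values are masked, not zeroed).
    """
    if name not in INDEX_BANDS:
        raise ValueError(f"unknown index {name!r}")
    c = {**DEFAULT_COEFFS, **(coeffs or {})}
    need = INDEX_BANDS[name]
    missing = [b for b in need if b not in scene.bands]
    if missing:
        raise ValueError(f"scene {scene.date} lacks bands {missing} needed by {name}")
    b = {k: scene.bands[k].astype(np.float64) for k in need}
    bad = np.zeros(scene.valid_mask.shape, dtype=bool)

    if name == "NDVI":
        vals, bad = _normdiff(b["NIR"], b["Red"])
    elif name == "NPCRI":
        vals, bad = _normdiff(b["Red"], b["Blue"])
    elif name == "NBR":
        vals, bad = _normdiff(b["NIR"], b["SWIR2"])
    elif name == "NBR2":
        vals, bad = _normdiff(b["SWIR1"], b["SWIR2"])
    elif name == "NDMI":
        vals, bad = _normdiff(b["NIR"], b["SWIR1"])
    elif name == "NDWI":
        vals, bad = _normdiff(b["Green"], b["NIR"])
    elif name == "BSI":
        vals, bad = _normdiff(b["SWIR1"] + b["Red"], b["NIR"] + b["Blue"])
    elif name == "SAVI":
        L = c["savi_L"]
        denom = b["NIR"] + b["Red"] + L
        bad = denom == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = (b["NIR"] - b["Red"]) / np.where(bad, 1.0, denom) * (1 + L)
        vals = np.where(bad, np.nan, vals)
    elif name == "MSAVI":
        disc = (2 * b["NIR"] + 1) ** 2 - 8 * (b["NIR"] - b["Red"])
        bad = disc < 0
        vals = (2 * b["NIR"] + 1 - np.sqrt(np.where(bad, 0.0, disc))) / 2
        vals = np.where(bad, np.nan, vals)
    elif name == "EVI":
        denom = b["NIR"] + c["evi_C1"] * b["Red"] - c["evi_C2"] * b["Blue"] + c["evi_L"]
        bad = denom == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = c["evi_G"] * (b["NIR"] - b["Red"]) / np.where(bad, 1.0, denom)
        vals = np.where(bad, np.nan, vals)

    mask = scene.valid_mask & ~bad & np.isfinite(vals)
    vals = np.where(mask, vals, np.nan)
    return IndexRaster(name=name, date=scene.date, values=vals, valid_mask=mask, coeffs=c)
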