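"""Scene filtering and per-year greenest-scene selection.

Whole scenes (never per-pixel composites) are chosen to represent each
analyzed year: the acquisition maximizing the area-mean vegetation index,
or minimizing the area-mean bare-soil index. Scenes with more than 5%
cloud/invalid pixels in the control area are excluded first.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .indices import GREENEST_MODE, compute_index
from .rasterdata import SceneStack

CLOUD_THRESHOLD = 0.05


def _is_file(source) -> bool:
    try:
        return Path(str(source)).is_file()
    except OSError:  # e.g. an inline JSON string longer than NAME_MAX
        return False


@dataclass
class PeriodSpec:
    """Before/after years for one intervention with one selected scene
    date per (year, index)."""

    intervention: int
    start_year: int
    before_years: list[int]
    after_years: list[int]
    selected: dict[str, dict[int, dt.date]] = field(default_factory=dict)
    mode: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if any(y > self.start_year for y in self.before_years):
            raise ValueError("before years must not follow the intervention start")
        if any(y < self.start_year for y in self.after_years):
            raise ValueError("after years must not precede the intervention start")

    def dates(self, index_name: str) -> tuple[list[dt.date], list[dt.date]]:
        """(before, after) selected scene dates for one index."""
        sel = self.selected[index_name]
        return ([sel[y] for y in self.before_years], [sel[y] for y in self.after_years])

    def to_json(self, path=None) -> str:
        payload = {
            "intervention": self.intervention,
            "start_year": self.start_year,
            "before_years": self.before_years,
            "after_years": self.after_years,
            "mode": self.mode,
            "selected": {
                ix: {str(y): d.isoformat() for y, d in sel.items()}
                for ix, sel in self.selected.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PeriodSpec":
        if isinstance(source, (str, Path)) and _is_file(source):
            source = Path(source).read_text()
        d = json.loads(source)
        return cls(
            intervention=d["intervention"],
            start_year=d["start_year"],
            before_years=d["before_years"],
            after_years=d["after_years"],
            mode=d.get("mode", {}),
            selected={
                ix: {int(y): dt.date.fromisoformat(s) for y, s in sel.items()}
                for ix, sel in d.get("selected", {}).items()
            },
        )


def filter_clouds(
    stack: SceneStack, control_mask: np.ndarray, threshold: float = CLOUD_THRESHOLD
) -> SceneStack:
    """Drop scenes whose invalid fraction within the control area exceeds
    the threshold (strictly "more than": exactly 5.0% is retained). Small
    clouds in retained scenes stay masked per pixel."""
    if not control_mask.any():
        raise ValueError("empty control mask")
    n_ctl = int(control_mask.sum())
    kept = []
    for scene in stack.scenes:
        n_bad = n_ctl - int(scene.valid_mask[control_mask].sum())
        # integer-count comparison so exactly-at-threshold scenes survive
        if n_bad <= threshold * n_ctl + 1e-9:
            kept.append(scene)
    return SceneStack(kept, stack.grid)


def pick_greenest(
    stack: SceneStack,
    year: int,
    index_name: str,
    mode: str | None = None,
    area_mask: np.ndarray | None = None,
    coeffs: dict | None = None,
) -> dt.date:
    """The scene date in ``year`` with the extremal spatial-mean index.

    ``mode`` is "max" for vegetation indices and "min" for the bare-soil
    index (defaulting per index). The mean is over valid pixels of
    ``area_mask`` (study area: intervened plus control thicket). Exact ties
    go to the earliest date.
    """
    if mode is None:
        mode = GREENEST_MODE[index_name]
    if mode not in ("max", "min"):
        raise ValueError(f"mode must be 'max' or 'min', got {mode!r}")
    candidates = [s for s in stack.scenes if s.date.year == year]
    if not candidates:
        raise LookupError(f"no retained scene in year {year}")
    best_date, best_val = None, None
    for scene in candidates:  # date-sorted; earliest tied date wins
        ir = compute_index(scene, index_name, coeffs)
        mask = ir.valid_mask if area_mask is None else (ir.valid_mask & area_mask)
        if not mask.any():
            continue
        val = float(ir.values[mask].mean())
        better = (
            best_val is None
            or (mode == "max" and val > best_val)
            or (mode == "min" and val < best_val)
        )
        if better:
            best_date, best_val = scene.date, val
    if best_date is None:
        raise LookupError(f"no valid pixels for {index_name} in year {year}")
    return best_date


def build_period_spec(
    intervention: int,
    start_year: int,
    stack: SceneStack,
    index_names,
    n_before: int = 3,
    n_after: int | None = None,
    after_years=None,
    area_mask: np.ndarray | None = None,
    start_date: dt.date | None = None,
) -> PeriodSpec:
    """Assemble a before/after period spec with one greenest scene per
    (year, index).

    Defaults to the ``n_before`` years preceding the start year and, when
    ``after_years`` is not given, the last ``n_after`` (= n_before) years
    available in the stack after the start. Scenes in the start year
    acquired before the intervention date itself (day resolution) count as
    "before"; interventions whose archive is too short simply pass a smaller
    ``n_before`` (the reference application used two before-years for its
    1990 interventions).
    """
    if start_date is None:
        start_date = dt.date(start_year, 1, 1)
    years_avail = sorted({s.date.year for s in stack.scenes})
    before_years = [y for y in years_avail if y < start_year][-n_before:]
    if any(s.date.year == start_year and s.date < start_date for s in stack.scenes):
        before_years = (before_years + [start_year])[-n_before:]
    if after_years is None:
        n_after = n_before if n_after is None else n_after
        after_years = [y for y in years_avail if y > start_year][-n_after:]
    after_years = sorted(after_years)
    shortfall = []
    if len(before_years) < min(n_before, 2):
        shortfall.append(f"before-years available: {before_years}")
    missing_after = [y for y in after_years if y not in years_avail]
    if missing_after:
        shortfall.append(f"after-years with no scene: {missing_after}")
    if shortfall:
        raise ValueError("insufficient years for period spec: " + "; ".join(shortfall))

    spec = PeriodSpec(
        intervention=intervention,
        start_year=start_year,
        before_years=sorted(before_years),
        after_years=after_years,
    )
    for ix in index_names:
        spec.mode[ix] = GREENEST_MODE[ix]
        sel = {}
        for y in spec.before_years + spec.after_years:
            sub = stack
            if y == start_year:  # only pre-intervention acquisitions count
                sub = SceneStack(
                    [s for s in stack.scenes if s.date.year != y or s.date < start_date],
                    stack.grid,
                )
            sel[y] = pick_greenest(sub, y, ix, area_mask=area_mask)
        spec.selected[ix] = sel
    return spec
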