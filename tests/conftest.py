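import datetime as dt

import numpy as np
import pytest

from pixelbaci import GridSpec
from pixelbaci.rasterdata import Scene, SceneStack
from pixelbaci.synthgen import SynthConfig, generate_landscape


def make_scene(date=dt.date(2017, 5, 14), valid=None, **bands):
    """Build a Scene from scalar or array band values."""
    arrays = {}
    shape = None
    for name, val in bands.items():
        arr = np.atleast_2d(np.asarray(val, dtype=float))
        arrays[name] = arr
        shape = arr.shape
    if valid is None:
        valid = np.ones(shape, dtype=bool)
    return Scene(date=date, bands=arrays, valid_mask=np.atleast_2d(valid))


@pytest.fixture
def scene_factory():
    return make_scene


@pytest.fixture
def grid():
    return GridSpec(n_rows=10, n_cols=10, x0=0.0, y0=300.0, pixel_size_m=30.0)


@pytest.fixture(scope="session")
def landscape():
    """Default-conditions synthetic landscape (100x100, 5 archetypes,
    delta=0.1 on revegetation, sigma=0.02, year effects N(0, 0.05))."""
    return generate_landscape(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def small_landscape():
    cfg = SynthConfig(
        n_rows=60, n_cols=60, reveg_cols=(20, 26), exclusion_cols=(40, 46), seed=5
    )
    return generate_landscape(cfg)


def stack_of(scenes, grid):
    return SceneStack(scenes, grid)
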