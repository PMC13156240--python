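import numpy as np
import pytest

from streamhab.raster_core import Grid, Mask
from streamhab.pipeline import Pipeline
from streamhab.synthetic_landscape import WorldConfig, generate_world, true_suitability


def make_grid(values, cell_size=60.0, kind="continuous", nodata=-9999.0):
    values = np.asarray(values)
    if kind == "categorical":
        values = values.astype(np.int64)
    else:
        values = values.astype(float)
    return Grid(
        values=values,
        nodata=nodata,
        origin_x=0.0,
        origin_y=values.shape[0] * cell_size,
        cell_size=cell_size,
        kind=kind,
    )


def make_mask(bool_array, cell_size=60.0):
    bool_array = np.asarray(bool_array, dtype=bool)
    return Mask(bool_array, make_grid(np.zeros(bool_array.shape), cell_size=cell_size))


@pytest.fixture
def grid_factory():
    return make_grid


@pytest.fixture
def mask_factory():
    return make_mask


@pytest.fixture(scope="session")
def small_world():
    """120x120 world shared by generator-level tests."""
    cfg = WorldConfig(seed=11, size=120)
    world = generate_world(cfg)
    true_suitability(world)
    return world


E2E_CONFIG = {
    "seed": 33,
    "world": {
        "size": 200,
        "n_occurrences": 600,
        "suit_coefficients": [-4.5, 0.0, -1.8, -0.4, 0.0],
    },
    "flow_threshold": 30,
    "background": {"n": 3000, "tau": 1500.0},
    "model": {"classes": "LQH", "rm": 1.0, "n_hinge": 8, "cv_folds": 5, "select": False},
}


@pytest.fixture(scope="session")
def e2e_pipeline(tmp_path_factory):
    """Full pipeline run on a 200x200 world, shared across test modules."""
    cfg = dict(E2E_CONFIG)
    cfg["out_dir"] = str(tmp_path_factory.mktemp("e2e_out"))
    pipe = Pipeline(cfg)
    pipe.run_all()
    return pipe
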