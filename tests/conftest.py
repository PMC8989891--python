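import numpy as np
import pandas as pd
import pytest

from brtland import (
    SyntheticConfig,
    generate_env_stack,
    sample_occurrences,
    true_suitability,
)
from brtland.raster import GridSpec, Raster


@pytest.fixture(scope="session")
def small_config():
    """A compact but fully featured synthetic study region."""
    return SyntheticConfig(
        grid_shape=(80, 120),
        resolution_deg=0.25,
        origin=(0.0, 30.0),
        n_presence=400,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_stack(small_config):
    return generate_env_stack(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_stack):
    return true_suitability(small_stack, small_config.true_weights)


@pytest.fixture(scope="session")
def small_points(small_config, small_truth):
    return sample_occurrences(small_truth, small_config.n_presence, seed=small_config.seed)


@pytest.fixture(scope="session")
def small_table(small_config, small_stack, small_points):
    from brtland import build_cell_table

    return build_cell_table(small_points, small_stack, seed=5)


@pytest.fixture(scope="session")
def fitted_small_model(small_table):
    from brtland import BRTConfig, fit_brt

    cfg = BRTConfig(
        learning_rate=0.05, tree_complexity=3, bag_fraction=0.75,
        step_size=25, max_trees=100, min_obs_in_node=10, patience=2, seed=3,
    )
    return fit_brt(small_table, cfg)


@pytest.fixture
def tiny_grid():
    return GridSpec(shape=(4, 5), resolution_deg=1.0, origin=(0.0, 4.0))


@pytest.fixture
def hand_xy():
    """10-row separable-ish dataset with unique best splits at every stage."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(10, 2))
    y = (X[:, 0] + 0.5 * rng.normal(size=10) > 0).astype(float)
    return X, y


def feature_cols(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("cell_id", "row", "col", "label")]


@pytest.fixture
def uniform_raster(tiny_grid):
    def make(value, **kw):
        return Raster(np.full(tiny_grid.shape, value), tiny_grid, **kw)

    return make
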