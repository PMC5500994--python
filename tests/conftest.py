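import numpy as np
import pytest

from orchard3d.raster_model import DsmGrid, GridTransform, OrchardConfig
from orchard3d.synthetic_orchard import CrownModel, generate_terrain, render_dsm


@pytest.fixture
def mini_config() -> OrchardConfig:
    """A 3 x 4 plantation at the standard 8 x 4 m spacing, one row per treatment."""
    return OrchardConfig(
        origin_xy=(10.0, 10.0), n_rows=3, n_cols=4,
        treatment_blocks=[(1, 1, "traditional"), (2, 2, "adapted"),
                          (3, 3, "mechanical")],
    )


@pytest.fixture
def flat_dsm() -> DsmGrid:
    """20 x 20 m flat terrain at 100 m elevation, 0.05 m pixels."""
    return generate_terrain((20.0, 20.0), 0.05, origin_xy=(0.0, 0.0),
                            base_elev=100.0)


@pytest.fixture
def single_crown_scene(flat_dsm):
    """One a=b=2 m, apex 3 m half-ellipsoid crown on flat terrain (noiseless)."""
    crown = CrownModel(center_xy=(10.3, 10.2), trunk_base_elev=100.0,
                       crown_base_height=0.0, apex_height=3.0,
                       semi_axis_x=2.0, semi_axis_y=2.0, tree_id=1)
    return render_dsm(flat_dsm, [crown]), crown


def make_grid(values, pixel_size=1.0, x_min=0.0, y_max=None, **kwargs) -> DsmGrid:
    values = np.asarray(values, dtype=float)
    if y_max is None:
        y_max = values.shape[0] * pixel_size
    return DsmGrid(values, GridTransform(x_min, y_max, pixel_size), **kwargs)
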