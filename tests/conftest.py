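import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from popforest import CensusFrame, GridTemplate, LandscapeSpec, generate_landscape


@pytest.fixture(scope="session")
def small_landscape():
    """Compact landscape reused by pipeline-level tests (120x120, 6/24 units)."""
    return generate_landscape(
        LandscapeSpec(n_rows=120, n_cols=120, n_coarse=6, n_fine=24, seed=11)
    )


@pytest.fixture
def unit_template():
    """10x10 grid with 1 m pixels at the origin."""
    return GridTemplate(
        origin_x=0.0, origin_y=10.0, pixel_width=1.0, pixel_height=1.0,
        n_rows=10, n_cols=10,
    )


def make_census(rects, counts, parents=None, levels=None, crs_id="local-metric"):
    """Census frame from (minx, miny, maxx, maxy) rectangles."""
    n = len(rects)
    parents = parents if parents is not None else [None] * n
    levels = levels if levels is not None else [1] * n
    return CensusFrame(
        pd.DataFrame(
            {
                "unit_id": [f"U{i}" for i in range(n)],
                "parent_id": parents,
                "admin_level": levels,
                "count": counts,
                "geometry": [box(*r) for r in rects],
            }
        ),
        crs_id=crs_id,
    )


@pytest.fixture
def two_square_census():
    """Two adjacent 5 m x 10 m units splitting a 10x10 grid of 1 m pixels."""
    return make_census([(0, 0, 5, 10), (5, 0, 10, 10)], [100, 300])
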