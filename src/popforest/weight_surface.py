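"""Per-pixel density weighting surface from the fitted forest.

The pruned forest predicts the log population density at every pixel of
the covariate stack; the weighting surface is the back-transformed mean
(exp of the per-tree mean log density, no smearing correction — the plain
back-transformed mean is the summary that validates best).  Water and
missing land-cover pixels are forced to zero density afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .density_forest import ForestModel
from .grid import GridTemplate
from .raster_prep import (
    MISSING_CODE,
    WATER_CODE,
    CovariateLayer,
    require_aligned_stack,
)

log = logging.getLogger(__name__)


@dataclass
class WeightRaster:
    """Predicted population density surface (people per km²) on the template.

    ``values`` is float32 (NaN outside the prediction boundary);
    ``zero_mask`` records which pixels were forced to zero and
    ``zero_provenance`` why.
    """

    values: np.ndarray
    template: GridTemplate
    response_range: tuple[float, float]
    zero_mask: np.ndarray | None = None
    zero_provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != self.template.shape:
            raise ValueError("weight raster not aligned to its template")
        if self.zero_mask is None:
            self.zero_mask = np.zeros(self.template.shape, dtype=bool)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def predict_weight_surface(
    model: ForestModel,
    stack: list[CovariateLayer],
    boundary_mask: np.ndarray | None = None,
    tile_rows: int = 256,
) -> WeightRaster:
    """Predict density for every pixel inside the boundary mask.

    The stack must contain every covariate the model was fitted with, all
    on one template.  Prediction proceeds in row tiles; results are
    independent of the tile size (each pixel's prediction involves only its
    own covariate values).  A nodata covariate value inside the boundary is
    an error naming the pixel and layer — gaps must be nibble-filled first.
    """
    template = require_aligned_stack(stack)
    by_name = {layer.name: layer for layer in stack}
    missing = [n for n in model.covariate_names if n not in by_name]
    if missing:
        raise ValueError(f"stack is missing model covariates: {missing}")
    layers = [by_name[n] for n in model.covariate_names]

    if boundary_mask is None:
        boundary_mask = np.ones(template.shape, dtype=bool)
    boundary_mask = np.asarray(boundary_mask, dtype=bool)
    if boundary_mask.shape != template.shape:
        raise ValueError("boundary mask not aligned to template")

    for layer in layers:
        bad = boundary_mask & ~layer.valid_mask
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"nodata covariate value inside the boundary: layer "
                f"{layer.name!r} at pixel (row {r}, col {c}); run "
                f"fill_nodata_nearest before predicting"
            )

    out = np.full(template.shape, np.nan, dtype=np.float32)
    for r0 in range(0, template.n_rows, tile_rows):
        r1 = min(r0 + tile_rows, template.n_rows)
        tile_mask = boundary_mask[r0:r1]
        if not tile_mask.any():
            continue
        X = np.column_stack(
            [layer.values[r0:r1][tile_mask] for layer in layers]
        )
        # float64 tree-mean accumulation happens inside predict_log
        w = np.exp(model.predict_log(X))
        tile = out[r0:r1]
        tile[tile_mask] = w.astype(np.float32)
    return WeightRaster(out, template, response_range=model.response_range)


def apply_structural_zeros(
    weights: WeightRaster,
    landcover: CovariateLayer,
    zero_classes=(WATER_CODE, MISSING_CODE),
) -> WeightRaster:
    """Force zero density on structurally unpopulated land-cover classes.

    Default classes: water bodies (210) and missing/cloud (230) — the cells
    for which population density is defined to be zero regardless of the
    model.  Provenance of the forced pixels is recorded on the result.
    """
    weights.template.require_same_grid(landcover.template, "land cover")
    if not zero_classes:
        log.warning("apply_structural_zeros called with no classes; identity")
        return weights
    zero = np.isin(landcover.values, np.asarray(zero_classes, dtype=np.float64))
    zero &= weights.valid_mask
    values = weights.values.copy()
    values[zero] = 0.0
    provenance = dict(weights.zero_provenance)
    for cls in zero_classes:
        n = int((np.isin(landcover.values, [float(cls)]) & zero).sum())
        provenance[f"landcover_class_{int(cls)}"] = n
    return WeightRaster(
        values,
        weights.template,
        response_range=weights.response_range,
        zero_mask=weights.zero_mask | zero,
        zero_provenance=provenance,
    )
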