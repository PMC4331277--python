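"""Covariate raster preparation on a shared grid template.

Turns census polygons and heterogeneous covariate sources into a stack of
co-registered rasters: binary class masks, Euclidean distance-to-class
layers, resampled/aggregated continuous layers, nearest-neighbour gap
filling ("nibble"), and the urban/rural split of the built land-cover class.

Conventions
-----------
* Pixel-centre semantics: a pixel belongs to the polygon containing its
  centre; distances are measured between pixel centres.
* Continuous, distance and binary layers are stored as float arrays with
  NaN for nodata; categorical layers as float arrays whose valid values are
  integer class codes (NaN for nodata).
* All outputs share one :class:`~popforest.grid.GridTemplate` bit-exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry.base import BaseGeometry

from .census import CensusFrame
from .grid import GridTemplate

log = logging.getLogger(__name__)

# Land-cover class codes used for the built/water/missing conventions.
URBAN_BUILT_CODE = 190
WATER_CODE = 210
MISSING_CODE = 230
RURAL_BUILT_CODE = 240


class LayerKind(str, Enum):
    CATEGORICAL = "categorical"
    BINARY_CLASS = "binary_class"
    DISTANCE = "distance"
    CONTINUOUS = "continuous"


@dataclass
class CovariateLayer:
    """A named single-band raster on the shared template.

    Names follow the 3-letter-source convention with ``_cls``/``_dst``
    suffixes for binary-class and distance-to-class layers (e.g.
    ``set_dst`` = distance to settlement points).
    """

    name: str
    kind: LayerKind
    values: np.ndarray
    template: GridTemplate

    def __post_init__(self) -> None:
        self.kind = LayerKind(self.kind)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.template.shape:
            raise ValueError(
                f"layer {self.name!r}: shape {self.values.shape} does not "
                f"match template {self.template.shape}"
            )
        if self.kind is LayerKind.BINARY_CLASS:
            valid = self.values[np.isfinite(self.values)]
            if valid.size and not np.isin(valid, (0.0, 1.0)).all():
                raise ValueError(f"binary layer {self.name!r} has values outside {{0,1}}")
        if self.kind is LayerKind.DISTANCE:
            valid = self.values[np.isfinite(self.values)]
            if valid.size and (valid < 0).any():
                raise ValueError(f"distance layer {self.name!r} has negative values")

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def with_values(self, values: np.ndarray) -> "CovariateLayer":
        return replace(self, values=np.asarray(values, dtype=np.float64))


class EmptyClassError(ValueError):
    """A class mask has no set cells, so a distance layer is undefined."""


# ---------------------------------------------------------------------------
# Grid template construction
# ---------------------------------------------------------------------------

def make_grid_template(
    census: CensusFrame,
    pixel_size: float,
    buffer_dist: float = 10_000.0,
) -> tuple[GridTemplate, BaseGeometry]:
    """Build the analysis grid from census boundaries plus an edge buffer.

    The census outer boundary is buffered by ``buffer_dist`` (default 10 km,
    which pads distance covariates against edge effects near borders), and
    the buffered bounding box is snapped outward to whole pixels.

    Returns the template and the buffered boundary polygon (for masking).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if buffer_dist < 0:
        raise ValueError("buffer_dist must be >= 0")
    if census.is_geographic and buffer_dist > 0:
        raise ValueError(
            "metric buffering on a geographic (degree) CRS is not meaningful; "
            "project the census data first"
        )
    boundary = census.union()
    if boundary.is_empty:
        raise ValueError("census geometries dissolve to an empty boundary")
    if buffer_dist > 0:
        boundary = boundary.buffer(buffer_dist)
    minx, miny, maxx, maxy = boundary.bounds
    n_cols = max(1, math.ceil((maxx - minx) / pixel_size - 1e-9))
    n_rows = max(1, math.ceil((maxy - miny) / pixel_size - 1e-9))
    template = GridTemplate(
        origin_x=minx,
        origin_y=maxy,
        pixel_width=float(pixel_size),
        pixel_height=float(pixel_size),
        n_rows=n_rows,
        n_cols=n_cols,
        crs_id=census.crs_id,
    )
    return template, boundary


# ---------------------------------------------------------------------------
# Unit rasterization
# ---------------------------------------------------------------------------

def rasterize_units(census: CensusFrame, template: GridTemplate) -> np.ndarray:
    """Label each pixel with the index of the census unit containing its centre.

    Returns an int32 raster of row positions into ``census.table`` with -1
    outside all units.  Units are painted in table order and the first unit
    claiming a pixel wins, so pixels whose centre lies on a shared edge are
    assigned by that stable ordering and never double-counted.  Overlapping
    claims and units that capture no pixel centre are logged.
    """
    labels = np.full(template.shape, -1, dtype=np.int32)
    xs = template.x_centers()
    ys = template.y_centers()
    overlap_px = 0
    for idx, geom in enumerate(census.geometries):
        r0, r1, c0, c1 = template.window_for_bounds(*geom.bounds)
        if r0 >= r1 or c0 >= c1:
            log.warning("unit %r captures no pixel centres", census.unit_ids[idx])
            continue
        gx, gy = np.meshgrid(xs[c0:c1], ys[r0:r1])
        inside = shapely.intersects_xy(geom, gx, gy)
        window = labels[r0:r1, c0:c1]
        overlap_px += int((inside & (window != -1)).sum())
        window[inside & (window == -1)] = idx
        if not (labels == idx).any():
            log.warning("unit %r captures no pixel centres", census.unit_ids[idx])
    if overlap_px:
        log.warning(
            "%d pixel centres claimed by more than one unit; kept the first "
            "unit in table order",
            overlap_px,
        )
    return labels


# ---------------------------------------------------------------------------
# Class masks and distance-to-class layers
# ---------------------------------------------------------------------------

def rasterize_features(
    geoms,
    template: GridTemplate,
    point_buffer: float | None = None,
) -> np.ndarray:
    """Binary mask of pixels whose centre intersects any feature geometry.

    Points and lines have zero area and would capture no centres, so they
    are buffered by ``point_buffer`` first (default: half the pixel
    diagonal, which marks at least the containing pixel).
    """
    mask = np.zeros(template.shape, dtype=bool)
    xs = template.x_centers()
    ys = template.y_centers()
    if point_buffer is None:
        point_buffer = 0.5 * math.hypot(template.pixel_width, template.pixel_height)
    for geom in geoms:
        g = geom
        if g.geom_type in (
            "Point",
            "MultiPoint",
            "LineString",
            "MultiLineString",
        ) or g.area == 0:
            g = g.buffer(point_buffer)
        r0, r1, c0, c1 = template.window_for_bounds(*g.bounds)
        if r0 >= r1 or c0 >= c1:
            continue
        gx, gy = np.meshgrid(xs[c0:c1], ys[r0:r1])
        mask[r0:r1, c0:c1] |= shapely.intersects_xy(g, gx, gy)
    return mask


def distance_from_mask(mask: np.ndarray, template: GridTemplate) -> np.ndarray:
    """Euclidean distance (CRS units) from each pixel centre to the nearest
    set-pixel centre; exactly 0 on set pixels."""
    if not mask.any():
        raise EmptyClassError("class mask has no set cells; distance is undefined")
    return ndimage.distance_transform_edt(
        ~mask, sampling=(template.pixel_height, template.pixel_width)
    )


def class_and_distance_rasters(
    source,
    template: GridTemplate,
    name: str,
    class_value: float | None = None,
    point_buffer: float | None = None,
) -> tuple[CovariateLayer, CovariateLayer]:
    """Build the ``{name}_cls`` binary mask and ``{name}_dst`` distance layer.

    ``source`` is either an iterable of shapely geometries (vector features)
    or a categorical raster array on the template, in which case
    ``class_value`` selects the class.

    Raises :class:`EmptyClassError` when the class has no set cells; callers
    should drop the layer (a constant large-distance stand-in would poison
    the training matrix).
    """
    template.require_metric("distance-to-class computation")
    if isinstance(source, np.ndarray):
        if class_value is None:
            raise ValueError("class_value required when source is a raster")
        if source.shape != template.shape:
            raise ValueError("categorical raster not aligned to template")
        mask = np.asarray(source) == class_value
    else:
        mask = rasterize_features(source, template, point_buffer=point_buffer)
    if not mask.any():
        raise EmptyClassError(f"class {name!r} has no set cells")
    cls = CovariateLayer(
        name=f"{name}_cls",
        kind=LayerKind.BINARY_CLASS,
        values=mask.astype(np.float64),
        template=template,
    )
    dst = CovariateLayer(
        name=f"{name}_dst",
        kind=LayerKind.DISTANCE,
        values=distance_from_mask(mask, template),
        template=template,
    )
    return cls, dst


# ---------------------------------------------------------------------------
# Resampling / aggregation onto the template
# ---------------------------------------------------------------------------

def _source_cell_targets(
    source_template: GridTemplate, template: GridTemplate
) -> tuple[np.ndarray, np.ndarray]:
    """Flat target-cell index for each source cell (centre mapping); second
    array flags source cells whose centre falls inside the template."""
    sx = source_template.x_centers()
    sy = source_template.y_centers()
    cols = np.floor((sx - template.origin_x) / template.pixel_width).astype(np.int64)
    rows = np.floor((template.origin_y - sy) / template.pixel_height).astype(np.int64)
    cgrid, rgrid = np.meshgrid(cols, rows)
    ok = (rgrid >= 0) & (rgrid < template.n_rows) & (cgrid >= 0) & (cgrid < template.n_cols)
    flat = rgrid * template.n_cols + cgrid
    return flat.ravel(), ok.ravel()


def _fractional_source_indices(
    template: GridTemplate, source_template: GridTemplate
) -> tuple[np.ndarray, np.ndarray]:
    """Fractional (row, col) position in the source grid of each template
    pixel centre, in pixel-centre coordinates (0 = first centre)."""
    tx = template.x_centers()
    ty = template.y_centers()
    fc = (tx - source_template.origin_x) / source_template.pixel_width - 0.5
    fr = (source_template.origin_y - ty) / source_template.pixel_height - 0.5
    return np.meshgrid(fc, fr)


def align_covariate(
    source_values: np.ndarray,
    source_template: GridTemplate,
    template: GridTemplate,
    method: str,
    name: str = "layer",
    kind: LayerKind | str = LayerKind.CONTINUOUS,
) -> CovariateLayer:
    """Resample/aggregate a georeferenced source raster onto the template.

    Methods
    -------
    ``majority_aggregate``
        Each target cell takes the modal class among the source cells whose
        centres fall in it (fine → coarse, categorical).  Ties break to the
        smallest class code.
    ``mean_aggregate``
        Mean of contributing source cells (fine → coarse, continuous).
    ``nearest``
        Nearest-neighbour sampling at target pixel centres (coarse → fine).
    ``bilinear``
        Bilinear interpolation at target pixel centres (continuous only).

    Target cells receiving no source cell (aggregate methods) are NaN.
    """
    kind = LayerKind(kind)
    source_values = np.asarray(source_values, dtype=np.float64)
    if source_values.shape != source_template.shape:
        raise ValueError("source raster does not match its template")
    if source_template.crs_id != template.crs_id:
        raise ValueError(
            "source CRS differs from template CRS; reproject before aligning"
        )
    if method in ("majority_aggregate",) and kind in (
        LayerKind.CONTINUOUS,
        LayerKind.DISTANCE,
    ):
        raise ValueError("majority aggregation is for categorical/binary data")
    if method == "bilinear" and kind in (LayerKind.CATEGORICAL, LayerKind.BINARY_CLASS):
        raise ValueError("bilinear interpolation is for continuous data")

    if method in ("majority_aggregate", "mean_aggregate"):
        flat_target, ok = _source_cell_targets(source_template, template)
        vals = source_values.ravel()
        ok = ok & np.isfinite(vals)
        flat_target = flat_target[ok]
        vals = vals[ok]
        n_cells = template.n_rows * template.n_cols
        if method == "mean_aggregate":
            sums = np.bincount(flat_target, weights=vals, minlength=n_cells)
            counts = np.bincount(flat_target, minlength=n_cells)
            with np.errstate(invalid="ignore"):
                out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        else:
            out = np.full(n_cells, np.nan)
            best = np.zeros(n_cells, dtype=np.int64)
            # ascending class order + strict > comparison = smallest-code tie rule
            for code in np.unique(vals):
                cnt = np.bincount(flat_target[vals == code], minlength=n_cells)
                better = cnt > best
                out[better] = code
                best = np.maximum(best, cnt)
        return CovariateLayer(name, kind, out.reshape(template.shape), template)

    if method in ("nearest", "bilinear"):
        fc, fr = _fractional_source_indices(template, source_template)
        order = 0 if method == "nearest" else 1
        out = ndimage.map_coordinates(
            np.nan_to_num(source_values, nan=0.0),
            [fr, fc],
            order=order,
            mode="nearest",
        )
        if not np.isfinite(source_values).all():
            # propagate nodata through the same resampling
            bad = ndimage.map_coordinates(
                (~np.isfinite(source_values)).astype(np.float64),
                [fr, fc],
                order=order,
                mode="nearest",
            )
            out = np.where(bad > 0, np.nan, out)
        return CovariateLayer(name, kind, out, template)

    raise ValueError(f"unknown resampling method {method!r}")


# ---------------------------------------------------------------------------
# Nearest-neighbour gap filling ("nibble")
# ---------------------------------------------------------------------------

def fill_nodata_nearest(
    layer: CovariateLayer, fill_region: np.ndarray | None = None
) -> CovariateLayer:
    """Fill nodata cells with the value of the nearest valid cell.

    The nearest-valid search is Euclidean between pixel centres.  Cells
    outside ``fill_region`` (boolean mask, default: everywhere) are left
    untouched; valid cells are never modified.
    """
    valid = layer.valid_mask
    if not valid.any():
        raise ValueError(f"layer {layer.name!r} is entirely nodata; cannot fill")
    if valid.all():
        return layer
    _, (ri, ci) = ndimage.distance_transform_edt(
        ~valid,
        sampling=(layer.template.pixel_height, layer.template.pixel_width),
        return_indices=True,
    )
    filled = layer.values[ri, ci]
    out = layer.values.copy()
    target = ~valid if fill_region is None else (~valid & np.asarray(fill_region, bool))
    out[target] = filled[target]
    return layer.with_values(out)


# ---------------------------------------------------------------------------
# Built-class urban/rural split
# ---------------------------------------------------------------------------

def split_built_class(
    landcover: CovariateLayer,
    urban_extent: np.ndarray,
    built_codes=(URBAN_BUILT_CODE, RURAL_BUILT_CODE),
    override_mask: np.ndarray | None = None,
) -> tuple[CovariateLayer, CovariateLayer]:
    """Recode built land-cover pixels as urban (190) or rural (240) built.

    A built pixel inside the urban-extent mask becomes the urban-area code
    190; outside it, the rural-settlement code 240.  ``override_mask``
    optionally forces additional pixels to be treated as built (ancillary
    built-area adjustment).  Also returns the merged binary ``lan_clsBLT``
    layer covering both built codes.
    """
    if urban_extent.shape != landcover.template.shape:
        raise ValueError("urban extent mask not aligned to template")
    values = landcover.values.copy()
    built = np.isin(values, np.asarray(built_codes, dtype=np.float64))
    if override_mask is not None:
        built |= np.asarray(override_mask, bool) & np.isfinite(values)
    if not built.any():
        log.warning("no built-class pixels found; split is a no-op")
    urban = np.asarray(urban_extent, bool)
    values[built & urban] = URBAN_BUILT_CODE
    values[built & ~urban] = RURAL_BUILT_CODE
    recoded = landcover.with_values(values)
    blt = CovariateLayer(
        name="lan_clsBLT",
        kind=LayerKind.BINARY_CLASS,
        values=built.astype(np.float64),
        template=landcover.template,
    )
    return recoded, blt


def require_aligned_stack(stack: list[CovariateLayer]) -> GridTemplate:
    """Assert all layers share one template and unique names; return it."""
    if not stack:
        raise ValueError("empty covariate stack")
    template = stack[0].template
    names = set()
    for layer in stack:
        template.require_same_grid(layer.template, f"layer {layer.name!r}")
        if layer.name in names:
            raise ValueError(f"duplicate layer name {layer.name!r} in stack")
        names.add(layer.name)
    return template
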