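"""Self-contained synthetic landscapes for pipeline testing and validation.

Generates a planar-metric landscape with two nested admin levels,
settlement-driven covariates and census counts drawn from a known
log-density model:

    lambda(p) = b0 + b1 * exp(-d_built(p) / d_scale) + b2 * built(p)
                + b3 * field(p) + eps,      eps ~ N(0, sigma^2)

where d_built is the distance to the nearest built-up pixel: density is
plateau-like across the built fabric of each settlement and decays with
distance from its edge, the classic urban density profile.

with water and cloud/missing pixels forced to zero density.  Unit counts
are the rounded zonal sums of ``exp(lambda) * pixel_area``, with the
rounding residual assigned so that fine counts nest exactly inside coarse
counts.  Regeneration from the same (spec, seed) is bit-identical.

Defaults describe a plausible rural/peri-urban region: baseline density
50 people per km², roughly an order of magnitude denser near settlements
and in built-up pixels, with moderate (sigma = 0.2) unexplained pixel
noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from shapely.geometry import box
from shapely.ops import unary_union

from .census import CensusFrame
from .dasymetric_engine import PopulationRaster
from .grid import GridTemplate
from .raster_prep import (
    MISSING_CODE,
    WATER_CODE,
    CovariateLayer,
    LayerKind,
    distance_from_mask,
    split_built_class,
)

_CROP_CODE = 11
_WOODY_CODE = 40
_BUILT_RAW_CODE = 190  # raw built class before the urban/rural split


@dataclass(frozen=True)
class LandscapeSpec:
    """Recipe for one synthetic landscape.

    Grid and admin sizes default to a compact test region; the truth-model
    coefficients are shared defaults for all study runs (see module notes).
    ``n_fine`` must be a multiple of ``n_coarse``.
    """

    n_rows: int = 200
    n_cols: int = 200
    pixel_size: float = 100.0  # metres
    n_coarse: int = 12
    n_fine: int = 120
    n_settlements: int = 8
    n_noise: int = 3
    beta0: float = math.log(50.0)  # baseline log density (people/km^2)
    beta1: float = 2.5  # built-proximity effect on exp(-d_built/d_scale)
    dist_scale: float = 2000.0  # metres
    beta2: float = 2.0  # built-class effect
    beta3: float = 0.5  # smooth-field effect
    sigma: float = 0.2  # pixel-level log-density noise sd
    # settlement hierarchy follows the rank-size rule: the k-th ranked
    # settlement's built-up radius is city_radius * k**(-rank_exponent)
    # (Zipf populations with plateau density give exponent 1/2), floored
    # at village_radius; patches above urban_threshold count as urban
    city_radius: float = 2500.0  # metres
    rank_exponent: float = 0.5
    village_radius: float = 400.0  # metres
    urban_threshold: float = 1000.0  # metres
    field_smooth_px: float = 8.0
    noise_smooth_px: float = 0.0  # 0: spatially white pure-noise layers
    balance_exponent: float = 0.5  # admin-unit seeds sample population**a
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_coarse < 2 or self.n_fine < self.n_coarse:
            raise ValueError("need n_fine >= n_coarse >= 2")
        if self.n_fine > self.n_rows * self.n_cols:
            raise ValueError("grid too small to host the requested fine units")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class Landscape:
    """Everything the pipeline consumes, plus the generating truth."""

    spec: LandscapeSpec
    template: GridTemplate
    fine: CensusFrame
    coarse: CensusFrame
    stack: list[CovariateLayer]
    landcover: CovariateLayer
    urban_extent: np.ndarray
    boundary_mask: np.ndarray
    truth_log_density: np.ndarray  # NaN on zero-density pixels
    truth_density: np.ndarray  # people per km^2, 0 on water/missing
    truth_ppp: np.ndarray  # people per pixel
    truth_params: dict


# ---------------------------------------------------------------------------
# Partition helpers
# ---------------------------------------------------------------------------
#
# Census geographies are loosely population-balanced: enumeration units
# enumerate comparable head counts, so dense places are carved into many
# small units of their own (a primate city spans several admin units even
# at coarse levels) while sparse countryside forms large ones.  The admin
# partition emulates this with a nested Voronoi tessellation whose seeds
# are sampled proportionally to (powered) population: fine units are
# pixel-wise Voronoi cells of the fine seeds, coarse units group whole
# fine cells by their seed's nearest coarse seed, so nesting is exact.

def _nearest_seed_labels(seed_flat: np.ndarray, shape) -> np.ndarray:
    """Pixel-wise index of the nearest seed (Euclidean, pixel centres)."""
    mask = np.zeros(shape, dtype=bool)
    mask.ravel()[seed_flat] = True
    seed_id = np.full(shape, -1, dtype=np.int64)
    seed_id.ravel()[seed_flat] = np.arange(len(seed_flat))
    _, (ri, ci) = ndimage.distance_transform_edt(~mask, return_indices=True)
    return seed_id[ri, ci]


def _partition_units(spec: LandscapeSpec, weight: np.ndarray, rng: np.random.Generator):
    """Nested Voronoi partition with seeds sampled proportional to weight.

    Returns (fine_labels, parent): an int raster assigning every pixel to
    one of n_fine units, and each fine unit's coarse parent index.
    """
    shape = weight.shape
    n_px = weight.size
    w = weight.ravel().astype(np.float64)
    p = w / w.sum() if w.sum() > 0 else np.full(n_px, 1.0 / n_px)
    fine_seeds = rng.choice(n_px, size=spec.n_fine, replace=False, p=p)
    coarse_seeds = rng.choice(n_px, size=spec.n_coarse, replace=False, p=p)

    fine_labels = _nearest_seed_labels(fine_seeds, shape)
    coarse_of_pixel = _nearest_seed_labels(coarse_seeds, shape)
    parent = coarse_of_pixel.ravel()[fine_seeds]

    # guarantee every coarse unit owns at least one fine cell
    for ci in range(spec.n_coarse):
        if not (parent == ci).any():
            rows, cols = np.divmod(fine_seeds, shape[1])
            crow, ccol = divmod(int(coarse_seeds[ci]), shape[1])
            free = np.flatnonzero(np.bincount(parent, minlength=spec.n_coarse)[parent] > 1)
            d2 = (rows[free] - crow) ** 2 + (cols[free] - ccol) ** 2
            parent[free[np.argmin(d2)]] = ci
    return fine_labels, parent


def _label_polygons(labels: np.ndarray, n_units: int, template: GridTemplate) -> list:
    """Pixel-aligned shapely polygons, one per label, via row-run boxes."""
    polys = [[] for _ in range(n_units)]
    ox, oy = template.origin_x, template.origin_y
    pw, ph = template.pixel_width, template.pixel_height
    for r in range(labels.shape[0]):
        row = labels[r]
        breaks = np.flatnonzero(np.diff(row)) + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [labels.shape[1]]))
        for s, e in zip(starts, ends):
            lab = int(row[s])
            if lab >= 0:
                polys[lab].append(
                    box(ox + s * pw, oy - (r + 1) * ph, ox + e * pw, oy - r * ph)
                )
    return [unary_union(p) for p in polys]


def _smooth_field(shape, smooth_px: float, rng: np.random.Generator) -> np.ndarray:
    """Standardised Gaussian-smoothed white noise (white when smooth_px=0)."""
    f = rng.standard_normal(shape)
    if smooth_px > 0:
        f = ndimage.gaussian_filter(f, sigma=smooth_px)
    return (f - f.mean()) / f.std()


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_landscape(spec: LandscapeSpec) -> Landscape:
    """Build the landscape, the covariate stack and consistent census counts."""
    rng = np.random.default_rng(spec.seed)
    template = GridTemplate(
        origin_x=0.0,
        origin_y=spec.n_rows * spec.pixel_size,
        pixel_width=spec.pixel_size,
        pixel_height=spec.pixel_size,
        n_rows=spec.n_rows,
        n_cols=spec.n_cols,
        crs_id="local-metric",
    )
    shape = template.shape
    boundary = np.ones(shape, dtype=bool)

    # -- water: a meandering river plus a lake ---------------------------
    cols = np.arange(spec.n_cols)
    center = (
        spec.n_rows * (0.55 + 0.15 * np.sin(2 * np.pi * cols / spec.n_cols + rng.uniform(0, 2 * np.pi)))
    )
    rows = np.arange(spec.n_rows)[:, None]
    river_half_width = max(1.0, spec.n_rows / 80)
    water = np.abs(rows - center[None, :]) <= river_half_width
    lr = rng.integers(spec.n_rows // 6, spec.n_rows // 3)
    lc = rng.integers(spec.n_cols // 6, spec.n_cols // 3)
    lake_r = max(3.0, spec.n_rows / 25)
    rr, cc2 = np.ogrid[: spec.n_rows, : spec.n_cols]
    water |= (rr - lr) ** 2 + (cc2 - lc) ** 2 <= lake_r**2

    # -- settlements: primate city, towns, villages (never on water) -----
    # keep the city and towns away from the grid edge so their built-up
    # patches lie inside the mapped region
    margin = int(math.ceil(spec.city_radius / spec.pixel_size))
    interior = np.zeros(shape, dtype=bool)
    interior[margin : spec.n_rows - margin, margin : spec.n_cols - margin] = True
    if not (~water & interior).any():  # grid smaller than the city footprint
        interior[:] = True
    land_idx = np.flatnonzero((~water & interior).ravel())
    pick = rng.choice(land_idx, size=spec.n_settlements, replace=False)
    settle = np.zeros(shape, dtype=bool)
    settle.ravel()[pick] = True
    set_dst = distance_from_mask(settle, template)

    radii = np.maximum(
        spec.village_radius,
        spec.city_radius * (np.arange(1, spec.n_settlements + 1)) ** -spec.rank_exponent,
    )
    rr_grid, cc_grid = np.ogrid[: spec.n_rows, : spec.n_cols]
    built_patches = np.zeros(shape, dtype=bool)
    urban_extent = np.zeros(shape, dtype=bool)
    for k, flat in enumerate(pick):
        prow, pcol = divmod(int(flat), spec.n_cols)
        r_px = radii[k] / spec.pixel_size
        disk = (rr_grid - prow) ** 2 + (cc_grid - pcol) ** 2 <= r_px**2
        built_patches |= disk
        if radii[k] >= spec.urban_threshold:
            urban_extent |= disk

    # -- land cover -------------------------------------------------------
    built = built_patches & ~water
    blt_dst = distance_from_mask(built, template)
    veg_field = _smooth_field(shape, spec.field_smooth_px, rng)
    landcover_vals = np.where(veg_field > 0, float(_CROP_CODE), float(_WOODY_CODE))
    landcover_vals[built] = float(_BUILT_RAW_CODE)
    landcover_vals[water] = float(WATER_CODE)
    # a small cloud/missing patch exercises the structural-zero path
    pr = rng.integers(0, spec.n_rows - max(2, spec.n_rows // 40))
    pc = rng.integers(0, spec.n_cols - max(2, spec.n_cols // 40))
    ps = max(2, spec.n_rows // 40)
    landcover_vals[pr : pr + ps, pc : pc + ps] = float(MISSING_CODE)
    landcover = CovariateLayer("lan_cover", LayerKind.CATEGORICAL, landcover_vals, template)
    landcover, blt = split_built_class(landcover, urban_extent)

    # -- continuous + noise covariates ------------------------------------
    terrain = _smooth_field(shape, spec.field_smooth_px, rng)
    stack: list[CovariateLayer] = [
        CovariateLayer("set_dst", LayerKind.DISTANCE, set_dst, template),
        CovariateLayer("lan_dstBLT", LayerKind.DISTANCE, blt_dst, template),
        blt,
        CovariateLayer(
            "lan_cls210",
            LayerKind.BINARY_CLASS,
            (landcover.values == WATER_CODE).astype(float),
            template,
        ),
        CovariateLayer("fld", LayerKind.CONTINUOUS, terrain, template),
    ]
    for k in range(spec.n_noise):
        stack.append(
            CovariateLayer(
                f"nse{k + 1}",
                LayerKind.CONTINUOUS,
                _smooth_field(shape, spec.noise_smooth_px, rng),
                template,
            )
        )

    # -- truth log density -------------------------------------------------
    eps = rng.normal(0.0, spec.sigma, size=shape) if spec.sigma > 0 else np.zeros(shape)
    lam = (
        spec.beta0
        + spec.beta1 * np.exp(-blt_dst / spec.dist_scale)
        + spec.beta2 * (blt.values == 1.0)
        + spec.beta3 * terrain
        + eps
    )
    zero_density = water | (landcover.values == MISSING_CODE)
    truth_log = np.where(zero_density, np.nan, lam)
    truth_density = np.where(zero_density, 0.0, np.exp(lam))
    truth_ppp = truth_density * template.pixel_area_km2

    # -- admin units: nested, loosely population-balanced Voronoi ---------
    # seeds sampled proportional to population**a (a < 1) mimic census
    # zoning: dense places split into many small units, sparse countryside
    # into large ones, while unit counts keep a realistic spread
    fine_labels, parent = _partition_units(spec, truth_ppp**spec.balance_exponent, rng)

    # -- census counts consistent with the truth --------------------------
    fine_raw = np.bincount(
        fine_labels.ravel(), weights=truth_ppp.ravel(), minlength=spec.n_fine
    )
    fine_counts = np.round(fine_raw).astype(np.int64)
    coarse_counts = np.zeros(spec.n_coarse, dtype=np.int64)
    for ci in range(spec.n_coarse):
        members = np.flatnonzero(parent == ci)
        target = int(round(fine_raw[members].sum()))
        residual = target - int(fine_counts[members].sum())
        largest = members[np.argmax(fine_counts[members])]
        fine_counts[largest] += residual
        if fine_counts[largest] < 0:  # pathological near-empty landscapes
            fine_counts[largest] = 0
            target = int(fine_counts[members].sum())
        coarse_counts[ci] = target

    fine_polys = _label_polygons(fine_labels, spec.n_fine, template)
    coarse_labels = parent[fine_labels]
    coarse_polys = _label_polygons(coarse_labels, spec.n_coarse, template)

    coarse_ids = [f"C{ci:03d}" for ci in range(spec.n_coarse)]
    fine_tbl = pd.DataFrame(
        {
            "unit_id": [f"F{fi:04d}" for fi in range(spec.n_fine)],
            "parent_id": [coarse_ids[p] for p in parent],
            "admin_level": 2,
            "count": fine_counts,
            "geometry": fine_polys,
        }
    )
    coarse_tbl = pd.DataFrame(
        {
            "unit_id": coarse_ids,
            "parent_id": None,
            "admin_level": 1,
            "count": coarse_counts,
            "geometry": coarse_polys,
        }
    )
    fine = CensusFrame(fine_tbl, crs_id="local-metric")
    coarse = CensusFrame(coarse_tbl, crs_id="local-metric")
    assert fine.total() == coarse.total()

    return Landscape(
        spec=spec,
        template=template,
        fine=fine,
        coarse=coarse,
        stack=stack,
        landcover=landcover,
        urban_extent=urban_extent,
        boundary_mask=boundary,
        truth_log_density=truth_log,
        truth_density=truth_density,
        truth_ppp=truth_ppp,
        truth_params={
            "beta0": spec.beta0,
            "beta1": spec.beta1,
            "beta2": spec.beta2,
            "beta3": spec.beta3,
            "sigma": spec.sigma,
            "dist_scale": spec.dist_scale,
        },
    )


# ---------------------------------------------------------------------------
# Truth comparison
# ---------------------------------------------------------------------------

def truth_error(pop: PopulationRaster, truth_ppp: np.ndarray) -> dict:
    """Per-pixel discrepancy between a population raster and the truth.

    Reports the per-pixel RMSE (people) and the Spearman rank correlation
    over valid pixels.
    """
    if pop.values.shape != truth_ppp.shape:
        raise ValueError("rasters not aligned")
    a = np.nan_to_num(pop.values.ravel(), nan=0.0)
    b = np.asarray(truth_ppp).ravel()
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    rho = float(stats.spearmanr(a, b).statistic)
    return {"pixel_rmse": rmse, "spearman": rho}


def make_signal_noise_table(
    n: int = 300,
    n_noise: int = 5,
    signal_beta: float = 2.0,
    sigma: float = 0.3,
    seed: int = 0,
) -> "pd.DataFrame":
    """Tabular fixture: one signal covariate + pure-noise covariates.

    Returns a ready :class:`~popforest.training_table.TrainingTable` whose
    response is ``beta * signal + eps`` shifted into a realistic density
    range — used for forest tuning/elimination behaviour checks without a
    full landscape.
    """
    from .training_table import TrainingTable

    rng = np.random.default_rng(seed)
    signal = rng.uniform(0, 1, n)
    response = 3.0 + signal_beta * signal + rng.normal(0, sigma, n)
    data = pd.DataFrame(
        {
            "count": np.maximum(1, np.round(np.exp(response)).astype(int)),
            "area_km2": np.ones(n),
            "response": response,
            "signal": signal,
        },
        index=pd.Index([f"U{i:04d}" for i in range(n)], name="unit_id"),
    )
    for k in range(n_noise):
        data[f"noise{k + 1}"] = rng.uniform(0, 1, n)
    return TrainingTable(data)
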