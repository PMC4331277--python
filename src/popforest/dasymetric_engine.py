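"""Dasymetric redistribution of census counts over the weighting surface.

Each census unit's count is spread over its pixels proportionally to the
predicted density weights, conserving the unit total exactly; the result
is a people-per-pixel raster.  Post-processing covers scaling to national
(UN-style) totals, exponential urban/rural growth projection
P(t) = P_d · e^(r·t), and the people-per-hectare value convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .census import CensusFrame
from .grid import GridTemplate
from .weight_surface import WeightRaster

log = logging.getLogger(__name__)


@dataclass
class PopulationRaster:
    """People per pixel (or per hectare) on the shared template."""

    values: np.ndarray
    template: GridTemplate
    unit_of_value: str = "people_per_pixel"
    reference_year: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.template.shape:
            raise ValueError("population raster not aligned to its template")
        if self.unit_of_value not in ("people_per_pixel", "people_per_hectare"):
            raise ValueError(f"unknown unit_of_value {self.unit_of_value!r}")

    def total(self) -> float:
        """Total people (requires people_per_pixel mode)."""
        if self.unit_of_value != "people_per_pixel":
            raise ValueError("total is defined for people_per_pixel rasters")
        return float(np.nansum(self.values))


@dataclass
class ProjectionParams:
    """Inputs of the exponential projection P = P_d · e^(r·t)."""

    r_urban: float  # per-year average urban growth rate
    r_rural: float  # per-year average rural growth rate
    t: float  # years elapsed since the input-data year

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("t must be >= 0")
        if not (np.isfinite(self.r_urban) and np.isfinite(self.r_rural)):
            raise ValueError("growth rates must be finite")


def redistribute_counts(
    census: CensusFrame,
    unit_raster: np.ndarray,
    weights: WeightRaster,
) -> PopulationRaster:
    """Spread each unit's count across its pixels proportionally to weights.

    Pixel p in unit u receives ``count_u * w_p / sum(w_q, q in u)``, so the
    zonal sum over each unit reproduces its count exactly.  Units whose
    weights sum to zero but whose count is positive fall back to a uniform
    split over their pixels (logged): conservation must hold regardless of
    the weight surface.  Pixels outside every unit get zero people.
    """
    labels = np.asarray(unit_raster)
    if labels.shape != weights.template.shape:
        raise ValueError("unit raster not aligned to weight raster")
    n_units = len(census)
    counts = census.counts.astype(np.float64)

    flat = labels.ravel()
    inside = flat >= 0
    w = np.nan_to_num(weights.values.ravel(), nan=0.0)
    wsum = np.bincount(flat[inside], weights=w[inside], minlength=n_units)
    npix = np.bincount(flat[inside], minlength=n_units)

    degenerate = (wsum == 0) & (counts > 0) & (npix > 0)
    if degenerate.any():
        bad = [census.unit_ids[i] for i in np.flatnonzero(degenerate)]
        log.warning(
            "units with zero weight sum but positive count fall back to a "
            "uniform split: %s", bad
        )
    lost = (npix == 0) & (counts > 0)
    if lost.any():
        bad = [census.unit_ids[i] for i in np.flatnonzero(lost)]
        log.warning("units with no pixels lose their counts: %s", bad)

    per_unit_scale = np.zeros(n_units)
    ok = wsum > 0
    per_unit_scale[ok] = counts[ok] / wsum[ok]
    uniform = np.zeros(n_units)
    uniform[degenerate] = counts[degenerate] / npix[degenerate]

    out = np.zeros(flat.shape, dtype=np.float64)
    lab_in = flat[inside]
    out[inside] = per_unit_scale[lab_in] * w[inside] + uniform[lab_in]
    return PopulationRaster(
        out.reshape(labels.shape), weights.template, "people_per_pixel"
    )


def adjust_to_total(pop: PopulationRaster, target_total: float) -> PopulationRaster:
    """Scale every pixel so the national total matches a target estimate.

    A uniform multiplication by ``target/current``: the relative spatial
    pattern is untouched.
    """
    if target_total <= 0:
        raise ValueError("target total must be positive")
    current = pop.total()
    if current <= 0:
        raise ValueError("current total must be positive to adjust")
    return replace(pop, values=pop.values * (target_total / current))


def project_growth(
    pop: PopulationRaster,
    urban_mask: np.ndarray,
    params: ProjectionParams,
) -> PopulationRaster:
    """Exponential growth projection P = P_d · e^(r·t), pixel by pixel.

    Pixels overlapping the urban-extent mask grow at the urban rate, all
    others at the rural rate.
    """
    urban = np.asarray(urban_mask, dtype=bool)
    if urban.shape != pop.template.shape:
        raise ValueError("urban mask not aligned to population raster")
    factor = np.where(
        urban, np.exp(params.r_urban * params.t), np.exp(params.r_rural * params.t)
    )
    year = (
        pop.reference_year + int(round(params.t))
        if pop.reference_year is not None
        else None
    )
    return replace(pop, values=pop.values * factor, reference_year=year)


def convert_units(pop: PopulationRaster, mode: str) -> PopulationRaster:
    """Switch between people-per-pixel and people-per-hectare values.

    On a metric grid the pixel area is width × height; at the nominal 100 m
    resolution one pixel is exactly one hectare and both modes coincide.
    """
    if mode not in ("people_per_pixel", "people_per_hectare"):
        raise ValueError(f"unknown unit mode {mode!r}")
    if mode == pop.unit_of_value:
        return pop
    area_ha = pop.template.pixel_area_ha
    if area_ha <= 0:
        raise ValueError("pixel area must be positive")
    if mode == "people_per_hectare":
        values = pop.values / area_ha
    else:
        values = pop.values * area_ha
    return replace(pop, values=values, unit_of_value=mode)


def zonal_sums(pop: PopulationRaster, unit_raster: np.ndarray, n_units: int) -> np.ndarray:
    """Per-unit pixel sums of a people-per-pixel raster (the 'predicted'
    counts of the cross-scale validation)."""
    if pop.unit_of_value != "people_per_pixel":
        raise ValueError("zonal sums need people_per_pixel values")
    labels = np.asarray(unit_raster).ravel()
    inside = labels >= 0
    vals = np.nan_to_num(pop.values.ravel(), nan=0.0)
    return np.bincount(labels[inside], weights=vals[inside], minlength=n_units)
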