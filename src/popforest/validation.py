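"""Cross-scale ("one level up") validation, error metrics and baselines.

The protocol: aggregate the fine census one admin level up, estimate the
density forest and redistribute counts using only the coarse level, then
sum the resulting people-per-pixel raster inside each withheld fine unit
and compare those "predicted" sums against the observed fine counts.
Metrics are RMSE, %RMSE (RMSE over the mean fine-unit count) and MAE.

Baselines mirror the simpler production methods: uniform areal weighting
(GPW-like) and a binary urban/rural weight contrast (GRUMP-like).  A
total-country variant pools every unit into one national count before
redistribution, measuring the weighting layer alone without the census
"anchor" effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .census import CensusFrame
from .dasymetric_engine import PopulationRaster, redistribute_counts, zonal_sums
from .density_forest import ForestModel, ForestParams, select_covariates
from .grid import GridTemplate
from .raster_prep import CovariateLayer, rasterize_units
from .training_table import build_training_table, zonal_aggregate
from .weight_surface import WeightRaster, apply_structural_zeros, predict_weight_surface

log = logging.getLogger(__name__)


@dataclass
class AccuracyReport:
    """Observed vs predicted unit counts for one weighting method."""

    method: str
    per_unit: pd.DataFrame  # index unit_id; columns observed, predicted
    rmse: float
    pct_rmse: float
    mae: float

    @property
    def scatter(self) -> pd.DataFrame:
        """Observed-vs-predicted pairs for external plotting."""
        return self.per_unit[["observed", "predicted"]]

    def slope(self) -> float:
        """Observed-vs-predicted least-squares slope (1 = unbiased)."""
        res = stats.linregress(self.per_unit["observed"], self.per_unit["predicted"])
        return float(res.slope)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_units": len(self.per_unit),
            "rmse": self.rmse,
            "pct_rmse": self.pct_rmse,
            "mae": self.mae,
        }


def error_metrics(observed, predicted, method: str = "", unit_ids=None) -> AccuracyReport:
    """RMSE, %RMSE and MAE of predicted unit sums against observed counts.

    %RMSE is 100 · RMSE / mean(observed); the mean is taken over all units
    including zero-count ones.
    """
    o = np.asarray(observed, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if o.shape != p.shape or o.ndim != 1 or len(o) < 1:
        raise ValueError("observed and predicted must be equal-length 1-D arrays")
    err = o - p
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    mean_o = float(np.mean(o))
    if mean_o == 0:
        raise ValueError("mean observed count is zero; %RMSE undefined")
    idx = pd.Index(unit_ids if unit_ids is not None else np.arange(len(o)), name="unit_id")
    return AccuracyReport(
        method=method,
        per_unit=pd.DataFrame({"observed": o, "predicted": p}, index=idx),
        rmse=rmse,
        pct_rmse=100.0 * rmse / mean_o,
        mae=mae,
    )


def percent_residuals(observed, predicted) -> np.ndarray:
    """Per-unit percent residual 100·(observed − predicted)/observed.

    Positive values are under-predictions, bounded above by 100 (predicting
    zero where people were counted); negative values are over-predictions.
    Zero-observed units are undefined (NaN, logged and excluded from maps).
    """
    o = np.asarray(observed, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    out = np.full(o.shape, np.nan)
    ok = o > 0
    out[ok] = 100.0 * (o[ok] - p[ok]) / o[ok]
    n_undef = int((~ok).sum())
    if n_undef:
        log.info("percent residual undefined for %d zero-observed units", n_undef)
    return out


def baseline_weights(
    mode: str,
    template: GridTemplate,
    boundary_mask: np.ndarray | None = None,
    urban_mask: np.ndarray | None = None,
    urban_rural_ratio: float = 5.0,
) -> WeightRaster:
    """Simple weighting surfaces for the comparison baselines.

    ``areal``: constant weights, i.e. an equal split by area (GPW-like).
    ``urban_binary``: weight ``urban_rural_ratio`` inside the urban-extent
    mask and 1 outside (GRUMP-like); a ratio of 1 degenerates to areal.
    """
    if boundary_mask is None:
        boundary_mask = np.ones(template.shape, dtype=bool)
    boundary_mask = np.asarray(boundary_mask, dtype=bool)
    if mode == "areal":
        vals = np.where(boundary_mask, 1.0, np.nan)
    elif mode == "urban_binary":
        if urban_mask is None:
            raise ValueError("urban_binary baseline needs an urban-extent mask")
        if urban_rural_ratio <= 1:
            log.warning(
                "urban:rural ratio %.3g <= 1; urban pixels are not upweighted",
                urban_rural_ratio,
            )
        vals = np.where(np.asarray(urban_mask, bool), float(urban_rural_ratio), 1.0)
        vals = np.where(boundary_mask, vals, np.nan)
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    return WeightRaster(vals, template, response_range=(0.0, np.inf))


@dataclass
class ExperimentResult:
    """Outputs of the one-level-up experiment."""

    reports: dict[str, AccuracyReport]
    model: ForestModel
    weights: WeightRaster
    population: PopulationRaster
    residual_pct_raster: np.ndarray  # fine-unit percent residual map (RF method)
    fine_unit_raster: np.ndarray
    coarse_unit_raster: np.ndarray
    elimination_log: list[dict]


def one_level_up_experiment(
    fine_census: CensusFrame,
    stack: list[CovariateLayer],
    template: GridTemplate,
    landcover: CovariateLayer | None = None,
    urban_mask: np.ndarray | None = None,
    boundary_mask: np.ndarray | None = None,
    forest_params: ForestParams | None = None,
    baselines: tuple[str, ...] = ("areal", "urban_binary"),
    urban_rural_ratio: float = 5.0,
    zero_classes=(210, 230),
    total_country: bool = True,
) -> ExperimentResult:
    """Run the full cross-scale validation pipeline.

    Aggregates the fine census one level up, builds the coarse training
    table, tunes/prunes/fits the forest, predicts the weight surface,
    redistributes the *coarse* counts and scores the fine-level zonal sums
    against the withheld fine counts.  Baseline weighting schemes and the
    pooled total-country redistribution reuse the same machinery.
    """
    if fine_census.table["parent_id"].isna().all():
        raise ValueError("one-level-up validation needs two nested admin levels")
    coarse = fine_census.aggregate(1)

    fine_labels = rasterize_units(fine_census, template)
    coarse_labels = rasterize_units(coarse, template)

    cov_rows = zonal_aggregate(stack, coarse_labels, coarse)
    table = build_training_table(coarse, cov_rows)
    reduced, model, history = select_covariates(table, forest_params)

    weights = predict_weight_surface(model, stack, boundary_mask)
    if landcover is not None:
        weights = apply_structural_zeros(weights, landcover, zero_classes)

    observed = fine_census.counts.astype(float)
    ids = fine_census.unit_ids
    reports: dict[str, AccuracyReport] = {}

    def score(w: WeightRaster, method: str, census=coarse, labels=coarse_labels):
        pop = redistribute_counts(census, labels, w)
        pred = zonal_sums(pop, fine_labels, len(fine_census))
        reports[method] = error_metrics(observed, pred, method=method, unit_ids=ids)
        return pop

    population = score(weights, "rf")
    for mode in baselines:
        bw = baseline_weights(
            mode,
            template,
            boundary_mask=boundary_mask,
            urban_mask=urban_mask,
            urban_rural_ratio=urban_rural_ratio,
        )
        score(bw, mode)

    if total_country:
        pooled = CensusFrame(
            pd.DataFrame(
                {
                    "unit_id": ["NATION"],
                    "parent_id": None,
                    "admin_level": 0,
                    "count": [fine_census.total()],
                    "geometry": [fine_census.union()],
                }
            ),
            crs_id=fine_census.crs_id,
        )
        pooled_labels = np.where(coarse_labels >= 0, 0, -1).astype(np.int32)
        score(weights, "rf_total", census=pooled, labels=pooled_labels)

    rf = reports["rf"]
    resid = percent_residuals(rf.per_unit["observed"], rf.per_unit["predicted"])
    resid_map = np.full(template.shape, np.nan)
    inside = fine_labels >= 0
    resid_map[inside] = resid[fine_labels[inside]]

    return ExperimentResult(
        reports=reports,
        model=model,
        weights=weights,
        population=population,
        residual_pct_raster=resid_map,
        fine_unit_raster=fine_labels,
        coarse_unit_raster=coarse_labels,
        elimination_log=history,
    )
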