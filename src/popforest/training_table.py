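"""Zonal covariate summaries and the log-density training response.

One row per (aggregated) census unit: the natural-log population density
response, the unit area, the census count, and one zonal summary per
covariate layer — means for continuous/distance layers, class proportions
for binary masks, and the modal class for categorical layers.  Units with
zero counts are removed before fitting (the log response is undefined
there) but remain available for prediction and redistribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .census import CensusFrame
from .raster_prep import CovariateLayer, LayerKind, require_aligned_stack

log = logging.getLogger(__name__)

_META_COLS = ("count", "area_km2", "response")


@dataclass
class TrainingTable:
    """Response + covariate matrix keyed by unit_id.

    ``data`` is indexed by unit_id with columns ``count``, ``area_km2``,
    ``response`` (= ln(count / area_km2), people per km² logged) followed by
    one column per covariate.  ``dropped_zero_count`` lists the unit ids
    removed because their count was zero.
    """

    data: pd.DataFrame
    dropped_zero_count: list = field(default_factory=list)
    density_unit: str = "people per km^2 (natural log)"

    def __post_init__(self) -> None:
        for col in _META_COLS:
            if col not in self.data.columns:
                raise ValueError(f"training table missing column {col!r}")
        if (self.data["count"] == 0).any():
            raise ValueError("training table must not contain zero-count rows")
        if not np.isfinite(self.data["response"]).all():
            raise ValueError("non-finite response values in training table")

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in _META_COLS]

    @property
    def n_units(self) -> int:
        return len(self.data)

    @property
    def X(self) -> np.ndarray:
        return self.data[self.covariate_names].to_numpy(dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        return self.data["response"].to_numpy(dtype=np.float64)

    def subset_covariates(self, names: list[str]) -> "TrainingTable":
        keep = list(_META_COLS) + list(names)
        return TrainingTable(
            self.data[keep].copy(),
            dropped_zero_count=list(self.dropped_zero_count),
            density_unit=self.density_unit,
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="unit_id")

    @classmethod
    def from_csv(cls, path) -> "TrainingTable":
        return cls(pd.read_csv(path, index_col="unit_id"))


def zonal_aggregate(
    stack: list[CovariateLayer],
    unit_raster: np.ndarray,
    census: CensusFrame,
) -> pd.DataFrame:
    """Per-unit zonal covariate summaries.

    ``unit_raster`` labels pixels with row positions into ``census.table``
    (-1 outside).  Continuous/distance layers are zonally averaged; binary
    class masks are averaged too (giving the class proportion); categorical
    layers take the zonal mode with ties broken to the smallest class code.
    Nodata pixels are excluded from each statistic.  Units with zero pixels
    are dropped with a warning.

    Returns a DataFrame indexed by unit_id, one column per layer.
    """
    require_aligned_stack(stack)
    labels = np.asarray(unit_raster)
    n_units = len(census)
    pixel_counts = np.bincount(labels[labels >= 0].ravel(), minlength=n_units)

    out = pd.DataFrame(index=pd.Index(census.unit_ids, name="unit_id"))
    flat_labels = labels.ravel()
    inside = flat_labels >= 0
    for layer in stack:
        vals = layer.values.ravel()
        ok = inside & np.isfinite(vals)
        lab = flat_labels[ok]
        v = vals[ok]
        if layer.kind is LayerKind.CATEGORICAL:
            col = np.full(n_units, np.nan)
            best = np.zeros(n_units, dtype=np.int64)
            for code in np.unique(v):
                cnt = np.bincount(lab[v == code], minlength=n_units)
                better = cnt > best
                col[better] = code
                best = np.maximum(best, cnt)
        else:
            sums = np.bincount(lab, weights=v, minlength=n_units)
            cnts = np.bincount(lab, minlength=n_units)
            with np.errstate(invalid="ignore"):
                col = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        out[layer.name] = col

    empty = pixel_counts == 0
    if empty.any():
        dropped = [census.unit_ids[i] for i in np.flatnonzero(empty)]
        log.warning("dropping %d units with zero pixels: %s", len(dropped), dropped)
        out = out.loc[[u for u in out.index if u not in set(dropped)]]
    return out


def build_training_table(
    census: CensusFrame,
    covariate_rows: pd.DataFrame,
    transform: str = "ln",
) -> TrainingTable:
    """Attach counts/areas and the log-density response to zonal covariates.

    Density is ``count / area_km2`` (people per km², area from the projected
    unit geometry); the response is its natural log by default.  ``log10``
    and ``sqrt`` transforms exist for comparison runs but the natural log is
    the production default.  Zero-count units are removed and reported.
    """
    areas = census.areas_km2()
    if (areas <= 0).any():
        bad = [census.unit_ids[i] for i in np.flatnonzero(areas <= 0)]
        raise ValueError(f"non-positive areas for units {bad}")
    meta = pd.DataFrame(
        {
            "count": census.counts,
            "area_km2": areas,
        },
        index=pd.Index(census.unit_ids, name="unit_id"),
    )
    meta = meta.loc[covariate_rows.index]

    zero = meta["count"] == 0
    dropped = list(meta.index[zero])
    if zero.all():
        raise ValueError("all census units have zero counts; nothing to fit")
    if dropped:
        log.info("removed %d zero-count units from training: %s", len(dropped), dropped)
    meta = meta.loc[~zero]

    density = meta["count"] / meta["area_km2"]
    if transform == "ln":
        response = np.log(density)
    elif transform == "log10":
        response = np.log10(density)
    elif transform == "sqrt":
        response = np.sqrt(density)
    else:
        raise ValueError(f"unknown response transform {transform!r}")
    meta["response"] = response

    data = meta.join(covariate_rows.loc[meta.index])
    if data[covariate_rows.columns].isna().any().any():
        bad = data.columns[data.isna().any()].tolist()
        raise ValueError(f"missing covariate values in columns {bad}; fill gaps first")
    unit = {
        "ln": "people per km^2 (natural log)",
        "log10": "people per km^2 (log10)",
        "sqrt": "people per km^2 (square root)",
    }[transform]
    if len(data) < 2:
        raise ValueError("need at least 2 non-zero-count units to fit a model")
    return TrainingTable(data, dropped_zero_count=dropped, density_unit=unit)
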