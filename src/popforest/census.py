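"""Census-unit container: polygons + counts + a nested admin hierarchy.

A :class:`CensusFrame` is a thin, geopandas-like wrapper around a pandas
DataFrame with a shapely ``geometry`` column and the columns the dasymetric
pipeline needs: ``unit_id``, ``parent_id``, ``admin_level``, ``count``.
Units at one admin level tile their parent one level up, and population is
conserved exactly under aggregation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.ops import unary_union

from .grid import is_geographic

log = logging.getLogger(__name__)

_REQUIRED = ("unit_id", "parent_id", "admin_level", "count", "geometry")


@dataclass
class CensusFrame:
    """Census polygons with counts and one-level-up parent links.

    ``table`` must carry columns ``unit_id`` (unique), ``parent_id``
    (id of the containing unit one admin level up, or None at the top),
    ``admin_level`` (int), ``count`` (people, >= 0) and ``geometry``
    (shapely polygon/multipolygon).
    """

    table: pd.DataFrame
    crs_id: str = "local-metric"

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"census table missing columns: {missing}")
        if len(self.table) == 0:
            raise ValueError("census frame is empty")
        if self.table["unit_id"].duplicated().any():
            dups = self.table.loc[self.table["unit_id"].duplicated(), "unit_id"]
            raise ValueError(f"duplicate unit_ids: {sorted(set(dups))}")
        if (self.table["count"] < 0).any():
            raise ValueError("census counts must be non-negative")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def unit_ids(self) -> list:
        return list(self.table["unit_id"])

    @property
    def counts(self) -> np.ndarray:
        return self.table["count"].to_numpy()

    @property
    def geometries(self) -> list:
        return list(self.table["geometry"])

    @property
    def is_geographic(self) -> bool:
        return is_geographic(self.crs_id)

    def total(self) -> int:
        """National total: exact integer sum of unit counts."""
        return int(self.table["count"].sum())

    def union(self):
        """Dissolved outer boundary of all units."""
        return unary_union(self.geometries)

    def areas_km2(self) -> np.ndarray:
        """Unit areas in km² from the (projected) geometry."""
        if self.is_geographic:
            raise ValueError("areas require a projected metric CRS")
        return np.array([g.area for g in self.geometries]) / 1e6

    # -- aggregation ------------------------------------------------------

    def aggregate(self, levels_up: int = 1) -> "CensusFrame":
        """Aggregate units ``levels_up`` admin levels up the hierarchy.

        Geometries are dissolved by ancestor id, counts are summed with
        integer arithmetic, so the national total is conserved exactly.
        ``levels_up=0`` is the identity.
        """
        if levels_up < 0:
            raise ValueError("levels_up must be >= 0")
        if levels_up == 0:
            return self
        cur = self
        for _ in range(levels_up):
            cur = cur._aggregate_once()
        return cur

    def _aggregate_once(self) -> "CensusFrame":
        t = self.table
        if t["parent_id"].isna().any():
            bad = t.loc[t["parent_id"].isna(), "unit_id"].tolist()
            raise ValueError(f"units missing parent links: {bad}")
        rows = []
        for pid, grp in t.groupby("parent_id", sort=True):
            rows.append(
                {
                    "unit_id": pid,
                    "parent_id": None,
                    "admin_level": int(grp["admin_level"].iloc[0]) - 1,
                    "count": int(grp["count"].sum()),
                    "geometry": unary_union(list(grp["geometry"])),
                }
            )
        out = CensusFrame(pd.DataFrame(rows), crs_id=self.crs_id)
        assert out.total() == self.total(), "aggregation must conserve population"
        return out

    # -- I/O --------------------------------------------------------------

    def to_geojson(self, path) -> None:
        feats = []
        for _, r in self.table.iterrows():
            feats.append(
                {
                    "type": "Feature",
                    "geometry": mapping(r["geometry"]),
                    "properties": {
                        "unit_id": r["unit_id"],
                        "parent_id": r["parent_id"],
                        "admin_level": int(r["admin_level"]),
                        "count": int(r["count"]),
                    },
                }
            )
        doc = {
            "type": "FeatureCollection",
            "crs_id": self.crs_id,
            "features": feats,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_geojson(cls, path, crs_id: str | None = None) -> "CensusFrame":
        with open(path) as fh:
            doc = json.load(fh)
        rows = []
        for feat in doc["features"]:
            props = dict(feat.get("properties") or {})
            props["geometry"] = shape(feat["geometry"])
            rows.append(props)
        return cls(pd.DataFrame(rows), crs_id=crs_id or doc.get("crs_id", "local-metric"))


def aggregate_census(census: CensusFrame, levels_up: int = 1) -> CensusFrame:
    """Functional alias for :meth:`CensusFrame.aggregate`."""
    return census.aggregate(levels_up)
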