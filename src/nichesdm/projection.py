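"""Projection of the consensus model onto climate rasters and downstream
range-change and country-risk products.

A fitted ensemble is projected cell-by-cell onto a (current or future)
climate stack, binarized at the equal-sensitivity/specificity threshold,
and pairs of binary maps are differenced into the four range-change
categories (never-suitable / new / stable / disappearance).  Country-level
invasion risk is the mean suitability over a country's cells, binned as
minimal [0, 0.15), low [0.15, 0.25), moderate [0.25, 0.50) and high
[0.50, 1.0].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .ensemble import Ensemble
from .raster import ClimateStack, SuitabilityMap

__all__ = [
    "CHANGE_CATEGORIES",
    "RISK_BINS",
    "BinaryMap",
    "ChangeMap",
    "project",
    "binarize",
    "change_map",
    "risk_category",
    "country_risk",
]

#: change-map codes: value -> category name
CHANGE_CATEGORIES = {0: "never-suitable", 1: "new", 2: "stable", 3: "disappearance"}

#: (lower edge, label); half-open bins, upper edge = next lower edge
RISK_BINS = [(0.0, "minimal"), (0.15, "low"), (0.25, "moderate"), (0.50, "high")]


class GridMismatchError(ValueError):
    pass


def project(ens: Ensemble, stack: ClimateStack, scenario: str = "current",
            variables: list[str] | None = None) -> SuitabilityMap:
    """Ensemble suitability for every valid cell of a climate stack.

    ``variables`` fixes the predictor order (defaults to the order used in
    training, i.e. the first member's training variables are unknown here,
    so pass the chosen variable list of the run); nodata propagates as NaN.
    """
    if variables is None:
        raise ValueError("pass the chosen variable list used to train the ensemble")
    stack.require_layers(variables)
    rows, cols = stack.valid_cells()
    X = stack.env_matrix(variables, rows, cols)
    values = np.full(stack.shape, np.nan)
    values[rows, cols] = np.clip(ens.predict(X), 0.0, 1.0)
    return SuitabilityMap(values=values, transform=stack.transform, scenario=scenario)


@dataclass
class BinaryMap:
    """Suitable (True) / unsuitable (False) cells; NaN-backed nodata mask."""

    suitable: np.ndarray
    nodata_mask: np.ndarray
    transform: object
    threshold: float
    scenario: str = "current"

    @property
    def n_suitable(self) -> int:
        return int(self.suitable[~self.nodata_mask].sum())


def binarize(smap: SuitabilityMap, threshold: float) -> BinaryMap:
    """Cell suitable iff suitability >= threshold (boundary counts in)."""
    nodata = smap.nodata_mask
    suitable = np.zeros(smap.values.shape, dtype=bool)
    ok = ~nodata
    suitable[ok] = smap.values[ok] >= threshold
    return BinaryMap(
        suitable=suitable,
        nodata_mask=nodata,
        transform=smap.transform,
        threshold=threshold,
        scenario=smap.scenario,
    )


@dataclass
class ChangeMap:
    """Per-cell range-change category between a current and a future map."""

    categories: np.ndarray  # int codes per CHANGE_CATEGORIES; -1 on nodata
    transform: object
    scenario: str
    counts: dict[str, int]

    def fractions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        return {k: v / total for k, v in self.counts.items()} if total else {}


def change_map(current: BinaryMap, future: BinaryMap) -> ChangeMap:
    """Classify each cell by its (current, future) suitability pair."""
    if current.suitable.shape != future.suitable.shape:
        raise GridMismatchError("binary maps are on different grids")
    nodata = current.nodata_mask | future.nodata_mask
    codes = np.full(current.suitable.shape, -1, dtype=int)
    ok = ~nodata
    cur, fut = current.suitable, future.suitable
    codes[ok & ~cur & ~fut] = 0
    codes[ok & ~cur & fut] = 1
    codes[ok & cur & fut] = 2
    codes[ok & cur & ~fut] = 3
    counts = {
        name: int((codes == code).sum()) for code, name in CHANGE_CATEGORIES.items()
    }
    return ChangeMap(
        categories=codes,
        transform=current.transform,
        scenario=future.scenario,
        counts=counts,
    )


def risk_category(mean_suitability: float) -> str:
    """Step function over the four risk bins (half-open on the right)."""
    if not 0 <= mean_suitability <= 1:
        raise ValueError(f"mean suitability outside [0, 1]: {mean_suitability}")
    label = RISK_BINS[0][1]
    for lower, name in RISK_BINS:
        if mean_suitability >= lower:
            label = name
    return label


def country_risk(
    smap: SuitabilityMap,
    countries: list[tuple[str, shapely.Geometry]],
    area_weighted: bool = False,
) -> pd.DataFrame:
    """Mean suitability and risk category per country.

    A cell belongs to a country when its centre lies inside (or on the
    boundary of) the country polygon.  Means are plain cell averages by
    default; ``area_weighted`` weights each cell by cos(latitude) to
    account for meridian convergence.  Countries with no covered cells are
    reported with NaN mean and category ``no-data``.
    """
    values = smap.values
    ok = np.isfinite(values)
    rows, cols = np.nonzero(ok)
    lon, lat = smap.transform.cell_center(rows, cols)
    vals = values[rows, cols]
    w = np.cos(np.radians(lat)) if area_weighted else np.ones_like(vals)

    records = []
    for name, geom in countries:
        if not geom.is_valid:
            raise ValueError(f"invalid geometry for country {name!r}")
        shapely.prepare(geom)
        inside = shapely.intersects_xy(geom, lon, lat)
        if not inside.any():
            records.append(
                {
                    "country": name,
                    "scenario": smap.scenario,
                    "mean_suitability": np.nan,
                    "category": "no-data",
                    "n_cells": 0,
                }
            )
            continue
        mean = float(np.average(vals[inside], weights=w[inside]))
        records.append(
            {
                "country": name,
                "scenario": smap.scenario,
                "mean_suitability": mean,
                "category": risk_category(mean),
                "n_cells": int(inside.sum()),
            }
        )
    return pd.DataFrame.from_records(records)
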