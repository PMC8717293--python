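"""Occurrence ingestion, cleaning, grid-thinning and environment extraction.

Occurrence sets are plain :class:`pandas.DataFrame` objects with the columns
``species, lon, lat, status, region, year`` (``status`` is one of
``native | invasive | unknown``).  The functions here take and return such
frames, mirroring how GBIF-style exports are curated before niche analysis:
invalid coordinates are dropped and counted, records are thinned to one per
(species, climate cell), and native/invasive status is assigned from range
polygons.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as _geojson_shape
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .raster import ClimateStack

__all__ = [
    "OCC_COLUMNS",
    "CleaningLog",
    "VariableSelection",
    "EnvTable",
    "make_occurrence_frame",
    "read_occurrences",
    "thin_to_grid",
    "assign_status",
    "select_variables",
    "extract_env",
    "background_env",
    "read_geojson_polygons",
]

OCC_COLUMNS = ["species", "lon", "lat", "status", "region", "year"]

# column-name aliases recognised in raw CSVs (checked case-insensitively)
_LON_ALIASES = ["lon", "decimallongitude", "longitude", "x"]
_LAT_ALIASES = ["lat", "decimallatitude", "latitude", "y"]
_SPECIES_ALIASES = ["species", "taxon", "scientificname", "name"]


class OccurrenceFormatError(ValueError):
    """Raw occurrence file lacks recognizable coordinate/taxon columns."""


@dataclass
class CleaningLog:
    """Bookkeeping for record-level cleaning steps."""

    n_read: int = 0
    n_missing_coords: int = 0
    n_invalid_coords: int = 0
    n_kept: int = 0
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def make_occurrence_frame(
    lon, lat, species="virtual", status="unknown", region="", year=None
) -> pd.DataFrame:
    """Assemble a standard occurrence frame from coordinate arrays."""
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    n = len(lon)
    return pd.DataFrame(
        {
            "species": np.broadcast_to(np.asarray(species, dtype=object), n).copy(),
            "lon": lon,
            "lat": lat,
            "status": np.broadcast_to(np.asarray(status, dtype=object), n).copy(),
            "region": np.broadcast_to(np.asarray(region, dtype=object), n).copy(),
            "year": np.broadcast_to(
                np.asarray(year if year is not None else np.nan), n
            ).copy(),
        }
    )


def _find_column(columns, aliases, override):
    if override is not None:
        if override not in columns:
            raise OccurrenceFormatError(f"configured column {override!r} not in file")
        return override
    lower = {c.lower(): c for c in columns}
    for a in aliases:
        if a in lower:
            return lower[a]
    return None


def read_occurrences(
    path,
    *,
    lon_col: str | None = None,
    lat_col: str | None = None,
    species_col: str | None = None,
    year_col: str | None = None,
) -> tuple[pd.DataFrame, CleaningLog]:
    """Read a Darwin-Core-style occurrence CSV.

    Rows with missing or out-of-range coordinates are dropped and counted in
    the returned :class:`CleaningLog`.  Duplicates are retained here; spatial
    de-duplication happens in :func:`thin_to_grid`.
    """
    try:
        raw = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise OccurrenceFormatError(f"cannot read occurrence file {path}: {exc}")

    lon_c = _find_column(raw.columns, _LON_ALIASES, lon_col)
    lat_c = _find_column(raw.columns, _LAT_ALIASES, lat_col)
    if lon_c is None or lat_c is None:
        raise OccurrenceFormatError(
            f"no coordinate columns found in {path} (columns: {list(raw.columns)})"
        )
    sp_c = _find_column(raw.columns, _SPECIES_ALIASES, species_col)
    yr_c = _find_column(raw.columns, ["year"], year_col)

    log = CleaningLog(n_read=len(raw))
    lon = pd.to_numeric(raw[lon_c], errors="coerce")
    lat = pd.to_numeric(raw[lat_c], errors="coerce")
    missing = lon.isna() | lat.isna()
    invalid = ~missing & ((lon < -180) | (lon > 180) | (lat < -90) | (lat > 90))
    keep = ~(missing | invalid)
    log.n_missing_coords = int(missing.sum())
    log.n_invalid_coords = int(invalid.sum())
    log.n_kept = int(keep.sum())
    if log.n_kept == 0:
        log.notes.append("no valid records after coordinate cleaning")
        warnings.warn(f"{path}: no valid occurrence records", stacklevel=2)

    kept = raw.loc[keep]
    status = (
        kept["status"].astype(str)
        if "status" in kept.columns
        else pd.Series("unknown", index=kept.index)
    )
    region = (
        kept["region"].astype(str)
        if "region" in kept.columns
        else pd.Series("", index=kept.index)
    )
    occ = pd.DataFrame(
        {
            "species": (
                kept[sp_c].astype(str) if sp_c else pd.Series("unknown", index=kept.index)
            ),
            "lon": lon.loc[keep].to_numpy(),
            "lat": lat.loc[keep].to_numpy(),
            "status": status.to_numpy(),
            "region": region.to_numpy(),
            "year": (
                pd.to_numeric(kept[yr_c], errors="coerce").to_numpy()
                if yr_c
                else np.full(log.n_kept, np.nan)
            ),
        }
    ).reset_index(drop=True)
    return occ, log


def thin_to_grid(occ: pd.DataFrame, stack: ClimateStack) -> pd.DataFrame:
    """Keep at most one record per (species, climate cell).

    Records outside the raster extent or on nodata cells are dropped; within a
    cell the first record in input order survives.  Idempotent.
    """
    if occ.empty:
        return occ.copy()
    row, col = stack.transform.cell_of(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    nrow, ncol = stack.shape
    inside = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
    valid = inside.copy()
    valid[inside] &= ~stack.nodata_mask[row[inside], col[inside]]
    thinned = occ.loc[valid].copy()
    thinned["_row"], thinned["_col"] = row[valid], col[valid]
    thinned = thinned.drop_duplicates(subset=["species", "_row", "_col"], keep="first")
    return thinned.drop(columns=["_row", "_col"]).reset_index(drop=True)


def read_geojson_polygons(path) -> list[tuple[str, shapely.Geometry]]:
    """Read (name, geometry) pairs from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    out = []
    for i, f in enumerate(feats):
        geom = _geojson_shape(f["geometry"])
        if not geom.is_valid:
            raise ValueError(f"invalid geometry in feature {i} of {path}")
        props = f.get("properties") or {}
        name = props.get("name") or props.get("NAME") or props.get("ADMIN") or str(i)
        out.append((str(name), geom))
    return out


def _covers_any(geoms, lon, lat) -> np.ndarray:
    """Point-in-any-polygon test; boundary points count as inside."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    hit = np.zeros(lon.shape, dtype=bool)
    for g in geoms:
        if not g.is_valid:
            raise ValueError("invalid polygon geometry")
        shapely.prepare(g)
        hit |= shapely.intersects_xy(g, lon, lat)
    return hit


def assign_status(
    occ: pd.DataFrame,
    native_polygons,
    region_polygons=None,
) -> pd.DataFrame:
    """Set ``status`` from native-range polygons: inside (or on the boundary
    of) any native polygon -> native, otherwise invasive.  Optionally tag
    ``region`` from a second (name, polygon) layer."""
    out = occ.copy()
    if out.empty:
        return out
    geoms = [g for _, g in native_polygons] if _is_named(native_polygons) else list(
        native_polygons
    )
    native = _covers_any(geoms, out["lon"].to_numpy(), out["lat"].to_numpy())
    out["status"] = np.where(native, "native", "invasive")
    if region_polygons:
        region = np.array(out["region"], dtype=object)
        for name, g in region_polygons:
            shapely.prepare(g)
            inside = shapely.intersects_xy(
                g, out["lon"].to_numpy(), out["lat"].to_numpy()
            )
            region[inside] = name
        out["region"] = region
    return out


def _is_named(polys) -> bool:
    return bool(polys) and isinstance(polys[0], tuple)


@dataclass
class VariableSelection:
    """Result of correlation-based climate-variable screening."""

    correlation_matrix: pd.DataFrame
    clusters: list[list[str]]
    chosen: list[str]
    threshold: float
    excluded_constant: list[str] = field(default_factory=list)


def select_variables(
    stack: ClimateStack,
    threshold: float = 0.8,
    preferred: tuple[str, ...] = (),
) -> VariableSelection:
    """Group collinear layers and keep one representative per group.

    Pairwise Pearson correlations over all valid cells feed a
    complete-linkage dendrogram on distance 1 - |r|, cut at 1 - threshold so
    every within-cluster pair satisfies |r| >= threshold.  Within a cluster
    the first layer listed in ``preferred`` wins; otherwise the member with
    the lowest mean |r| against all other layers (the least redundant one).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    rows, cols = stack.valid_cells()
    names = stack.layer_names
    values = {n: stack.layers[n][rows, cols] for n in names}
    constant = [n for n in names if np.std(values[n]) == 0]
    if constant:
        warnings.warn(
            f"excluding zero-variance layers from selection: {constant}", stacklevel=2
        )
    active = [n for n in names if n not in constant]
    if len(active) < 2:
        corr = pd.DataFrame(np.ones((len(active),) * 2), index=active, columns=active)
        return VariableSelection(corr, [active] if active else [], list(active), threshold, constant)

    mat = np.corrcoef(np.array([values[n] for n in active]))
    corr = pd.DataFrame(mat, index=active, columns=active)
    dist = 1.0 - np.abs(mat)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(z, t=1.0 - threshold, criterion="distance")

    mean_abs_r = (np.abs(mat).sum(axis=1) - 1.0) / max(len(active) - 1, 1)
    clusters: list[list[str]] = []
    chosen: list[str] = []
    for lab in sorted(set(labels)):
        members = [n for n, l in zip(active, labels) if l == lab]
        clusters.append(members)
        pick = next((p for p in preferred if p in members), None)
        if pick is None:
            pick = min(members, key=lambda n: (mean_abs_r[active.index(n)], n))
        chosen.append(pick)
    return VariableSelection(corr, clusters, chosen, threshold, constant)


@dataclass
class EnvTable:
    """Per-point climate values for a fixed, ordered set of variables."""

    data: pd.DataFrame  # columns = chosen variables, fixed order
    label: str = "background"  # presence | absence | background
    n_dropped: int = 0

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def extract_env(
    points: pd.DataFrame,
    stack: ClimateStack,
    chosen: list[str],
    label: str = "background",
) -> EnvTable:
    """Read the chosen layers at each point's containing cell.

    Points outside the extent or on nodata cells are dropped and counted, so
    ``len(result.data) + result.n_dropped == len(points)``.
    """
    stack.require_layers(chosen)
    lon = points["lon"].to_numpy(dtype=float)
    lat = points["lat"].to_numpy(dtype=float)
    row, col = stack.transform.cell_of(lon, lat)
    nrow, ncol = stack.shape
    inside = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
    ok = inside.copy()
    ok[inside] &= ~stack.nodata_mask[row[inside], col[inside]]
    env = pd.DataFrame(
        {n: stack.layers[n][row[ok], col[ok]] for n in chosen},
        index=points.index[ok],
    )
    return EnvTable(data=env, label=label, n_dropped=int((~ok).sum()))


def background_env(
    stack: ClimateStack,
    chosen: list[str],
    sample: int | None = None,
    seed: int | None = None,
) -> EnvTable:
    """Environment table over all valid cells (optionally subsampled)."""
    stack.require_layers(chosen)
    rows, cols = stack.valid_cells()
    if sample is not None and sample < len(rows):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(rows), size=sample, replace=False)
        rows, cols = rows[idx], cols[idx]
    env = pd.DataFrame({n: stack.layers[n][rows, cols] for n in chosen})
    return EnvTable(data=env, label="background", n_dropped=0)
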