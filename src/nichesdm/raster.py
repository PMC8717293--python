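"""Gridded climate layers on a shared geographic lon/lat grid.

A :class:`ClimateStack` is the environmental universe for both the niche
comparisons and the distribution models: a set of named 2-D layers (e.g.
bioclim variables ``bio4``, ``bio5`` ...) on a common north-up WGS84 grid
with a shared nodata mask.  I/O is plain multi-band GeoTIFF (baseline tags:
ModelPixelScale, ModelTiepoint, GDAL_NODATA) written and read with
:mod:`tifffile`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridTransform", "ClimateStack", "SuitabilityMap", "LayerMismatchError"]

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

_NODATA_FILL = -9999.0


class LayerMismatchError(KeyError):
    """A requested climate layer is not present in the stack."""


@dataclass(frozen=True)
class GridTransform:
    """North-up geographic grid: cell (0, 0) is the north-west corner cell.

    Cells are half-open ``[west, east) x (south, north]`` in the raster
    convention: column = floor((lon - west) / cell_size), row =
    floor((north - lat) / cell_size).
    """

    west: float
    north: float
    cell_size: float  # degrees per cell, > 0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    def cell_of(self, lon, lat):
        """Map coordinates to (row, col) integer cell indices (vectorized)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.west) / self.cell_size).astype(int)
        row = np.floor((self.north - lat) / self.cell_size).astype(int)
        return row, col

    def cell_center(self, row, col):
        """Lon/lat of cell centres (vectorized)."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        lon = self.west + (col + 0.5) * self.cell_size
        lat = self.north - (row + 0.5) * self.cell_size
        return lon, lat


@dataclass
class ClimateStack:
    """Named raster layers sharing one grid and one nodata mask."""

    layers: dict[str, np.ndarray]
    transform: GridTransform
    nodata_mask: np.ndarray = field(default=None)  # True where nodata

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("ClimateStack needs at least one layer")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1:
            raise ValueError(f"layers have inconsistent shapes: {shapes}")
        self.layers = {k: np.asarray(v, dtype=float) for k, v in self.layers.items()}
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.shape:
                raise ValueError("nodata_mask shape does not match layers")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_valid(self) -> int:
        return int((~self.nodata_mask).sum())

    def require_layers(self, names) -> None:
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise LayerMismatchError(
                f"layers {missing} not in stack (has {self.layer_names})"
            )

    def contains(self, lon, lat):
        """Boolean mask: points falling inside the raster extent."""
        row, col = self.transform.cell_of(lon, lat)
        nrow, ncol = self.shape
        return (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)

    def valid_cells(self):
        """(rows, cols) index arrays of all non-nodata cells, row-major order."""
        rows, cols = np.nonzero(~self.nodata_mask)
        return rows, cols

    def env_matrix(self, names, rows, cols) -> np.ndarray:
        """Stack layer values at given cells into an (n, k) matrix."""
        self.require_layers(names)
        return np.column_stack([self.layers[n][rows, cols] for n in names])

    def with_layers(self, names) -> "ClimateStack":
        """Sub-stack restricted to the named layers (shared mask/transform)."""
        self.require_layers(names)
        return ClimateStack(
            layers={n: self.layers[n] for n in names},
            transform=self.transform,
            nodata_mask=self.nodata_mask,
        )

    # -- GeoTIFF I/O -----------------------------------------------------
    def to_geotiff(self, path) -> None:
        """Write as a multi-band GeoTIFF (band order = layer order)."""
        import tifffile

        data = np.stack([self.layers[n] for n in self.layer_names]).astype("float32")
        data[:, self.nodata_mask] = _NODATA_FILL
        cs = self.transform.cell_size
        meta = {
            "layer_names": self.layer_names,
            "transform": {
                "west": self.transform.west,
                "north": self.transform.north,
                "cell_size": cs,
            },
        }
        extratags = [
            (_TAG_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
            (
                _TAG_MODEL_TIEPOINT,
                "d",
                6,
                (0.0, 0.0, 0.0, self.transform.west, self.transform.north, 0.0),
            ),
            (_TAG_GDAL_NODATA, "s", 0, str(_NODATA_FILL)),
        ]
        kwargs = {"planarconfig": "separate"} if data.shape[0] > 1 else {}
        tifffile.imwrite(
            path,
            data if data.shape[0] > 1 else data[0],
            photometric="minisblack",
            description=json.dumps(meta),
            extratags=extratags,
            **kwargs,
        )

    @classmethod
    def from_geotiff(cls, path) -> "ClimateStack":
        import tifffile

        with tifffile.TiffFile(path) as tif:
            data = tif.asarray().astype(float)
            page = tif.pages[0]
            desc = page.description or ""
            tags = {t.code: t.value for t in page.tags.values()}
        if data.ndim == 2:
            data = data[None]
        names = None
        transform = None
        if desc:
            try:
                meta = json.loads(desc)
                names = meta.get("layer_names")
                t = meta.get("transform", {})
                transform = GridTransform(t["west"], t["north"], t["cell_size"])
            except (ValueError, KeyError):
                pass
        if transform is None:
            scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
            tie = tags.get(_TAG_MODEL_TIEPOINT)
            if scale is None or tie is None:
                raise ValueError(f"{path}: no georeferencing tags found")
            transform = GridTransform(west=tie[3], north=tie[4], cell_size=scale[0])
        if names is None:
            names = [f"band{i + 1}" for i in range(data.shape[0])]
        nodata = float(tags.get(_TAG_GDAL_NODATA, _NODATA_FILL))
        mask = np.any(data == nodata, axis=0) | np.any(~np.isfinite(data), axis=0)
        layers = {n: np.where(mask, np.nan, d) for n, d in zip(names, data)}
        return cls(layers=layers, transform=transform, nodata_mask=mask)


@dataclass
class SuitabilityMap:
    """Per-cell habitat suitability in [0, 1] on a ClimateStack grid.

    ``values`` is NaN on nodata cells; ``scenario`` tags the climate the map
    was projected onto (e.g. ``current``, ``ssp585-2081-2100``).
    """

    values: np.ndarray
    transform: GridTransform
    scenario: str = "current"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1]")

    @property
    def nodata_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def to_geotiff(self, path) -> None:
        ClimateStack(
            layers={f"suitability_{self.scenario}": self.values},
            transform=self.transform,
            nodata_mask=self.nodata_mask,
        ).to_geotiff(path)
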