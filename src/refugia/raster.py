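"""Single-band raster data model and GeoTIFF I/O.

The :class:`Grid` is the in-memory currency of the whole pipeline: a 2-D
array of cell values on a uniform square-cell grid in an equal-area
projection, plus a boolean nodata mask that every arithmetic operation
propagates.  Coordinates follow the common raster convention: ``origin``
is the outer corner of the upper-left cell, x increases eastward with
column index, y decreases with row index, and cell *centers* are what
point lookups refer to.

Files are plain single-band GeoTIFFs.  Georeferencing is carried by the
standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA and
GeoAsciiParams), written and read through :mod:`tifffile`, so the output
opens in ordinary GIS software.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import tifffile

__all__ = ["Grid", "GridStack", "read_grid", "write_grid", "aggregate_fraction", "grid_difference"]

# GeoTIFF / GDAL private tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_ASCII_PARAMS = 34737
_TAG_GDAL_NODATA = 42113

_DEFAULT_NODATA = -9999.0


@dataclass
class Grid:
    """A single-band raster: values + nodata mask + geometry.

    Parameters
    ----------
    values
        2-D float array of cell values.  Entries under the mask are
        ignored by all operations.
    nodata_mask
        2-D boolean array, True where the cell carries no data.
    cell_size
        Edge length of the (square) cells, in the projection's linear
        unit (metres for an equal-area projection).
    origin
        (x0, y0) of the upper-left corner of the upper-left cell.
    crs_tag
        Opaque CRS label carried through I/O; never interpreted.
    """

    values: np.ndarray
    nodata_mask: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str = "local-equal-area"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError(f"Grid values must be 2-D, got {self.values.ndim}-D")
        if self.values.shape != self.nodata_mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.nodata_mask.shape}"
            )
        if not (self.cell_size > 0):
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def geometry(self) -> tuple[tuple[int, int], float, tuple[float, float], str]:
        return (self.shape, self.cell_size, self.origin, self.crs_tag)

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
            and self.crs_tag == other.crs_tag
        )

    def cell_center(self, row: np.ndarray | int, col: np.ndarray | int) -> tuple:
        """(x, y) coordinates of cell centers for the given indices."""
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin[1] - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def cell_index(self, x: np.ndarray | float, y: np.ndarray | float) -> tuple:
        """(row, col) of the cells containing the given points."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((self.origin[1] - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=self.nodata_mask)

    def copy(self) -> "Grid":
        return Grid(self.values.copy(), self.nodata_mask.copy(), self.cell_size, self.origin, self.crs_tag)

    def like(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Grid":
        """New Grid sharing this grid's geometry."""
        if mask is None:
            mask = self.nodata_mask.copy()
        return Grid(values, mask, self.cell_size, self.origin, self.crs_tag)


@dataclass
class GridStack:
    """An ordered set of co-registered :class:`Grid` layers.

    All layers must share geometry exactly; the combined nodata mask is
    the union of the layer masks.
    """

    layers: dict[str, Grid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.layers)
        for name in names[1:]:
            if not self.layers[names[0]].same_geometry(self.layers[name]):
                raise ValueError(f"layer {name!r} geometry differs from {names[0]!r}")

    def add(self, name: str, grid: Grid) -> None:
        if self.layers and not self.template.same_geometry(grid):
            raise ValueError(f"layer {name!r} geometry differs from existing layers")
        self.layers[name] = grid

    @property
    def template(self) -> Grid:
        return next(iter(self.layers.values()))

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> Grid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    def combined_mask(self) -> np.ndarray:
        mask = np.zeros(self.template.shape, dtype=bool)
        for g in self.layers.values():
            mask |= g.nodata_mask
        return mask

    def values_at(self, rows: np.ndarray, cols: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        """Extract an (n_points, n_layers) matrix of layer values at cells."""
        names = names or self.names
        return np.column_stack([self.layers[n].values[rows, cols] for n in names])

    def table(self, names: list[str] | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All jointly valid cells as (rows, cols, value matrix)."""
        valid = ~self.combined_mask()
        rows, cols = np.nonzero(valid)
        return rows, cols, self.values_at(rows, cols, names)

    def write(self, directory: str | Path, manifest_name: str = "stack.json") -> Path:
        """Write one GeoTIFF per layer plus a JSON manifest naming them in order."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        entries = []
        for name, grid in self.layers.items():
            path = directory / f"{name}.tif"
            write_grid(grid, path)
            entries.append({"name": name, "file": path.name})
        manifest = directory / manifest_name
        manifest.write_text(json.dumps({"layers": entries}, indent=2))
        return manifest

    @classmethod
    def read(cls, manifest_path: str | Path) -> "GridStack":
        manifest_path = Path(manifest_path)
        spec = json.loads(manifest_path.read_text())
        stack = cls()
        for entry in spec["layers"]:
            stack.add(entry["name"], read_grid(manifest_path.parent / entry["file"]))
        return stack


def read_grid(path: str | Path) -> Grid:
    """Read a single-band GeoTIFF into a :class:`Grid`.

    Rejects multi-band files and non-square cells; cells equal to the
    declared nodata value (GDAL_NODATA tag) come back masked.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim == 3:
            raise ValueError(f"expected a single-band raster, file has {data.shape[-1]} bands")
        if len(tif.pages) > 1:
            raise ValueError(f"expected a single-band raster, file has {len(tif.pages)} pages")
        tags = page.tags
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value if _TAG_MODEL_PIXEL_SCALE in tags else (1.0, 1.0, 0.0)
        if not np.isclose(scale[0], scale[1]):
            raise ValueError(f"non-square cells: x size {scale[0]} != y size {scale[1]}")
        tiepoint = tags[_TAG_MODEL_TIEPOINT].value if _TAG_MODEL_TIEPOINT in tags else (0, 0, 0, 0, 0, 0)
        # tiepoint maps raster (i, j) -> model (x, y); standard usage anchors (0, 0)
        origin = (float(tiepoint[3]) - float(tiepoint[0]) * scale[0],
                  float(tiepoint[4]) + float(tiepoint[1]) * scale[1])
        nodata = _DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
        crs_tag = "local-equal-area"
        if _TAG_GEO_ASCII_PARAMS in tags:
            crs_tag = str(tags[_TAG_GEO_ASCII_PARAMS].value).strip("\x00|")
    values = np.asarray(data, dtype=float)
    mask = np.isclose(values, nodata) | ~np.isfinite(values)
    values = np.where(mask, 0.0, values)
    return Grid(values, mask, float(scale[0]), origin, crs_tag)


def write_grid(grid: Grid, path: str | Path, nodata: float = _DEFAULT_NODATA) -> None:
    """Write a :class:`Grid` as a single-band GeoTIFF.

    Masked cells are stored as the declared ``nodata`` sentinel, recorded
    in the GDAL_NODATA tag so other tools recover the mask.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if np.any(np.isclose(grid.values[~grid.nodata_mask], nodata)):
        raise ValueError(f"grid contains unmasked cells equal to the nodata sentinel {nodata}")
    data = np.where(grid.nodata_mask, nodata, grid.values).astype(np.float64)
    x0, y0 = grid.origin
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GEO_ASCII_PARAMS, "s", 0, grid.crs_tag + "|"),
        (_TAG_GDAL_NODATA, "s", 0, repr(nodata)),
    ]
    tifffile.imwrite(path, data, extratags=extratags, photometric="minisblack")


def aggregate_fraction(
    fine: Grid,
    include_codes: set,
    exclude_codes: set,
    factor: int,
) -> Grid:
    """Fraction of each coarse cell covered by categories in ``include_codes``.

    Each ``factor x factor`` block of the fine categorical grid becomes one
    coarse cell whose value is::

        count(code in include_codes) / count(code not in exclude_codes)

    i.e. excluded categories (water, cleared land, unknown) leave the
    denominator entirely.  Blocks with zero valid cells become nodata.
    Edge blocks shorter than ``factor`` aggregate over the cells present.
    """
    if include_codes & exclude_codes:
        raise ValueError(f"include and exclude code sets overlap: {include_codes & exclude_codes}")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    nr, nc = fine.shape
    cr, cc = -(-nr // factor), -(-nc // factor)
    codes = fine.values
    valid = ~fine.nodata_mask & ~np.isin(codes, list(exclude_codes))
    included = valid & np.isin(codes, list(include_codes))

    num = _block_sum(included.astype(float), factor, cr, cc)
    den = _block_sum(valid.astype(float), factor, cr, cc)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    mask = den == 0
    return Grid(frac, mask, fine.cell_size * factor, fine.origin, fine.crs_tag)


def _block_sum(arr: np.ndarray, factor: int, cr: int, cc: int) -> np.ndarray:
    """Sum over factor x factor blocks, tolerating short edge blocks."""
    nr, nc = arr.shape
    padded = np.zeros((cr * factor, cc * factor), dtype=arr.dtype)
    padded[:nr, :nc] = arr
    return padded.reshape(cr, factor, cc, factor).sum(axis=(1, 3))


def block_reduce_mean(fine: Grid, factor: int) -> Grid:
    """Mean-aggregate a continuous fine grid to the coarse grid."""
    nr, nc = fine.shape
    cr, cc = -(-nr // factor), -(-nc // factor)
    vals = np.where(fine.nodata_mask, 0.0, fine.values)
    num = _block_sum(vals, factor, cr, cc)
    cnt = _block_sum((~fine.nodata_mask).astype(float), factor, cr, cc)
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, num / np.maximum(cnt, 1), 0.0)
    return Grid(mean, cnt == 0, fine.cell_size * factor, fine.origin, fine.crs_tag)


def grid_difference(a: Grid, b: Grid) -> Grid:
    """Cellwise a - b with mask union; geometries must match exactly."""
    if not a.same_geometry(b):
        raise ValueError("grid_difference requires identical geometry")
    mask = a.nodata_mask | b.nodata_mask
    diff = np.where(mask, 0.0, a.values - b.values)
    return a.like(diff, mask)
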