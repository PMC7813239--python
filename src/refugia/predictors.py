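"""Derivation of the six habitat predictors from raw grids.

From a fine-resolution DEM and vegetation map plus coarse climate grids
this module builds the predictor stack used for suitability modelling,
in canonical layer order:

1. ``roughness``     terrain roughness (m): max minus min elevation over a
                     cell's 3x3 neighbourhood, averaged up to the
                     analysis grid — a surrogate for rocky refugia;
2. ``aspect_north``  percentage of north-facing fine cells per coarse cell;
3. ``woodland``      fraction of woodland/forest cover;
4. ``grassland``     fraction of grassland/shrubland/sedgeland cover;
5. ``tmin_july``     minimum temperature of the coldest month (deg C);
6. ``precip_ann``    mean annual precipitation (mm).

Vegetation fractions omit excluded classes (water, cleared land,
unknown) from their denominators.  Collinearity among predictors is
screened with Spearman's rank correlation over an explicit point set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter, minimum_filter
from scipy.stats import spearmanr

from .raster import Grid, GridStack, _block_sum, aggregate_fraction, block_reduce_mean
from .landscape import VEG_WOODLAND, VEG_GRASSLAND, VEG_WATER, VEG_CLEARED

__all__ = [
    "PredictorConfig",
    "CANONICAL_ORDER",
    "roughness",
    "aspect_north_fraction",
    "vegetation_fractions",
    "spearman_matrix",
    "build_predictor_stack",
]

CANONICAL_ORDER = ["roughness", "aspect_north", "woodland", "grassland", "tmin_july", "precip_ann"]


@dataclass
class PredictorConfig:
    """Predictor-derivation settings.

    ``aspect_north_window`` is the compass interval (degrees, clockwise
    from north) counted as "north-facing"; the default [315, 45) is the
    symmetric quadrant around north.  Code sets partition the vegetation
    classes; ``excluded_codes`` leave fraction denominators entirely.
    """

    aspect_north_window: tuple[float, float] = (315.0, 45.0)
    woodland_codes: frozenset = frozenset({VEG_WOODLAND})
    grassland_codes: frozenset = frozenset({VEG_GRASSLAND})
    excluded_codes: frozenset = frozenset({VEG_WATER, VEG_CLEARED})
    aggregation_factor: int = 4

    def __post_init__(self) -> None:
        self.woodland_codes = frozenset(self.woodland_codes)
        self.grassland_codes = frozenset(self.grassland_codes)
        self.excluded_codes = frozenset(self.excluded_codes)
        self.aspect_north_window = tuple(self.aspect_north_window)
        lo, hi = self.aspect_north_window
        if lo % 360 == hi % 360:
            raise ValueError("aspect window is empty")
        sets = [self.woodland_codes, self.grassland_codes, self.excluded_codes]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("vegetation code sets must be pairwise disjoint")


def roughness(elevation: Grid) -> Grid:
    """Terrain roughness: max minus min elevation over the 3x3 neighbourhood.

    Neighbourhoods are truncated at grid edges and at nodata cells; a
    cell needs at least 2 valid cells in its neighbourhood, otherwise it
    becomes nodata.  Result is in the elevation unit (m) on the same grid.
    """
    nr, nc = elevation.shape
    if nr < 2 or nc < 2:
        raise ValueError(f"roughness needs at least a 2x2 grid, got {elevation.shape}")
    vals = elevation.values
    mask = elevation.nodata_mask
    hi = np.where(mask, -np.inf, vals)
    lo = np.where(mask, np.inf, vals)
    nb_max = maximum_filter(hi, size=3, mode="constant", cval=-np.inf)
    nb_min = minimum_filter(lo, size=3, mode="constant", cval=np.inf)
    # count of valid cells in each neighbourhood
    count = _neighbourhood_sum((~mask).astype(float))
    out_mask = count < 2
    rough = np.where(out_mask, 0.0, nb_max - nb_min)
    return elevation.like(rough, out_mask)


def _neighbourhood_sum(a: np.ndarray) -> np.ndarray:
    p = np.pad(a, 1, mode="constant")
    return sum(
        p[1 + di : 1 + di + a.shape[0], 1 + dj : 1 + dj + a.shape[1]]
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
    )


def fine_cell_aspect(fine_elevation: Grid) -> np.ndarray:
    """Downslope compass aspect (degrees clockwise from north) per fine cell.

    Gradients come from central differences (one-sided at edges); the
    aspect is the direction of steepest descent.  Flat cells and cells
    whose difference stencil touches nodata come back as NaN.
    """
    vals = np.where(fine_elevation.nodata_mask, np.nan, fine_elevation.values)
    cs = fine_elevation.cell_size
    # axis 0 is row: y (northing) decreases with row index
    dz_dsouth, dz_deast = np.gradient(vals, cs)
    dz_dnorth = -dz_dsouth
    down_east, down_north = -dz_deast, -dz_dnorth
    flat = (down_east == 0) & (down_north == 0)
    aspect = np.degrees(np.arctan2(down_east, down_north)) % 360.0
    aspect[flat] = np.nan
    return aspect


def _in_window(angles: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window[0] % 360.0, window[1] % 360.0
    with np.errstate(invalid="ignore"):
        if lo < hi:
            return (angles >= lo) & (angles < hi)
        return (angles >= lo) | (angles < hi)


def aspect_north_fraction(fine_elevation: Grid, config: PredictorConfig) -> Grid:
    """Percentage of north-facing fine cells per coarse cell.

    Flat fine cells have no defined aspect and are excluded from both
    numerator and denominator; a coarse cell whose fine block is all
    flat (or nodata) becomes nodata.  Values are percentages in [0, 100].
    """
    factor = config.aggregation_factor
    fr, fc = fine_elevation.shape
    if fr % factor or fc % factor:
        raise ValueError(
            f"fine grid {fine_elevation.shape} not divisible by aggregation factor {factor}"
        )
    aspect = fine_cell_aspect(fine_elevation)
    defined = np.isfinite(aspect)
    north = defined & _in_window(aspect, config.aspect_north_window)
    cr, cc = fr // factor, fc // factor
    num = _block_sum(north.astype(float), factor, cr, cc)
    den = _block_sum(defined.astype(float), factor, cr, cc)
    frac = np.where(den > 0, 100.0 * num / np.maximum(den, 1), 0.0)
    return Grid(frac, den == 0, fine_elevation.cell_size * factor, fine_elevation.origin,
                fine_elevation.crs_tag)


def vegetation_fractions(fine_codes: Grid, config: PredictorConfig) -> tuple[Grid, Grid]:
    """(woodland, grassland) cover fractions on the coarse grid."""
    woodland = aggregate_fraction(
        fine_codes, set(config.woodland_codes), set(config.excluded_codes), config.aggregation_factor
    )
    grassland = aggregate_fraction(
        fine_codes, set(config.grassland_codes), set(config.excluded_codes), config.aggregation_factor
    )
    return woodland, grassland


def spearman_matrix(stack: GridStack, xy: np.ndarray, names: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Spearman rank correlations of predictors at given points.

    The point set (presences, background, or both) is an explicit
    argument because the correlation structure depends on it.  Constant
    predictors yield NaN (undefined) against every other predictor, not 0.
    """
    names = names or stack.names
    xy = np.asarray(xy, dtype=float)
    if xy.shape[0] < 3:
        raise ValueError("need at least 3 points for a rank correlation")
    template = stack.template
    rows, cols = template.cell_index(xy[:, 0], xy[:, 1])
    values = stack.values_at(rows, cols, names)
    ok = np.all(np.isfinite(values), axis=1) & ~stack.combined_mask()[rows, cols]
    values = values[ok]
    if values.shape[0] < 3:
        raise ValueError("fewer than 3 points carry complete predictor values")
    corr, _ = spearmanr(values)
    if values.shape[1] == 2:  # spearmanr collapses 2 columns to a scalar
        corr = np.array([[1.0, corr], [corr, 1.0]])
    corr = np.atleast_2d(corr)
    # spearmanr leaves constant columns as NaN already; force the diagonal to 1
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=names, columns=names)


def build_predictor_stack(
    fine: GridStack,
    coarse_climate: GridStack,
    config: PredictorConfig,
) -> GridStack:
    """Assemble the six-layer predictor stack in canonical order.

    Roughness is computed at the fine resolution and mean-aggregated to
    the analysis grid; aspect percentage and vegetation fractions are
    block statistics; climate layers pass through.
    """
    factor = config.aggregation_factor
    rough_fine = roughness(fine["elevation"])
    rough = block_reduce_mean(rough_fine, factor)
    aspect = aspect_north_fraction(fine["elevation"], config)
    woodland, grassland = vegetation_fractions(fine["vegetation"], config)
    stack = GridStack()
    for name, grid in [
        ("roughness", rough),
        ("aspect_north", aspect),
        ("woodland", woodland),
        ("grassland", grassland),
        ("tmin_july", coarse_climate["tmin_july"]),
        ("precip_ann", coarse_climate["precip_ann"]),
    ]:
        stack.add(name, grid)
    return stack


def write_predictor_stack(stack: GridStack, directory: str | Path) -> Path:
    """Write one GeoTIFF per predictor plus a manifest in canonical order."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ordered = GridStack({name: stack[name] for name in CANONICAL_ORDER if name in stack})
    return ordered.write(directory, manifest_name="predictors.json")
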