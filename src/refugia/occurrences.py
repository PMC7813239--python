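"""Occurrence record preparation and background-point sampling.

Implements the presence-data hygiene used for presence-background
modelling: drop flagged records (the stand-in for manual inspection and
provider exclusions), drop records whose coordinate uncertainty exceeds
a threshold (default 1 km), collapse exact coordinate duplicates to a
single entry, split off hold-out validation sites by region, and sample
background ("pseudo-absence") points from a chosen spatial extent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import Polygon, box

from .raster import Grid

__all__ = [
    "OccurrenceSet",
    "RegionMask",
    "filter_occurrences",
    "split_holdout",
    "sample_background",
]

_COLUMNS = ["x", "y", "uncertainty_m", "source", "flagged"]


@dataclass
class OccurrenceSet:
    """Point occurrence records with coordinate uncertainty and QC flags."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns: {missing}")
        self.records = df[_COLUMNS].reset_index(drop=True).astype(
            {"x": float, "y": float, "uncertainty_m": float, "flagged": bool}
        )
        if not np.all(np.isfinite(self.records[["x", "y"]].to_numpy())):
            raise ValueError("occurrence coordinates must be finite")
        if np.any(self.records["uncertainty_m"] <= 0):
            raise ValueError("uncertainty_m must be positive")

    @classmethod
    def from_arrays(
        cls,
        x: Sequence[float],
        y: Sequence[float],
        uncertainty_m: Sequence[float] | float = 100.0,
        source: Sequence[str] | str = "synthetic",
        flagged: Sequence[bool] | bool = False,
    ) -> "OccurrenceSet":
        n = len(x)
        df = pd.DataFrame(
            {
                "x": np.asarray(x, dtype=float),
                "y": np.asarray(y, dtype=float),
                "uncertainty_m": np.broadcast_to(np.asarray(uncertainty_m, dtype=float), n).copy(),
                "source": np.broadcast_to(np.asarray(source, dtype=object), n).copy(),
                "flagged": np.broadcast_to(np.asarray(flagged, dtype=bool), n).copy(),
            }
        )
        return cls(df)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def xy(self) -> np.ndarray:
        return self.records[["x", "y"]].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OccurrenceSet":
        return cls(pd.read_csv(path))


@dataclass
class RegionMask:
    """A spatial region given either as a polygon or a boolean grid.

    Polygon masks use point-in-polygon semantics; grid masks mark
    eligible cells True.  Exactly one of the two must be supplied.
    """

    polygon: Polygon | None = None
    grid: Grid | None = None

    def __post_init__(self) -> None:
        if (self.polygon is None) == (self.grid is None):
            raise ValueError("RegionMask needs exactly one of polygon or grid")
        if self.polygon is not None and self.polygon.is_empty:
            raise ValueError("polygon mask has empty interior")
        if self.grid is not None and not np.any(
            np.asarray(self.grid.values, dtype=bool) & ~self.grid.nodata_mask
        ):
            raise ValueError("grid mask has no eligible cells")

    @classmethod
    def from_bounds(cls, xmin: float, ymin: float, xmax: float, ymax: float) -> "RegionMask":
        return cls(polygon=box(xmin, ymin, xmax, ymax))

    def contains_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.polygon is not None:
            return contains_xy(self.polygon, x, y)
        rows, cols = self.grid.cell_index(x, y)
        nr, nc = self.grid.shape
        inside = (rows >= 0) & (rows < nr) & (cols >= 0) & (cols < nc)
        out = np.zeros(x.shape, dtype=bool)
        ok = np.asarray(self.grid.values, dtype=bool) & ~self.grid.nodata_mask
        out[inside] = ok[rows[inside], cols[inside]]
        return out

    def eligible_cells(self, template: Grid) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of unmasked template cells whose centers fall inside."""
        rows, cols = np.nonzero(~template.nodata_mask)
        x, y = template.cell_center(rows, cols)
        inside = self.contains_points(x, y)
        return rows[inside], cols[inside]


def filter_occurrences(occ: OccurrenceSet, max_uncertainty_m: float = 1000.0) -> OccurrenceSet:
    """Apply the standard record filter.

    Drops flagged records, drops records with coordinate uncertainty
    above ``max_uncertainty_m`` (default 1 km), and keeps a single entry
    per exact (x, y) pair.  Output order is deterministic (sorted by y
    then x) which makes the operation idempotent.
    """
    df = occ.records
    df = df[~df["flagged"]]
    df = df[df["uncertainty_m"] <= max_uncertainty_m]
    df = df.sort_values(["y", "x", "uncertainty_m"], kind="mergesort")
    df = df.drop_duplicates(subset=["x", "y"], keep="first")
    if df.empty:
        raise ValueError(
            "no occurrence records survive filtering; inspect uncertainties and flags"
        )
    return OccurrenceSet(df.reset_index(drop=True))


def split_holdout(occ: OccurrenceSet, region: RegionMask) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Partition records into (train, holdout) by membership in ``region``."""
    inside = region.contains_points(occ.records["x"].to_numpy(), occ.records["y"].to_numpy())
    if not inside.any():
        warnings.warn("hold-out region contains no occurrence records", stacklevel=2)
    train = occ.records[~inside].reset_index(drop=True)
    holdout = occ.records[inside].reset_index(drop=True)
    return (
        OccurrenceSet(train) if len(train) else _empty_set(),
        OccurrenceSet(holdout) if len(holdout) else _empty_set(),
    )


def _empty_set() -> OccurrenceSet:
    obj = OccurrenceSet.__new__(OccurrenceSet)
    obj.records = pd.DataFrame(columns=_COLUMNS)
    return obj


def sample_background(
    mask: RegionMask,
    template: Grid,
    n: int,
    seed: int,
) -> np.ndarray:
    """Sample ``n`` background points uniformly from cells inside ``mask``.

    Points land on centers of unmasked template cells; cells are drawn
    with replacement (the requested counts can exceed the number of
    distinct eligible cells on small extents).  Returns an (n, 2) array
    of (x, y).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rows, cols = mask.eligible_cells(template)
    if rows.size == 0:
        raise ValueError("mask contains no unmasked template cells")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, rows.size, size=n)
    x, y = template.cell_center(rows[idx], cols[idx])
    return np.column_stack([x, y])
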