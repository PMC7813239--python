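"""Synthetic landscapes and virtual-species occurrences.

Generates raster inputs with the statistical structure the downstream
analysis assumes — a spatially autocorrelated elevation surface, climate
fields correlated with elevation and latitude, and a categorical
vegetation mosaic with excluded classes — plus occurrence records
sampled from a *known* suitability surface.  Because the ground truth is
known, the whole pipeline can be exercised as a parameter-recovery
experiment: the fitted model should rediscover the saturating terrain
response and the unimodal climate responses that generated the data.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .occurrences import OccurrenceSet
from .raster import Grid, GridStack, block_reduce_mean

__all__ = [
    "LandscapeConfig",
    "TruthParams",
    "generate_landscape",
    "true_suitability",
    "sample_occurrences",
]

# vegetation class codes of the synthetic mosaic
VEG_WOODLAND = 1
VEG_GRASSLAND = 2
VEG_HEATH = 3       # valid but neither woodland nor grassland
VEG_WATER = 4       # excluded from fraction denominators
VEG_CLEARED = 5     # excluded from fraction denominators


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape generator.

    The defaults emulate a temperate south-eastern Australian setting at
    desk scale: a 120x120 coarse grid of 1 km cells with a 4x4 fine
    subgrid (250 m) per coarse cell, elevations to 1500 m, a winter
    minimum-temperature field driven by an atmospheric lapse rate and a
    latitudinal gradient, and an annual-precipitation field with an
    orographic (elevation-driven) component.
    """

    shape: tuple[int, int] = (120, 120)
    fine_factor: int = 4
    cell_size: float = 1000.0               # coarse cell edge, m
    elevation_scale_m: float = 1500.0
    elevation_smooth: float = 2.5           # gaussian sigma, fine cells
    vegetation_smooth: float = 8.0          # gaussian sigma, fine cells
    # tmin (deg C): base - lapse*elevation + row gradient + noise
    tmin_base_c: float = 11.0
    lapse_c_per_m: float = 6.5e-3
    tmin_row_gradient: float = -0.035       # deg C per coarse row (southward cooling)
    tmin_noise_sd: float = 0.4
    # precipitation (mm/yr): base + orographic*elevation + row gradient + noise
    precip_base_mm: float = 450.0
    orographic_mm_per_m: float = 0.55
    precip_row_gradient: float = 1.2        # mm per coarse row
    precip_noise_sd: float = 30.0
    # cumulative class proportions of the vegetation mosaic
    veg_classes: tuple[int, ...] = (VEG_WOODLAND, VEG_GRASSLAND, VEG_HEATH, VEG_WATER, VEG_CLEARED)
    veg_proportions: tuple[float, ...] = (0.40, 0.30, 0.15, 0.05, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape[0] < 1 or self.shape[1] < 1:
            raise ValueError(f"shape must be positive, got {self.shape}")
        if self.fine_factor < 1:
            raise ValueError("fine_factor must be >= 1")
        if len(self.veg_classes) != len(self.veg_proportions):
            raise ValueError("veg_classes and veg_proportions lengths differ")
        if not np.isclose(sum(self.veg_proportions), 1.0):
            raise ValueError("veg_proportions must sum to 1")

    @property
    def fine_shape(self) -> tuple[int, int]:
        return (self.shape[0] * self.fine_factor, self.shape[1] * self.fine_factor)

    @property
    def fine_cell_size(self) -> float:
        return self.cell_size / self.fine_factor


@dataclass
class TruthParams:
    """Ground-truth response of the virtual species.

    The shapes mirror what the analysis is expected to recover: a
    saturating positive terrain-roughness effect up to ``roughness_sat_m``
    (the rocky-refuge analogue of the 220 m plateau), a unimodal annual
    precipitation response falling off below ``precip_low_mm`` and above
    ``precip_high_mm``, a unimodal winter minimum-temperature response
    peaked at ``tmin_opt_c``, and a linear woodland-fraction effect.
    Terrain roughness carries the dominant coefficient by design.
    """

    roughness_sat_m: float = 220.0
    precip_opt_mm: float = 800.0
    precip_low_mm: float = 500.0
    precip_high_mm: float = 1100.0
    tmin_opt_c: float = 5.0
    tmin_width_c: float = 4.0
    coef_roughness: float = 12.0
    coef_precip: float = 2.0
    coef_tmin: float = 1.0
    coef_woodland: float = 0.8
    intercept: float = -14.0

    def __post_init__(self) -> None:
        if self.roughness_sat_m <= 0:
            raise ValueError("roughness_sat_m must be positive")
        if not (self.precip_low_mm < self.precip_opt_mm < self.precip_high_mm):
            raise ValueError("precip cuts must bracket the optimum")


def _smoothed_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if sigma > 0:
        noise = gaussian_filter(noise, sigma=sigma, mode="reflect")
    return noise


def _rescale(a: np.ndarray, lo: float, hi: float) -> np.ndarray:
    amin, amax = a.min(), a.max()
    if np.isclose(amin, amax):
        return np.full_like(a, (lo + hi) / 2)
    return lo + (a - amin) * (hi - lo) / (amax - amin)


def generate_landscape(config: LandscapeConfig) -> GridStack:
    """Generate the raw input stack of a synthetic study region.

    Returns a :class:`GridStack` with fine-resolution ``elevation`` (m)
    and ``vegetation`` (class codes) layers and coarse-resolution
    ``tmin_july`` (deg C) and ``precip_ann`` (mm) layers, plus a coarse
    ``elevation_coarse`` convenience layer (block mean).  Fine and
    coarse layers are returned in two stacks because their geometry
    differs; see the return value.

    Returns
    -------
    GridStack
        With keys ``elevation`` and ``vegetation`` on the fine grid and,
        accessible via ``generate_landscape(...).coarse``, a second stack
        holding ``tmin_july``, ``precip_ann`` and ``elevation_coarse``.
    """
    rng = np.random.default_rng(config.seed)
    fr, fc = config.fine_shape
    origin = (0.0, 0.0)

    elev_field = _smoothed_noise(rng, (fr, fc), config.elevation_smooth)
    elevation = _rescale(elev_field, 0.0, config.elevation_scale_m)
    elev_grid = Grid(elevation, None, config.fine_cell_size, origin)

    veg_field = _smoothed_noise(rng, (fr, fc), config.vegetation_smooth)
    # map the smoothed field to class codes by its own quantiles so class
    # areas match the configured proportions
    cum = np.cumsum(config.veg_proportions)[:-1]
    thresholds = np.quantile(veg_field, cum)
    veg_codes = np.asarray(config.veg_classes)[np.searchsorted(thresholds, veg_field)]
    veg_grid = Grid(veg_codes.astype(float), None, config.fine_cell_size, origin)

    fine = GridStack({"elevation": elev_grid, "vegetation": veg_grid})

    elev_coarse = block_reduce_mean(elev_grid, config.fine_factor)
    cr, cc = elev_coarse.shape
    row_idx = np.arange(cr)[:, None] * np.ones((1, cc))

    tmin = (
        config.tmin_base_c
        - config.lapse_c_per_m * elev_coarse.values
        + config.tmin_row_gradient * row_idx
        + config.tmin_noise_sd * rng.standard_normal((cr, cc))
    )
    precip = (
        config.precip_base_mm
        + config.orographic_mm_per_m * elev_coarse.values
        + config.precip_row_gradient * row_idx
        + config.precip_noise_sd * rng.standard_normal((cr, cc))
    )
    coarse = GridStack(
        {
            "elevation_coarse": elev_coarse,
            "tmin_july": elev_coarse.like(tmin, np.zeros((cr, cc), dtype=bool)),
            "precip_ann": elev_coarse.like(precip, np.zeros((cr, cc), dtype=bool)),
        }
    )
    fine.coarse = coarse  # type: ignore[attr-defined]
    return fine


def _unimodal(x: np.ndarray, opt: float, halfwidth: float) -> np.ndarray:
    """Quadratic bump: 1 at the optimum, 0 at opt +/- halfwidth, negative beyond."""
    return 1.0 - ((x - opt) / halfwidth) ** 2


def true_suitability(stack: GridStack, params: TruthParams) -> Grid:
    """Ground-truth habitat suitability of the virtual species.

    Computes ``logistic(intercept + c_r * min(roughness, r*)/r*
    + c_p * bump(precip) + c_t * bump(tmin) + c_w * woodland)`` over the
    coarse predictor stack; values lie strictly in (0, 1).
    """
    required = ["roughness", "tmin_july", "precip_ann", "woodland"]
    for name in required:
        if name not in stack:
            raise KeyError(f"true_suitability requires layer {name!r}")
    r = stack["roughness"].values
    tmin = stack["tmin_july"].values
    precip = stack["precip_ann"].values
    wood = stack["woodland"].values
    eta = (
        params.intercept
        + params.coef_roughness * np.minimum(r, params.roughness_sat_m) / params.roughness_sat_m
        + params.coef_precip
        * _unimodal(precip, params.precip_opt_mm, (params.precip_high_mm - params.precip_low_mm) / 2)
        + params.coef_tmin * _unimodal(tmin, params.tmin_opt_c, params.tmin_width_c)
        + params.coef_woodland * wood
    )
    template = stack["roughness"]
    return template.like(expit(eta), stack.combined_mask())


def sample_occurrences(
    suitability: Grid,
    n: int,
    dup_rate: float = 0.0,
    coarse_accuracy_rate: float = 0.0,
    seed: int = 0,
    jitter: bool = False,
) -> OccurrenceSet:
    """Sample virtual-species occurrence records from a suitability surface.

    Cells are drawn with replacement with probability proportional to
    suitability and converted to cell-center coordinates (optionally
    jittered within the cell).  A fraction ``dup_rate`` of the records is
    then duplicated exactly, and a fraction ``coarse_accuracy_rate`` is
    assigned a coordinate uncertainty above 1 km (2500 m) so the standard
    filter removes it; all other records get uncertainty 100 m.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= dup_rate < 1 and 0 <= coarse_accuracy_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    valid = ~suitability.nodata_mask
    weights = np.where(valid, suitability.values, 0.0).ravel()
    total = weights.sum()
    if total <= 0:
        raise ValueError("suitability is zero or nodata everywhere")
    rng = np.random.default_rng(seed)
    flat = rng.choice(weights.size, size=n, replace=True, p=weights / total)
    rows, cols = np.unravel_index(flat, suitability.shape)
    x, y = suitability.cell_center(rows, cols)
    if jitter:
        half = suitability.cell_size / 2
        x = x + rng.uniform(-half, half, size=n)
        y = y + rng.uniform(-half, half, size=n)

    uncertainty = np.full(n, 100.0)
    n_coarse = int(round(coarse_accuracy_rate * n))
    if n_coarse:
        coarse_idx = rng.choice(n, size=n_coarse, replace=False)
        uncertainty[coarse_idx] = 2500.0

    x, y = np.asarray(x), np.asarray(y)
    n_dup = int(round(dup_rate * n))
    if n_dup:
        dup_idx = rng.choice(n, size=n_dup, replace=True)
        x = np.concatenate([x, x[dup_idx]])
        y = np.concatenate([y, y[dup_idx]])
        uncertainty = np.concatenate([uncertainty, uncertainty[dup_idx]])
    return OccurrenceSet.from_arrays(x, y, uncertainty, source="virtual-species")
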