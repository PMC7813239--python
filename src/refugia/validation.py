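"""Null-group validation of hold-out translocation sites.

Asks whether the suitability predicted at a small set of hold-out sites
(a disjunct region excluded from model fitting) could plausibly arise
by chance: the observed group statistic (mean and median suitability
over the g hold-out cells) is compared against B random groups of g
distinct cells drawn uniformly from a background extent.  The p-value
uses the add-one resampling form p = (1 + #{null >= observed}) / (B + 1),
which cannot reach zero under finite resampling.  The null distribution
summary reports both the normal-approximation 95% CI of the mean of
group statistics and the empirical 2.5/97.5 percentiles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .occurrences import RegionMask
from .raster import Grid

__all__ = ["NullTestConfig", "StatisticSummary", "NullTestResult", "null_group_test", "summarize_validation"]


@dataclass
class NullTestConfig:
    group_size: int = 9
    n_groups: int = 10_000
    statistics: tuple[str, ...] = ("mean", "median")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")
        if self.n_groups < 100:
            raise ValueError("n_groups must be >= 100")
        for s in self.statistics:
            if s not in ("mean", "median"):
                raise ValueError(f"unknown statistic {s!r}")


@dataclass
class StatisticSummary:
    """Observed-vs-null summary for one group statistic."""

    observed: float
    null_mean: float
    ci_low: float
    ci_high: float
    pct_2_5: float
    pct_97_5: float
    p_value: float
    exceedance_count: int


@dataclass
class NullTestResult:
    group_size: int
    n_groups: int
    observed_values: list[float]
    statistics: dict[str, StatisticSummary]

    def to_dict(self) -> dict:
        return {
            "group_size": self.group_size,
            "n_groups": self.n_groups,
            "observed_values": self.observed_values,
            "statistics": {k: asdict(v) for k, v in self.statistics.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "NullTestResult":
        return cls(
            d["group_size"],
            d["n_groups"],
            list(d["observed_values"]),
            {k: StatisticSummary(**v) for k, v in d["statistics"].items()},
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NullTestResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


_STAT_FN = {"mean": np.mean, "median": np.median}


def _distinct_groups(n_cells: int, g: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """B uniform groups of g distinct cell indices (rejection sampling)."""
    if g > n_cells:
        raise ValueError(f"cannot draw {g} distinct cells from {n_cells}")
    idx = rng.integers(0, n_cells, size=(B, g))
    if g > 1:
        for _ in range(1000):
            s = np.sort(idx, axis=1)
            bad = np.any(s[:, 1:] == s[:, :-1], axis=1)
            if not bad.any():
                break
            idx[bad] = rng.integers(0, n_cells, size=(int(bad.sum()), g))
        else:  # pragma: no cover - tiny cell sets only
            raise RuntimeError("could not draw distinct groups; too few eligible cells")
    return idx


def null_group_test(
    suitability: Grid,
    mask: RegionMask,
    holdout_xy: np.ndarray,
    config: NullTestConfig,
) -> NullTestResult:
    """Compare hold-out site suitability against random background groups.

    ``holdout_xy`` is an (n, 2) array of site coordinates; each must fall
    on a valid suitability cell.  Groups are drawn without replacement
    within a group, independently across groups, from the unmasked cells
    inside ``mask``.  Fully reproducible from ``config.seed``.
    """
    holdout_xy = np.atleast_2d(np.asarray(holdout_xy, dtype=float))
    rows, cols = suitability.cell_index(holdout_xy[:, 0], holdout_xy[:, 1])
    nr, nc = suitability.shape
    on_grid = (rows >= 0) & (rows < nr) & (cols >= 0) & (cols < nc)
    ok = on_grid.copy()
    ok[on_grid] &= ~suitability.nodata_mask[rows[on_grid], cols[on_grid]]
    if not ok.all():
        bad = holdout_xy[~ok].tolist()
        raise ValueError(f"hold-out points off-grid or on nodata cells: {bad}")
    observed_values = suitability.values[rows, cols]

    g = len(observed_values)
    if g != config.group_size:
        warnings.warn(
            f"hold-out size {g} != configured group size {config.group_size}; using {g}",
            stacklevel=2,
        )
    erows, ecols = mask.eligible_cells(suitability)
    if erows.size < g:
        raise ValueError("fewer eligible background cells than the group size")
    rng = np.random.default_rng(config.seed)
    groups = _distinct_groups(erows.size, g, config.n_groups, rng)
    group_values = suitability.values[erows[groups], ecols[groups]]

    summaries: dict[str, StatisticSummary] = {}
    B = config.n_groups
    for stat in config.statistics:
        fn = _STAT_FN[stat]
        observed = float(fn(observed_values))
        null_stats = fn(group_values, axis=1)
        count = int(np.sum(null_stats >= observed))
        p = (1 + count) / (B + 1)
        mu = float(null_stats.mean())
        half = 1.96 * float(null_stats.std(ddof=1)) / np.sqrt(B)
        summaries[stat] = StatisticSummary(
            observed=observed,
            null_mean=mu,
            ci_low=mu - half,
            ci_high=mu + half,
            pct_2_5=float(np.percentile(null_stats, 2.5)),
            pct_97_5=float(np.percentile(null_stats, 97.5)),
            p_value=float(p),
            exceedance_count=count,
        )
    return NullTestResult(g, B, [float(v) for v in observed_values], summaries)


def summarize_validation(result: NullTestResult, alpha: float = 0.05) -> dict:
    """Human-readable + JSON-safe report of observed vs null suitability."""
    lines = [f"hold-out group of {result.group_size} sites vs {result.n_groups} null groups"]
    report: dict = {"group_size": result.group_size, "n_groups": result.n_groups, "statistics": {}}
    obs = np.asarray(result.observed_values)
    report["observed_range"] = [float(obs.min()), float(obs.max())]
    for stat, s in result.statistics.items():
        verdict = (
            "observed inconsistent with chance" if s.p_value < alpha else "consistent with chance"
        )
        lines.append(
            f"{stat}: observed {s.observed:.4g} vs null {s.null_mean:.4g} "
            f"(95% CI {s.ci_low:.4g}-{s.ci_high:.4g}); p = {s.p_value:.4g} -> {verdict}"
        )
        report["statistics"][stat] = {**asdict(s), "verdict": verdict}
    report["text"] = "\n".join(lines)
    return report
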