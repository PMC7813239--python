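"""Config-driven orchestration of the full screening analysis.

Stages (each restartable from the files the previous stages wrote):

``simulate``  synthetic landscape -> predictor stack, ground-truth
              suitability, virtual occurrence records;
``prepare``   occurrence filtering, hold-out split, background sampling
              per extent design, collinearity screen;
``evaluate``  repeated k-fold cross-validation, AUC-weighted ensemble,
              permutation importance, response curves, per design;
``predict``   ensemble suitability map per design + the between-design
              difference map;
``limiting``  limiting-factor map from a single full-data model;
``validate``  null-group test of the hold-out sites per design.

Every stochastic stage draws its seed deterministically from the master
seed and the stage name, so two runs with the same master seed produce
byte-identical numeric outputs and reordering optional stages cannot
shift downstream randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import (
    EvalConfig,
    build_ensemble,
    cross_validate,
    ensemble_predict,
    variable_importance,
)
from .landscape import LandscapeConfig, TruthParams, generate_landscape, sample_occurrences, true_suitability
from .maxent import MaxentConfig, MaxentModel, limiting_factor, response_curve, train
from .occurrences import OccurrenceSet, RegionMask, filter_occurrences, sample_background, split_holdout
from .predictors import CANONICAL_ORDER, PredictorConfig, build_predictor_stack, spearman_matrix, write_predictor_stack
from .raster import Grid, GridStack, grid_difference, read_grid, write_grid
from .validation import NullTestConfig, null_group_test, summarize_validation
from .evaluation import EnsembleModel

logger = logging.getLogger("refugia")

__all__ = ["BackgroundDesign", "RunConfig", "run_pipeline", "make_report"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class BackgroundDesign:
    """One background-extent design: a named mask and a point count."""

    name: str
    n: int
    bounds: tuple[float, float, float, float] | None = None  # None = full extent


def _default_designs() -> list[BackgroundDesign]:
    # a range-restricted extent (left ~70% of the default domain, the
    # bioregion analogue) and the full study extent
    return [
        BackgroundDesign("restricted", 10_000, (0.0, -120_000.0, 84_000.0, 0.0)),
        BackgroundDesign("full", 30_000, None),
    ]


@dataclass
class RunConfig:
    """Everything one run needs, in one auditable place."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    truth: TruthParams = field(default_factory=TruthParams)
    predictor: PredictorConfig = field(default_factory=PredictorConfig)
    maxent: MaxentConfig = field(default_factory=MaxentConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    null_test: NullTestConfig = field(default_factory=NullTestConfig)
    background_designs: list[BackgroundDesign] = field(default_factory=_default_designs)
    n_occurrences: int = 2000
    dup_rate: float = 0.15
    coarse_accuracy_rate: float = 0.25
    holdout_bounds: tuple[float, float, float, float] | None = (8_000.0, -24_000.0, 24_000.0, -8_000.0)
    seed: int = 0
    outdir: str = "run"

    @classmethod
    def desk(cls, seed: int = 0, outdir: str = "run", **overrides) -> "RunConfig":
        """Scaled-down profile for quick interactive runs and checks.

        Keeps the default 120x120 landscape and ground truth but uses
        smaller background samples, a lighter cross-validation design
        (k=5, 2 repeats), fewer hinge knots, and 1000 null groups.
        """
        cfg = cls(
            maxent=MaxentConfig(knots_per_variable=10),
            evaluation=EvalConfig(k=5, repeats=2, importance_permutations=5),
            null_test=NullTestConfig(n_groups=1000),
            background_designs=[
                BackgroundDesign("restricted", 2000, (0.0, -120_000.0, 84_000.0, 0.0)),
                BackgroundDesign("full", 4000, None),
            ],
            n_occurrences=1200,
            seed=seed,
            outdir=outdir,
        )
        return replace(cfg, **overrides) if overrides else cfg

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {
            "landscape": LandscapeConfig,
            "truth": TruthParams,
            "predictor": PredictorConfig,
            "maxent": MaxentConfig,
            "evaluation": EvalConfig,
            "null_test": NullTestConfig,
        }
        kwargs: dict = {}
        for key, typ in sub.items():
            if key in d:
                val = d.pop(key)
                if isinstance(val, dict):
                    val = _coerce_dataclass(typ, val)
                kwargs[key] = val
        if "background_designs" in d:
            kwargs["background_designs"] = [
                BackgroundDesign(
                    b["name"], int(b["n"]),
                    tuple(b["bounds"]) if b.get("bounds") is not None else None,
                )
                if isinstance(b, dict) else b
                for b in d.pop("background_designs")
            ]
        if d.get("holdout_bounds") is not None:
            d["holdout_bounds"] = tuple(d["holdout_bounds"])
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=False))


def _coerce_dataclass(typ, d: dict):
    fields_ = {f for f in typ.__dataclass_fields__}
    unknown = set(d) - fields_
    if unknown:
        raise ValueError(f"unknown keys for {typ.__name__}: {sorted(unknown)}")
    converted = {}
    for k, v in d.items():
        converted[k] = tuple(v) if isinstance(v, list) else v
    return typ(**converted)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _design_mask(design: BackgroundDesign, template: Grid) -> RegionMask:
    if design.bounds is None:
        xmin = template.origin[0]
        ymax = template.origin[1]
        xmax = xmin + template.shape[1] * template.cell_size
        ymin = ymax - template.shape[0] * template.cell_size
        return RegionMask.from_bounds(xmin, ymin, xmax, ymax)
    return RegionMask.from_bounds(*design.bounds)


def extract_table(stack: GridStack, xy: np.ndarray, names: list[str] | None = None) -> pd.DataFrame:
    """Predictor values at points; drops points on nodata or off-grid."""
    names = names or stack.names
    xy = np.asarray(xy, dtype=float)
    template = stack.template
    rows, cols = template.cell_index(xy[:, 0], xy[:, 1])
    nr, nc = template.shape
    ok = (rows >= 0) & (rows < nr) & (cols >= 0) & (cols < nc)
    combined = stack.combined_mask()
    ok[ok] &= ~combined[rows[ok], cols[ok]]
    values = stack.values_at(rows[ok], cols[ok], names)
    return pd.DataFrame(values, columns=names)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(config: RunConfig) -> dict:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("[simulate] generating landscape %sx%s", *config.landscape.shape)
    lcfg = replace(config.landscape, seed=stage_seed(config.seed, "landscape"))
    fine = generate_landscape(lcfg)
    stack = build_predictor_stack(fine, fine.coarse, config.predictor)
    write_predictor_stack(stack, out / "predictors")
    truth = true_suitability(stack, config.truth)
    write_grid(truth, out / "true_suitability.tif")
    occ = sample_occurrences(
        truth,
        config.n_occurrences,
        dup_rate=config.dup_rate,
        coarse_accuracy_rate=config.coarse_accuracy_rate,
        seed=stage_seed(config.seed, "occurrences"),
    )
    occ.to_csv(out / "occurrences.csv")
    return {"predictors": str(out / "predictors" / "predictors.json"),
            "true_suitability": str(out / "true_suitability.tif"),
            "occurrences": str(out / "occurrences.csv")}


def run_prepare(config: RunConfig) -> dict:
    out = Path(config.outdir)
    stack = GridStack.read(out / "predictors" / "predictors.json")
    template = stack.template
    occ = OccurrenceSet.from_csv(out / "occurrences.csv")
    filtered = filter_occurrences(occ)
    logger.info("[prepare] %d records -> %d after filtering", len(occ), len(filtered))
    if config.holdout_bounds is not None:
        region = RegionMask.from_bounds(*config.holdout_bounds)
        trainset, holdout = split_holdout(filtered, region)
    else:
        trainset, holdout = filtered, None
    trainset.to_csv(out / "train.csv")
    outputs = {"train": str(out / "train.csv")}
    if holdout is not None:
        holdout.to_csv(out / "holdout.csv")
        outputs["holdout"] = str(out / "holdout.csv")
    for design in config.background_designs:
        mask = _design_mask(design, template)
        pts = sample_background(
            mask, template, design.n, seed=stage_seed(config.seed, f"background:{design.name}")
        )
        path = out / f"background_{design.name}.csv"
        pd.DataFrame(pts, columns=["x", "y"]).to_csv(path, index=False)
        outputs[f"background_{design.name}"] = str(path)
    # collinearity screen over presences + first design's background
    first = config.background_designs[0]
    bg = pd.read_csv(out / f"background_{first.name}.csv").to_numpy()
    pts = np.vstack([trainset.xy, bg])
    src = spearman_matrix(stack, pts)
    src.to_csv(out / "spearman.csv")
    outputs["spearman"] = str(out / "spearman.csv")
    return outputs


def run_evaluate(config: RunConfig) -> dict:
    out = Path(config.outdir)
    stack = GridStack.read(out / "predictors" / "predictors.json")
    trainset = OccurrenceSet.from_csv(out / "train.csv")
    presence_table = extract_table(stack, trainset.xy, CANONICAL_ORDER)
    outputs: dict = {}
    eval_cfg = replace(config.evaluation, seed=stage_seed(config.seed, "evaluation"))
    for design in config.background_designs:
        bg_xy = pd.read_csv(out / f"background_{design.name}.csv").to_numpy()
        background_table = extract_table(stack, bg_xy, CANONICAL_ORDER)
        logger.info("[evaluate] design %s: %d presences, %d background",
                    design.name, len(presence_table), len(background_table))
        results, models = cross_validate(presence_table, background_table, config.maxent, eval_cfg)
        metrics = pd.DataFrame(
            [(r.repeat, r.fold, r.auc, r.tss, r.tss_threshold) for r in results],
            columns=["repeat", "fold", "auc", "tss", "threshold"],
        )
        metrics_path = out / f"metrics_{design.name}.csv"
        metrics.to_csv(metrics_path, index=False)
        outputs[f"metrics_{design.name}"] = str(metrics_path)

        ensemble = build_ensemble(models, results)
        mdir = out / "models" / design.name
        mdir.mkdir(parents=True, exist_ok=True)
        member_files = []
        for i, member in enumerate(ensemble.members):
            mp = mdir / f"member_{i}.json"
            member.to_json(mp)
            member_files.append(mp.name)
        manifest = {
            "members": member_files,
            "weights": ensemble.weights.tolist(),
            "aucs": ensemble.member_aucs.tolist(),
        }
        (mdir / "ensemble.json").write_text(json.dumps(manifest, indent=2))
        outputs[f"ensemble_{design.name}"] = str(mdir / "ensemble.json")

        # single full-data model: limiting-factor map + response curves
        full_model = train(presence_table, background_table, config.maxent)
        full_model.to_json(mdir / "full_model.json")
        outputs[f"full_model_{design.name}"] = str(mdir / "full_model.json")
        curves = []
        for var in full_model.variables:
            xs, ps = response_curve(full_model, var, n_steps=100)
            curves.append(pd.DataFrame({"variable": var, "x": xs, "p": ps}))
        cpath = out / f"response_curves_{design.name}.csv"
        pd.concat(curves, ignore_index=True).to_csv(cpath, index=False)
        outputs[f"response_curves_{design.name}"] = str(cpath)

        importance = variable_importance(ensemble, presence_table, background_table, eval_cfg)
        ipath = out / f"importance_{design.name}.csv"
        importance.to_csv(ipath, index=False)
        outputs[f"importance_{design.name}"] = str(ipath)
    return outputs


def _load_ensemble(mdir: Path) -> EnsembleModel:
    manifest = json.loads((mdir / "ensemble.json").read_text())
    members = [MaxentModel.from_json(mdir / f) for f in manifest["members"]]
    return EnsembleModel(members, np.asarray(manifest["weights"]), np.asarray(manifest["aucs"]))


def run_predict(config: RunConfig) -> dict:
    out = Path(config.outdir)
    stack = GridStack.read(out / "predictors" / "predictors.json")
    outputs: dict = {}
    maps = {}
    for design in config.background_designs:
        ensemble = _load_ensemble(out / "models" / design.name)
        suit = ensemble_predict(ensemble, stack)
        path = out / f"suitability_{design.name}.tif"
        write_grid(suit, path)
        maps[design.name] = suit
        outputs[f"suitability_{design.name}"] = str(path)
    if len(config.background_designs) >= 2:
        a = maps[config.background_designs[0].name]
        b = maps[config.background_designs[1].name]
        diff = grid_difference(a, b)
        dpath = out / "suitability_difference.tif"
        write_grid(diff, dpath)
        outputs["suitability_difference"] = str(dpath)
    return outputs


def run_limiting(config: RunConfig) -> dict:
    out = Path(config.outdir)
    stack = GridStack.read(out / "predictors" / "predictors.json")
    outputs: dict = {}
    for design in config.background_designs:
        model = MaxentModel.from_json(out / "models" / design.name / "full_model.json")
        lim = limiting_factor(model, stack)
        path = out / f"limiting_{design.name}.tif"
        write_grid(lim, path)
        outputs[f"limiting_{design.name}"] = str(path)
    return outputs


def run_validate(config: RunConfig) -> dict:
    out = Path(config.outdir)
    outputs: dict = {}
    holdout_path = out / "holdout.csv"
    if config.holdout_bounds is None or not holdout_path.exists():
        return {"skipped": "no hold-out region configured"}
    holdout = OccurrenceSet.from_csv(holdout_path)
    if len(holdout) == 0:
        return {"skipped": "hold-out region contains no occurrences"}
    ncfg = replace(config.null_test, seed=stage_seed(config.seed, "validation"))
    for design in config.background_designs:
        suit = read_grid(out / f"suitability_{design.name}.tif")
        mask = _design_mask(design, suit)
        result = null_group_test(suit, mask, holdout.xy, ncfg)
        report = summarize_validation(result)
        path = out / f"validation_{design.name}.json"
        path.write_text(json.dumps({"result": result.to_dict(), "report": report}, indent=2))
        outputs[f"validation_{design.name}"] = str(path)
    return outputs


_STAGES = [
    ("simulate", run_simulate),
    ("prepare", run_prepare),
    ("evaluate", run_evaluate),
    ("predict", run_predict),
    ("limiting", run_limiting),
    ("validate", run_validate),
]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Run all (or selected) stages and write the run manifest.

    The manifest records the full config, the derived per-stage seeds,
    every output path with its SHA-256 digest, and explicit entries for
    skipped stages.  Any stage failure aborts with the stage name and
    cause.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _jsonable(config.to_dict()),
        "stage_seeds": {name: stage_seed(config.seed, name) for name in
                        ["landscape", "occurrences", "evaluation", "validation"]},
        "stages": {},
        "outputs": {},
    }
    selected = stages or [name for name, _ in _STAGES]
    for name, fn in _STAGES:
        if name not in selected:
            continue
        logger.info("[%s] starting", name)
        try:
            result = fn(config)
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        if "skipped" in result:
            manifest["stages"][name] = {"status": "skipped", "reason": result["skipped"]}
        else:
            manifest["stages"][name] = {"status": "ok"}
            manifest["outputs"].update(result)
    for key, path in manifest["outputs"].items():
        manifest["outputs"][key] = {"path": path, "sha256": _sha256(Path(path))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def make_report(manifest_path: str | Path) -> Path:
    """Render figures and the validation table from a completed run.

    Produces importance bars and response curves per design, the
    suitability / difference / limiting maps, and a validation summary,
    reading stored outputs only.  Idempotent.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    outputs = manifest["outputs"]
    out = manifest_path.parent
    rdir = out / "report"
    rdir.mkdir(exist_ok=True)
    missing = [k for k, v in outputs.items() if not Path(v["path"]).exists()]
    if missing:
        raise FileNotFoundError(f"missing run outputs: {missing}")
    designs = [d["name"] for d in manifest["config"]["background_designs"]]

    for design in designs:
        imp = pd.read_csv(outputs[f"importance_{design}"]["path"])
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.barh(imp["variable"], imp["importance"], color="#31688e")
        ax.set_xlabel("permutation importance")
        ax.set_title(f"predictor importance ({design} background)")
        fig.tight_layout()
        fig.savefig(rdir / f"importance_{design}.png", dpi=120)
        plt.close(fig)

        curves = pd.read_csv(outputs[f"response_curves_{design}"]["path"])
        variables = curves["variable"].unique()
        fig, axes = plt.subplots(2, 3, figsize=(10, 5))
        for ax, var in zip(axes.ravel(), variables):
            sub = curves[curves["variable"] == var]
            ax.plot(sub["x"], sub["p"], color="#35b779")
            ax.set_title(var, fontsize=9)
            ax.set_ylim(0, 1)
        fig.suptitle(f"response curves ({design} background)")
        fig.tight_layout()
        fig.savefig(rdir / f"response_curves_{design}.png", dpi=120)
        plt.close(fig)

    n_maps = len(designs) + (2 if "suitability_difference" in outputs else 1)
    fig, axes = plt.subplots(1, n_maps + 1, figsize=(4 * (n_maps + 1), 4))
    axes = np.atleast_1d(axes)
    col = 0
    for design in designs:
        g = read_grid(outputs[f"suitability_{design}"]["path"])
        im = axes[col].imshow(np.ma.MaskedArray(g.values, g.nodata_mask), vmin=0, vmax=1)
        axes[col].set_title(f"suitability ({design})", fontsize=9)
        fig.colorbar(im, ax=axes[col], shrink=0.7)
        col += 1
    if "suitability_difference" in outputs:
        g = read_grid(outputs["suitability_difference"]["path"])
        im = axes[col].imshow(np.ma.MaskedArray(g.values, g.nodata_mask), cmap="RdBu")
        axes[col].set_title("difference (a-b)", fontsize=9)
        fig.colorbar(im, ax=axes[col], shrink=0.7)
        col += 1
    g = read_grid(outputs[f"limiting_{designs[0]}"]["path"])
    im = axes[col].imshow(np.ma.MaskedArray(g.values, g.nodata_mask), cmap="tab10", vmin=0, vmax=9)
    axes[col].set_title("limiting factor", fontsize=9)
    fig.tight_layout()
    fig.savefig(rdir / "maps.png", dpi=120)
    plt.close(fig)

    lines = []
    for design in designs:
        key = f"validation_{design}"
        if key in outputs:
            payload = json.loads(Path(outputs[key]["path"]).read_text())
            lines.append(f"== {design} ==")
            lines.append(payload["report"]["text"])
    (rdir / "validation.txt").write_text("\n".join(lines) if lines else "validation skipped\n")
    return rdir
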