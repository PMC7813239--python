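"""Model evaluation, repeated k-fold cross-validation, and ensembling.

Discrimination is measured with AUC — the probability that a random
presence scores above a random background point, computed from ranks
(the Mann-Whitney estimate, ties counted half) — and with the true
skill statistic TSS = sensitivity + specificity - 1 maximized over
score thresholds, treating background points as absences.

Model selection follows the repeated k-fold design: presences and
background are independently partitioned into k folds, a model is fit
on each k-1 fold training split and scored on its held-out fold, and
the whole partition is redrawn ``repeats`` times.  The best fold-model
of each repeat (by held-out AUC) enters an ensemble whose weights are
proportional to skill above chance, (AUC - 0.5) clipped at zero.

Variable importance is permutation-based: the mean AUC drop when one
predictor's values are shuffled across the evaluation points, averaged
over several permutations and normalized to sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .maxent import MaxentConfig, MaxentModel, predict_stack, predict_table, train
from .raster import Grid, GridStack

__all__ = [
    "EvalConfig",
    "EvaluationResult",
    "EnsembleModel",
    "auc",
    "tss",
    "cross_validate",
    "build_ensemble",
    "ensemble_predict",
    "variable_importance",
]


@dataclass
class EvalConfig:
    k: int = 10
    repeats: int = 10
    seed: int = 0
    importance_permutations: int = 10

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class EvaluationResult:
    repeat: int
    fold: int
    auc: float
    tss: float
    tss_threshold: float


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("presence and background scores must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    rank_sum_p = ranks[: p.size].sum()
    return float((rank_sum_p - p.size * (p.size + 1) / 2) / (p.size * b.size))


def tss(presence_scores: np.ndarray, background_scores: np.ndarray) -> tuple[float, float]:
    """Maximum of sensitivity + specificity - 1 over all unique score thresholds.

    A point is predicted present when its score >= threshold; background
    points are treated as absences.  Returns (tss, threshold); threshold
    ties resolve to the smallest.
    """
    p = np.sort(np.asarray(presence_scores, dtype=float))
    b = np.sort(np.asarray(background_scores, dtype=float))
    if p.size == 0 or b.size == 0:
        raise ValueError("presence and background scores must be non-empty")
    thresholds = np.unique(np.concatenate([p, b]))
    sens = 1.0 - np.searchsorted(p, thresholds, side="left") / p.size
    spec = np.searchsorted(b, thresholds, side="left") / b.size
    scores = sens + spec - 1.0
    best = int(np.argmax(scores))  # first maximum -> smallest threshold
    return float(scores[best]), float(thresholds[best])


def _fold_ids(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random partition of range(n) into k near-equal folds."""
    ids = np.repeat(np.arange(k), -(-n // k))[:n]
    return ids[rng.permutation(n)]


def cross_validate(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    maxent_config: MaxentConfig,
    eval_config: EvalConfig,
) -> tuple[list[EvaluationResult], list[MaxentModel]]:
    """Repeated k-fold cross-validation of the maximum-entropy model.

    Presences and background are partitioned independently; each of the
    k x repeats fold-models is fit on the k-1 training folds of both
    sets and evaluated on the held-out folds.  Fold assignment derives
    deterministically from (seed, repeat).
    """
    m = len(presences)
    if m < eval_config.k:
        raise ValueError(f"need at least k={eval_config.k} presences, have {m}")
    results: list[EvaluationResult] = []
    models: list[MaxentModel] = []
    for rep in range(eval_config.repeats):
        rng = np.random.default_rng([eval_config.seed, rep])
        p_fold = _fold_ids(m, eval_config.k, rng)
        b_fold = _fold_ids(len(background), eval_config.k, rng)
        for fold in range(eval_config.k):
            p_train = presences[p_fold != fold]
            b_train = background[b_fold != fold]
            p_test = presences[p_fold == fold]
            b_test = background[b_fold == fold]
            model = train(p_train, b_train, maxent_config)
            sp = predict_table(model, p_test)
            sb = predict_table(model, b_test)
            a = auc(sp, sb)
            t, thr = tss(sp, sb)
            results.append(EvaluationResult(rep, fold, a, t, thr))
            models.append(model)
    return results, models


@dataclass
class EnsembleModel:
    """AUC-weighted ensemble of maximum-entropy models."""

    members: list[MaxentModel]
    weights: np.ndarray
    member_aucs: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.member_aucs = np.asarray(self.member_aucs, dtype=float)
        if len(self.members) != self.weights.size:
            raise ValueError("one weight per member required")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")

    @property
    def variables(self) -> list[str]:
        return self.members[0].variables

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        return sum(
            w * predict_table(mem, table) for w, mem in zip(self.weights, self.members)
        )


def build_ensemble(
    models: list[MaxentModel],
    results: list[EvaluationResult],
    rule: str = "best-per-repeat",
) -> EnsembleModel:
    """Select the best fold-model per repeat and weight by skill above chance.

    Weights are proportional to max(AUC - 0.5, 0), normalized; if every
    selected member has AUC <= 0.5 the ensemble falls back to uniform
    weights with a warning.
    """
    if not models:
        raise ValueError("no models to ensemble")
    if len(models) != len(results):
        raise ValueError("results must cover all models")
    if rule != "best-per-repeat":
        raise ValueError(f"unknown ensembling rule {rule!r}")
    best: dict[int, int] = {}
    for i, res in enumerate(results):
        j = best.get(res.repeat)
        if j is None or res.auc > results[j].auc:
            best[res.repeat] = i
    idx = [best[rep] for rep in sorted(best)]
    members = [models[i] for i in idx]
    aucs = np.array([results[i].auc for i in idx])
    raw = np.maximum(aucs - 0.5, 0.0)
    if raw.sum() <= 0:
        warnings.warn("all member AUCs <= 0.5; falling back to uniform weights", stacklevel=2)
        weights = np.full(len(members), 1.0 / len(members))
    else:
        weights = raw / raw.sum()
    return EnsembleModel(members, weights, aucs)


def ensemble_predict(ensemble: EnsembleModel, stack: GridStack) -> Grid:
    """Weighted mean of the members' logistic suitability maps."""
    out: Grid | None = None
    for w, member in zip(ensemble.weights, ensemble.members):
        pred = predict_stack(member, stack)
        if out is None:
            out = pred.like(w * pred.values, pred.nodata_mask.copy())
        else:
            out.values += w * pred.values
            out.nodata_mask |= pred.nodata_mask
    assert out is not None
    out.values[out.nodata_mask] = 0.0
    return out


def variable_importance(
    ensemble: EnsembleModel,
    presences: pd.DataFrame,
    background: pd.DataFrame,
    eval_config: EvalConfig,
) -> pd.DataFrame:
    """Permutation importance: mean AUC drop per shuffled predictor.

    Each variable's values are permuted jointly across all evaluation
    points (presences + background) ``importance_permutations`` times;
    the mean AUC drop, clipped at zero, is normalized to sum to 1.
    Returns a DataFrame sorted descending with columns
    ``variable, auc_drop, importance, rank``.
    """
    variables = ensemble.variables
    combined = pd.concat([presences, background], ignore_index=True)[variables]
    n_p = len(presences)
    scores = ensemble.predict_table(combined)
    base = auc(scores[:n_p], scores[n_p:])
    rng = np.random.default_rng(eval_config.seed)
    drops = np.zeros(len(variables))
    for i, var in enumerate(variables):
        acc = 0.0
        for _ in range(eval_config.importance_permutations):
            shuffled = combined.copy()
            shuffled[var] = rng.permutation(shuffled[var].to_numpy())
            s = ensemble.predict_table(shuffled)
            acc += base - auc(s[:n_p], s[n_p:])
        drops[i] = acc / eval_config.importance_permutations
    clipped = np.maximum(drops, 0.0)
    total = clipped.sum()
    importance = clipped / total if total > 0 else np.zeros_like(clipped)
    out = pd.DataFrame({"variable": variables, "auc_drop": drops, "importance": importance})
    out = out.sort_values("importance", ascending=False, kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
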