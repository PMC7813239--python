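import numpy as np
import pandas as pd
import pytest

from refugia.evaluation import (
    EnsembleModel,
    EvalConfig,
    auc,
    build_ensemble,
    cross_validate,
    ensemble_predict,
    tss,
    variable_importance,
)
from refugia.maxent import MaxentConfig, predict_table, train
from refugia.raster import Grid, GridStack


def brute_auc(p, b):
    wins = sum((pi > bi) + 0.5 * (pi == bi) for pi in p for bi in b)
    return wins / (len(p) * len(b))


def brute_tss(p, b):
    best, best_thr = -np.inf, None
    for thr in sorted(set(np.concatenate([p, b]))):
        sens = np.mean(np.asarray(p) >= thr)
        spec = np.mean(np.asarray(b) < thr)
        if sens + spec - 1 > best:
            best, best_thr = sens + spec - 1, thr
    return best, best_thr


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_pairwise_counting_example(self):
        assert auc([0.8, 0.3], [0.5, 0.2]) == 0.75

    def test_identical_sets_half(self):
        assert auc([0.3, 0.7], [0.3, 0.7]) == 0.5

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            p = rng.integers(0, 6, rng.integers(2, 10)) / 5
            b = rng.integers(0, 6, rng.integers(2, 10)) / 5
            assert auc(p, b) == pytest.approx(brute_auc(p, b))

    def test_complement_symmetry(self):
        rng = np.random.default_rng(1)
        p, b = rng.random(13), rng.random(17)
        assert auc(p, b) == pytest.approx(1 - auc(b, p))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        p, b = rng.random(10), rng.random(10)
        assert auc(np.exp(3 * p), np.exp(3 * b)) == pytest.approx(auc(p, b))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auc([], [0.5])


class TestTSS:
    def test_perfect_separation(self):
        t, thr = tss([0.9, 0.8], [0.1, 0.2])
        assert t == 1.0
        assert 0.2 < thr <= 0.8

    def test_identical_multisets_zero(self):
        t, _ = tss([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert t == pytest.approx(0.0)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            p = rng.integers(0, 8, rng.integers(2, 12)) / 7
            b = rng.integers(0, 8, rng.integers(2, 12)) / 7
            t, thr = tss(p, b)
            bt, bthr = brute_tss(p, b)
            assert t == pytest.approx(bt)
            assert thr == pytest.approx(bthr)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        p, b = rng.random(12), rng.random(12)
        assert tss(2 * p + 1, 2 * b + 1)[0] == pytest.approx(tss(p, b)[0])

    def test_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            t, _ = tss(rng.random(8), rng.random(8))
            assert -1 <= t <= 1


def separable_tables(seed=0, m=40, n=200):
    rng = np.random.default_rng(seed)
    p = pd.DataFrame({"x": rng.uniform(0.7, 1.0, m), "z": rng.normal(size=m)})
    b = pd.DataFrame({"x": rng.uniform(0.0, 0.55, n), "z": rng.normal(size=n)})
    return p, b


class TestCrossValidate:
    mcfg = MaxentConfig(knots_per_variable=6)

    def test_partition_property(self):
        p, b = separable_tables(1)
        ecfg = EvalConfig(k=4, repeats=2, seed=3)
        results, models = cross_validate(p, b, self.mcfg, ecfg)
        assert len(results) == 8 and len(models) == 8
        # every presence lands in exactly one test fold per repeat: fold
        # sizes sum to m and repeats are independently shuffled
        from refugia.evaluation import _fold_ids
        for rep in range(2):
            rng = np.random.default_rng([3, rep])
            ids = _fold_ids(len(p), 4, rng)
            assert len(ids) == len(p)
            assert set(ids) == {0, 1, 2, 3}

    def test_separable_toy_high_auc(self):
        p, b = separable_tables(2)
        results, _ = cross_validate(p, b, self.mcfg, EvalConfig(k=2, repeats=1, seed=0))
        assert np.mean([r.auc for r in results]) > 0.9

    def test_seeded_determinism(self):
        p, b = separable_tables(3)
        ecfg = EvalConfig(k=3, repeats=2, seed=9)
        r1, _ = cross_validate(p, b, self.mcfg, ecfg)
        r2, _ = cross_validate(p, b, self.mcfg, ecfg)
        assert [(r.auc, r.tss) for r in r1] == [(r.auc, r.tss) for r in r2]

    def test_too_few_presences_rejected(self):
        p, b = separable_tables(4, m=3)
        with pytest.raises(ValueError, match="k=10"):
            cross_validate(p, b, self.mcfg, EvalConfig(k=10, repeats=1))


class TestEnsemble:
    def _models(self, n=2, seed=0):
        p, b = separable_tables(seed)
        model = train(p, b, MaxentConfig(knots_per_variable=6))
        return [model] * n

    def _results(self, aucs):
        from refugia.evaluation import EvaluationResult
        return [EvaluationResult(rep, 0, a, 0.5, 0.5) for rep, a in enumerate(aucs)]

    def test_auc_weight_rule(self):
        models = self._models(2)
        ens = build_ensemble(models, self._results([0.9, 0.7]))
        assert np.allclose(ens.weights, [2 / 3, 1 / 3])

    def test_chance_member_gets_zero_weight(self):
        models = self._models(3)
        ens = build_ensemble(models, self._results([0.5, 0.8, 0.7]))
        assert ens.weights[0] == 0.0
        assert np.isclose(ens.weights.sum(), 1.0)

    def test_all_chance_falls_back_to_uniform(self):
        models = self._models(2)
        with pytest.warns(UserWarning, match="uniform"):
            ens = build_ensemble(models, self._results([0.5, 0.4]))
        assert np.allclose(ens.weights, 0.5)

    def test_best_per_repeat_selection(self):
        from refugia.evaluation import EvaluationResult
        models = self._models(4)
        results = [
            EvaluationResult(0, 0, 0.6, 0, 0), EvaluationResult(0, 1, 0.9, 0, 0),
            EvaluationResult(1, 0, 0.8, 0, 0), EvaluationResult(1, 1, 0.7, 0, 0),
        ]
        ens = build_ensemble(models, results)
        assert len(ens.members) == 2
        assert np.allclose(ens.member_aucs, [0.9, 0.8])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_ensemble([], [])

    def test_identical_members_equal_single(self):
        p, b = separable_tables(5)
        model = train(p, b, MaxentConfig(knots_per_variable=6))
        ens = build_ensemble([model, model], self._results([0.8, 0.8]))
        assert np.allclose(ens.predict_table(b), predict_table(model, b))


class TestEnsemblePredict:
    def test_weighted_mean_and_convexity(self, small_stack):
        import refugia.pipeline as pl
        rng = np.random.default_rng(7)
        template = small_stack.template
        rows = rng.integers(0, 30, 80)
        cols = rng.integers(0, 30, 80)
        xy = np.column_stack(template.cell_center(rows, cols))
        table = pl.extract_table(small_stack, xy)
        p = table.iloc[:30].reset_index(drop=True)
        b = table.iloc[30:].reset_index(drop=True)
        m1 = train(p, b, MaxentConfig(knots_per_variable=5))
        m2 = train(p, b, MaxentConfig(knots_per_variable=5, beta_multiplier=10.0))
        from refugia.maxent import predict_stack
        from refugia.evaluation import EnsembleModel
        ens = EnsembleModel([m1, m2], np.array([0.25, 0.75]), np.array([0.9, 0.8]))
        combined = ensemble_predict(ens, small_stack)
        g1, g2 = predict_stack(m1, small_stack), predict_stack(m2, small_stack)
        ok = ~combined.nodata_mask
        assert np.allclose(combined.values[ok], 0.25 * g1.values[ok] + 0.75 * g2.values[ok])
        lower = np.minimum(g1.values, g2.values)[ok]
        upper = np.maximum(g1.values, g2.values)[ok]
        assert np.all(combined.values[ok] >= lower - 1e-12)
        assert np.all(combined.values[ok] <= upper + 1e-12)

    def test_single_member_identity(self):
        p, b = separable_tables(6)
        model = train(p, b, MaxentConfig(knots_per_variable=6))
        stack = GridStack({
            "x": Grid(np.linspace(0, 1, 9).reshape(3, 3), None, 1000.0),
            "z": Grid(np.zeros((3, 3)), None, 1000.0),
        })
        from refugia.maxent import predict_stack
        ens = EnsembleModel([model], np.array([1.0]), np.array([0.9]))
        assert np.allclose(ensemble_predict(ens, stack).values, predict_stack(model, stack).values)


class TestVariableImportance:
    def test_driving_variable_dominates_noise(self):
        p, b = separable_tables(8, m=60, n=300)
        model = train(p, b, MaxentConfig(knots_per_variable=6))
        ens = EnsembleModel([model], np.array([1.0]), np.array([0.95]))
        imp = variable_importance(ens, p, b, EvalConfig(k=2, repeats=1, seed=0, importance_permutations=10))
        assert imp.iloc[0]["variable"] == "x"
        assert imp["importance"].sum() == pytest.approx(1.0)

    def test_single_variable_importance_one(self):
        rng = np.random.default_rng(9)
        p = pd.DataFrame({"x": rng.uniform(0.6, 1, 40)})
        b = pd.DataFrame({"x": rng.uniform(0, 1, 200)})
        model = train(p, b, MaxentConfig(knots_per_variable=6))
        ens = EnsembleModel([model], np.array([1.0]), np.array([0.9]))
        imp = variable_importance(ens, p, b, EvalConfig(importance_permutations=3))
        assert imp["importance"].iloc[0] == 1.0

    def test_pure_noise_variable_near_zero_drop(self):
        p, b = separable_tables(10, m=80, n=400)
        model = train(p, b, MaxentConfig(knots_per_variable=6))
        ens = EnsembleModel([model], np.array([1.0]), np.array([0.9]))
        imp = variable_importance(ens, p, b, EvalConfig(seed=1, importance_permutations=10))
        noise_drop = float(imp.loc[imp["variable"] == "z", "auc_drop"].iloc[0])
        assert abs(noise_drop) < 0.02
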