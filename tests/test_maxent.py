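import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from refugia.maxent import (
    FeatureSet,
    HingeFeature,
    MaxentConfig,
    MaxentModel,
    build_features,
    fit,
    limiting_factor,
    objective,
    penalties,
    predict_logistic,
    predict_raw,
    predict_table,
    response_curve,
    train,
)
from refugia.raster import Grid, GridStack


def toy_tables(seed=0, m=20, n=100):
    """Presences shifted high on variable x relative to background."""
    rng = np.random.default_rng(seed)
    return (
        pd.DataFrame({"x": rng.uniform(0.4, 1.0, m)}),
        pd.DataFrame({"x": rng.uniform(0.0, 1.0, n)}),
    )


def grid_search_1d(F_p, F_b, r, lo=-10, hi=10, tol=1e-6):
    """Refining dense grid search over a single coefficient."""
    for _ in range(40):
        grid = np.linspace(lo, hi, 41)
        vals = [objective(np.array([g]), F_p, F_b, r) for g in grid]
        i = int(np.argmin(vals))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, 40)]
        if hi - lo < tol:
            break
    return grid[i]


def grid_search_2d(F_p, F_b, r, span=8.0, tol=1e-5):
    center = np.zeros(2)
    width = span
    for _ in range(60):
        g1 = center[0] + np.linspace(-width, width, 21)
        g2 = center[1] + np.linspace(-width, width, 21)
        vals = np.array([[objective(np.array([a, b]), F_p, F_b, r) for b in g2] for a in g1])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        center = np.array([g1[i], g2[j]])
        width = width * 2 / 20 * 1.5
        if width < tol:
            break
    return center


class TestBuildFeatures:
    cfg = MaxentConfig(knots_per_variable=30)

    def test_constant_variable_contributes_nothing(self):
        p = pd.DataFrame({"c": np.ones(10), "x": np.arange(10.0)})
        b = pd.DataFrame({"c": np.ones(20), "x": np.arange(20.0)})
        fs = build_features(p, b, self.cfg)
        assert all(f.variable != "c" for f in fs.features)

    def test_forward_hinge_endpoints(self):
        f = HingeFeature("x", "forward", knot=2.0, vmin=0.0, vmax=10.0)
        assert f(np.array([2.0]))[0] == 0.0
        assert f(np.array([10.0]))[0] == 1.0
        assert f(np.array([-5.0]))[0] == 0.0  # clamped below
        assert f(np.array([50.0]))[0] == 1.0  # clamped above

    def test_reverse_hinge_endpoints(self):
        f = HingeFeature("x", "reverse", knot=2.0, vmin=0.0, vmax=10.0)
        assert f(np.array([2.0]))[0] == 0.0
        assert f(np.array([0.0]))[0] == 1.0

    def test_few_distinct_values_dedupe(self):
        vals = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        p = pd.DataFrame({"x": vals})
        b = pd.DataFrame({"x": np.repeat(vals, 4)})
        fs = build_features(p, b, self.cfg)
        # 30 requested knots collapse onto at most the 3 interior values
        assert len(fs.features) <= 10
        knots = {f.knot for f in fs.features}
        assert all(0.0 < t < 4.0 for t in knots)

    def test_feature_values_in_unit_interval(self):
        p, b = toy_tables(3)
        fs = build_features(p, b, self.cfg)
        F = fs.transform(pd.concat([p, b]))
        assert np.all((F >= 0) & (F <= 1))

    def test_empty_tables_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            build_features(pd.DataFrame({"x": []}), pd.DataFrame({"x": [1.0]}), self.cfg)


class TestFit:
    def test_zero_features_null_model(self):
        model = fit(np.zeros((5, 0)), np.zeros((50, 0)), MaxentConfig())
        raw = predict_raw(model, np.zeros((50, 0)))
        assert np.allclose(raw, 1 / 50)
        assert model.entropy == pytest.approx(np.log(50))
        assert np.allclose(predict_logistic(model, np.zeros((10, 0))), 0.3)

    def test_huge_beta_zeroes_all_coefficients(self):
        p, b = toy_tables(1)
        cfg = MaxentConfig(beta_multiplier=1e6, knots_per_variable=10)
        model = train(p, b, cfg)
        assert np.all(model.coefficients == 0)

    def test_single_hinge_matches_grid_search(self):
        rng = np.random.default_rng(2)
        xp = rng.uniform(0.5, 1.0, 20)
        xb = rng.uniform(0.0, 1.0, 100)
        feat = HingeFeature("x", "forward", 0.2, 0.0, 1.0)
        F_p = feat(xp)[:, None]
        F_b = feat(xb)[:, None]
        cfg = MaxentConfig()
        r = penalties(F_p, cfg)
        model = fit(F_p, F_b, cfg)
        oracle = grid_search_1d(F_p, F_b, r)
        assert model.coefficients[0] == pytest.approx(oracle, abs=1e-3)

    def test_two_hinges_match_grid_search(self):
        rng = np.random.default_rng(5)
        xp = rng.uniform(0.3, 1.0, 20)
        xb = rng.uniform(0.0, 1.0, 100)
        f1 = HingeFeature("x", "forward", 0.25, 0.0, 1.0)
        f2 = HingeFeature("x", "reverse", 0.75, 0.0, 1.0)
        F_p = np.column_stack([f1(xp), f2(xp)])
        F_b = np.column_stack([f1(xb), f2(xb)])
        cfg = MaxentConfig()
        r = penalties(F_p, cfg)
        model = fit(F_p, F_b, cfg)
        oracle = grid_search_2d(F_p, F_b, r)
        assert np.allclose(model.coefficients, oracle, atol=1e-3)

    def test_fit_no_worse_than_null(self):
        p, b = toy_tables(7)
        cfg = MaxentConfig(knots_per_variable=10)
        fs = build_features(p, b, cfg)
        F_p, F_b = fs.transform(p), fs.transform(b)
        r = penalties(F_p, cfg)
        model = fit(F_p, F_b, cfg, fs)
        assert objective(model.coefficients, F_p, F_b, r) <= objective(
            np.zeros(len(fs)), F_p, F_b, r
        )

    def test_minimum_objective_nondecreasing_in_beta(self):
        p, b = toy_tables(8)
        mins = []
        for beta in (0.5, 2.5, 10.0):
            cfg = MaxentConfig(beta_multiplier=beta, knots_per_variable=10)
            fs = build_features(p, b, cfg)
            F_p, F_b = fs.transform(p), fs.transform(b)
            model = fit(F_p, F_b, cfg, fs)
            mins.append(objective(model.coefficients, F_p, F_b, penalties(F_p, cfg)))
        assert mins[0] <= mins[1] + 1e-9 <= mins[2] + 2e-9

    def test_raw_normalizes_over_training_background(self):
        p, b = toy_tables(9)
        model = train(p, b, MaxentConfig(knots_per_variable=10))
        # training background includes the presence samples (Maxent default)
        F_train_bg = np.vstack([model.features.transform(b), model.features.transform(p)])
        raw = predict_raw(model, F_train_bg)
        assert abs(raw.sum() - 1.0) < 1e-10

    def test_predictor_scaling_invariance(self):
        p, b = toy_tables(10)
        cfg = MaxentConfig(knots_per_variable=10)
        m1 = train(p, b, cfg)
        m2 = train(p * 1000.0, b * 1000.0, cfg)
        assert np.allclose(m1.coefficients, m2.coefficients)
        assert np.allclose(predict_table(m1, p), predict_table(m2, p * 1000.0))

    def test_deterministic(self):
        p, b = toy_tables(11)
        cfg = MaxentConfig(knots_per_variable=10)
        assert np.array_equal(train(p, b, cfg).coefficients, train(p, b, cfg).coefficients)

    def test_too_few_presences_rejected(self):
        with pytest.raises(ValueError, match="presence"):
            fit(np.zeros((1, 2)), np.zeros((10, 2)), MaxentConfig())


class TestPredict:
    def toy_model(self, lam=0.5, entropy=None):
        fs = FeatureSet([HingeFeature("x", "forward", 0.0, 0.0, 1.0)], ["x"], {"x": (0.0, 1.0)})
        F_b = np.array([[0.0], [0.5], [1.0]])
        eta = F_b @ [lam]
        log_z = logsumexp(eta)
        q = np.exp(eta - log_z)
        H = -(q * (eta - log_z)).sum() if entropy is None else entropy
        return MaxentModel(fs, np.array([lam]), float(log_z), float(H), 0.3,
                           {"x": 0.5}, 3), F_b

    def test_raw_matches_direct_evaluation(self):
        model, F_b = self.toy_model()
        eta = F_b[:, 0] * 0.5
        expected = np.exp(eta) / np.exp(eta).sum()
        assert np.allclose(predict_raw(model, F_b), expected)

    def test_renormalize_sums_to_one_anywhere(self):
        model, _ = self.toy_model()
        pts = np.array([[0.1], [0.9], [0.4], [0.2]])
        assert predict_raw(model, pts, renormalize=True).sum() == pytest.approx(1.0)

    def test_logistic_formula_point(self):
        # tau = 0.3 and e^H * q = 2  ->  p = 0.6 / 1.3
        fs = FeatureSet([], [], {})
        model = MaxentModel(fs, np.zeros(0), log_z=0.0, entropy=np.log(2.0), tau=0.3)
        # with no features q = e^0 / e^0 = 1, e^H = 2
        p = predict_logistic(model, np.zeros((1, 0)))
        assert p[0] == pytest.approx(0.6 / 1.3)

    def test_logistic_tau_half_identity(self):
        fs = FeatureSet([], [], {})
        model = MaxentModel(fs, np.zeros(0), log_z=0.0, entropy=0.0, tau=0.5)
        assert predict_logistic(model, np.zeros((4, 0)))[0] == pytest.approx(0.5)

    def test_logistic_monotone_in_raw(self):
        model, _ = self.toy_model(lam=2.0)
        xs = np.linspace(0, 1, 20)[:, None]
        p = predict_logistic(model, xs)
        assert np.all(np.diff(p) > 0)
        assert np.all((p > 0) & (p < 1))

    def test_serialization_round_trip(self, tmp_path):
        p, b = toy_tables(12)
        model = train(p, b, MaxentConfig(knots_per_variable=10))
        model.to_json(tmp_path / "m.json")
        loaded = MaxentModel.from_json(tmp_path / "m.json")
        assert np.array_equal(loaded.coefficients, model.coefficients)
        assert np.array_equal(predict_table(loaded, b), predict_table(model, b))


class TestResponseCurve:
    def test_inactive_variable_flat(self):
        rng = np.random.default_rng(13)
        p = pd.DataFrame({"x": rng.uniform(0.5, 1, 30), "noise": rng.normal(size=30)})
        b = pd.DataFrame({"x": rng.uniform(0, 1, 200), "noise": rng.normal(size=200)})
        model = train(p, b, MaxentConfig(knots_per_variable=8))
        active = {f.variable for f, lam in zip(model.features.features, model.coefficients) if lam}
        if "noise" not in active:
            _, ps = response_curve(model, "noise")
            assert np.allclose(ps, ps[0])

    def test_single_positive_hinge_nondecreasing(self):
        fs = FeatureSet([HingeFeature("x", "forward", 0.3, 0.0, 1.0)], ["x"], {"x": (0.0, 1.0)})
        model = MaxentModel(fs, np.array([1.5]), 0.0, 0.0, 0.3, {"x": 0.5}, 10)
        _, ps = response_curve(model, "x", n_steps=50)
        assert np.all(np.diff(ps) >= 0)

    def test_unknown_variable_rejected(self):
        fs = FeatureSet([], ["x"], {"x": (0.0, 1.0)})
        model = MaxentModel(fs, np.zeros(0), 0.0, 0.0, 0.3, {"x": 0.5})
        with pytest.raises(KeyError):
            response_curve(model, "zzz")


class TestLimitingFactor:
    def two_var_setup(self):
        rng = np.random.default_rng(14)
        p = pd.DataFrame({"a": rng.uniform(0.6, 1, 30), "b": rng.uniform(0.4, 0.6, 30)})
        bg = pd.DataFrame({"a": rng.uniform(0, 1, 150), "b": rng.uniform(0, 1, 150)})
        model = train(p, bg, MaxentConfig(knots_per_variable=6))
        stack = GridStack({
            "a": Grid(np.array([[0.05, 0.9], [0.5, 0.1]]), None, 1000.0),
            "b": Grid(np.array([[0.5, 0.05], [0.9, 0.95]]), None, 1000.0),
        })
        return model, stack

    def test_matches_brute_force_enumeration(self):
        model, stack = self.two_var_setup()
        lim = limiting_factor(model, stack)
        for r in range(2):
            for c in range(2):
                table = pd.DataFrame({"a": [stack["a"].values[r, c]],
                                      "b": [stack["b"].values[r, c]]})
                actual = predict_table(model, table)[0]
                deltas = []
                for v in ["a", "b"]:
                    repl = table.copy()
                    repl[v] = model.presence_means[v]
                    deltas.append(predict_table(model, repl)[0] - actual)
                assert lim.values[r, c] == int(np.argmax(deltas))

    def test_single_variable_model_always_limited_by_it(self):
        p, b = toy_tables(15)
        model = train(p, b, MaxentConfig(knots_per_variable=6))
        stack = GridStack({"x": Grid(np.array([[0.0, 0.5], [0.9, 0.2]]), None, 1000.0)})
        lim = limiting_factor(model, stack)
        assert np.all(lim.values == 0)

    def test_presence_mean_cell_ties_to_first_variable(self):
        model, stack = self.two_var_setup()
        mstack = GridStack({
            "a": Grid(np.array([[model.presence_means["a"]]]), None, 1000.0),
            "b": Grid(np.array([[model.presence_means["b"]]]), None, 1000.0),
        })
        lim = limiting_factor(model, mstack)
        assert lim.values[0, 0] == 0

    def test_missing_layer_rejected(self):
        model, _ = self.two_var_setup()
        with pytest.raises(KeyError, match="'b'"):
            limiting_factor(model, GridStack({"a": Grid(np.zeros((2, 2)), None, 1000.0)}))
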