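import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from streamhab.maxent_engine import (
    MaxentModel,
    aicc,
    crossvalidate,
    fit,
    make_features,
    predict,
    predict_rows,
    sample_background,
    select_model,
)
from streamhab.maxent_engine.features import Feature, FeatureSet


def frame(**cols):
    return pd.DataFrame(cols)


def _classes(model):
    from streamhab.maxent_engine.selection import _classes_of

    return _classes_of(model)


class TestMakeFeatures:
    def test_hinge_below_knot_is_zero(self):
        fs = FeatureSet(
            [Feature("hinge_fwd", "v", knot=5.0)], {"v": (0.0, 10.0)},
            np.array([0.5]), {},
        )
        assert fs.transform(frame(v=[3.0]))[0, 0] == 0.0

    def test_forward_hinge_scaling(self):
        fs = FeatureSet(
            [Feature("hinge_fwd", "v", knot=5.0)], {"v": (0.0, 10.0)},
            np.array([0.5]), {},
        )
        assert fs.transform(frame(v=[7.5]))[0, 0] == pytest.approx(0.5)

    def test_lqp_feature_count_two_variables(self):
        vals = frame(a=np.linspace(0, 1, 30), b=np.linspace(3, 9, 30))
        fs = make_features(vals, n_presence=10, classes="LQP", categorical_vars=())
        assert len(fs) == 5  # 2 linear + 2 quadratic + 1 product

    def test_constant_variable_dropped(self):
        vals = frame(a=np.linspace(0, 1, 30), b=np.full(30, 2.0))
        fs = make_features(vals, n_presence=10, classes="L", categorical_vars=())
        assert fs.variables == ["a"]

    def test_categorical_indicators_per_level(self):
        vals = frame(a=np.linspace(0, 1, 30), landform=np.repeat([1, 6, 9], 10))
        fs = make_features(vals, n_presence=10, classes="L")
        labels = fs.labels
        assert sum("landform" in lab for lab in labels) == 3

    def test_all_features_in_unit_interval(self):
        rng = np.random.default_rng(0)
        vals = frame(a=rng.random(100) * 40 - 7, b=rng.random(100) * 3,
                     landform=rng.integers(1, 11, 100))
        fs = make_features(vals, n_presence=20, classes="LQHP", n_hinge=5)
        X = fs.transform(vals)
        assert X.min() >= 0.0 and X.max() <= 1.0

    def test_invalid_classes_rejected(self):
        with pytest.raises(ValueError):
            make_features(frame(a=[1.0, 2.0]), n_presence=2, classes="LT")

    def test_serialization_round_trip(self):
        vals = frame(a=np.linspace(0, 5, 30), landform=np.repeat([1, 9], 15))
        fs = make_features(vals, n_presence=10, classes="LQH", n_hinge=3)
        back = FeatureSet.from_dict(fs.to_dict())
        assert np.array_equal(back.transform(vals), fs.transform(vals))


def _objective(lam, X_pres, X_bg, betas, rm):
    """Independent re-statement of the fit objective (test-side oracle)."""
    return (
        -float(X_pres.mean(axis=0) @ lam)
        + float(logsumexp(X_bg @ lam))
        + float(rm * betas @ np.abs(lam))
    )


def _coordinate_descent_oracle(X_pres, X_bg, betas, rm, n_sweeps=400):
    """Exact 1-D line search per coordinate on the convex objective."""
    lam = np.zeros(X_pres.shape[1])
    for _ in range(n_sweeps):
        moved = 0.0
        for j in range(len(lam)):
            def f(t):
                trial = lam.copy()
                trial[j] = t
                return _objective(trial, X_pres, X_bg, betas, rm)

            res = minimize_scalar(f, bracket=(lam[j] - 1.0, lam[j] + 1.0))
            moved = max(moved, abs(res.x - lam[j]))
            lam[j] = res.x
        if moved < 1e-10:
            break
    return lam


class TestFit:
    @pytest.fixture
    def toy(self):
        rng = np.random.default_rng(1)
        back = frame(a=rng.random(200), b=rng.random(200))
        pres = frame(a=rng.random(20) * 0.3 + 0.7, b=rng.random(20))
        fs = make_features(
            pd.concat([pres, back], ignore_index=True),
            n_presence=20, classes="LQ", categorical_vars=(),
        )
        return fs, pres, back

    def test_zero_coefficients_give_uniform_raw(self, toy):
        fs, pres, back = toy
        model = MaxentModel(
            features=fs, lam=np.zeros(len(fs)), rm=1.0,
            log_z=float(np.log(len(back))), entropy=float(np.log(len(back))),
            n_presence=len(pres),
        )
        raw = model.raw(back)
        assert np.allclose(raw, 1.0 / len(back))

    def test_concentrated_presences_positive_linear_coefficient(self):
        rng = np.random.default_rng(21)
        back = frame(a=rng.random(200))
        pres = frame(a=rng.random(20) * 0.3 + 0.7)
        fs = make_features(
            pd.concat([pres, back], ignore_index=True),
            n_presence=20, classes="L", categorical_vars=(),
        )
        model = fit(fs, pres, back)
        assert model.lam[fs.labels.index("a")] > 0

    def test_raw_sums_to_one_over_background(self, toy):
        fs, pres, back = toy
        model = fit(fs, pres, back)
        assert model.raw(back).sum() == pytest.approx(1.0, rel=1e-9)

    def test_matches_coordinate_descent_oracle(self):
        rng = np.random.default_rng(2)
        back = frame(a=rng.random(60), b=rng.random(60))
        pres = frame(a=rng.random(20) * 0.4 + 0.6, b=rng.random(20) * 0.5)
        fs = make_features(
            pd.concat([pres, back], ignore_index=True),
            n_presence=20, classes="L", categorical_vars=(),
        )
        model = fit(fs, pres, back)
        X_pres = fs.transform(pres)
        X_bg = fs.transform(back)
        oracle = _coordinate_descent_oracle(X_pres, X_bg, fs.betas, 1.0)
        assert np.allclose(model.lam, oracle, atol=1e-3)

    def test_objective_not_worse_than_oracle(self):
        rng = np.random.default_rng(3)
        back = frame(a=rng.random(80), b=rng.random(80), c=rng.random(80))
        pres = frame(a=rng.random(25) ** 2, b=rng.random(25) * 0.4 + 0.6,
                     c=rng.random(25))
        fs = make_features(
            pd.concat([pres, back], ignore_index=True),
            n_presence=25, classes="LQ", categorical_vars=(),
        )
        model = fit(fs, pres, back)
        X_pres, X_bg = fs.transform(pres), fs.transform(back)
        oracle = _coordinate_descent_oracle(X_pres, X_bg, fs.betas, 1.0)
        ours = _objective(model.lam, X_pres, X_bg, fs.betas, 1.0)
        theirs = _objective(oracle, X_pres, X_bg, fs.betas, 1.0)
        assert ours <= theirs + 1e-6

    def test_strong_regularization_zeroes_coefficients(self, toy):
        fs, pres, back = toy
        model = fit(fs, pres, back, rm=1e4)
        assert np.all(model.lam == 0.0)
        assert np.allclose(model.raw(back), 1.0 / len(back))

    def test_too_few_presences_rejected(self, toy):
        fs, pres, back = toy
        with pytest.raises(ValueError):
            fit(fs, pres.iloc[:1], back)

    def test_model_json_round_trip(self, toy, tmp_path):
        fs, pres, back = toy
        model = fit(fs, pres, back)
        model.to_json(tmp_path / "m.json")
        back_model = MaxentModel.from_json(tmp_path / "m.json")
        assert np.allclose(back_model.cloglog(back), model.cloglog(back))


class TestPredict:
    def test_uniform_raw_cloglog(self):
        fs = FeatureSet([Feature("linear", "v")], {"v": (0.0, 1.0)}, np.array([1.0]), {})
        n = 50
        model = MaxentModel(
            features=fs, lam=np.zeros(1), rm=1.0,
            log_z=float(np.log(n)), entropy=float(np.log(n)), n_presence=10,
        )
        vals = frame(v=np.linspace(0, 1, n))
        out = predict_rows(model, vals, output="cloglog")
        assert np.allclose(out, 1 - np.exp(-1))

    def test_cloglog_monotone_in_raw(self):
        rng = np.random.default_rng(4)
        back = frame(v=rng.random(100))
        pres = frame(v=rng.random(30) * 0.3 + 0.7)
        fs = make_features(pd.concat([pres, back], ignore_index=True),
                           n_presence=30, classes="L", categorical_vars=())
        model = fit(fs, pres, back)
        raw = model.raw(back)
        clog = model.cloglog(back)
        order = np.argsort(raw)
        assert np.all(np.diff(clog[order]) >= -1e-12)


class TestAicc:
    def _model_with_k(self, k, n_features=6):
        fs = FeatureSet(
            [Feature("linear", f"v{i}") for i in range(n_features)],
            {f"v{i}": (0.0, 1.0) for i in range(n_features)},
            np.ones(n_features), {},
        )
        lam = np.zeros(n_features)
        lam[:k] = 0.5
        return MaxentModel(features=fs, lam=lam, rm=1.0, log_z=0.0,
                           entropy=1.0, n_presence=0)

    def test_formula_arithmetic(self):
        # k=3, n=132, logL=-500 -> AICc = 1006.1875
        k, n, logl = 3, 132, -500.0
        val = 2 * k - 2 * logl + 2 * k * (k + 1) / (n - k - 1)
        assert val == pytest.approx(1006.1875)

    def test_zero_coefficient_features_do_not_count(self):
        rng = np.random.default_rng(5)
        vals = frame(**{f"v{i}": rng.random(132) for i in range(6)})
        m3 = self._model_with_k(3)
        rec = aicc(m3, vals, vals)
        assert rec.k == 3
        m3b = self._model_with_k(3, n_features=8)
        vals8 = frame(**{f"v{i}": rng.random(132) for i in range(8)})
        rec_b = aicc(m3b, vals8, vals8)
        assert rec_b.k == 3  # extra zero features change nothing

    def test_undefined_when_n_too_small(self):
        rng = np.random.default_rng(6)
        m = self._model_with_k(3)
        vals = frame(**{f"v{i}": rng.random(4) for i in range(6)})
        rec = aicc(m, vals, vals)  # n = 4 = k + 1
        assert rec.aicc is None


class TestSelectModel:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(7)
        back = frame(a=rng.random(150))
        pres = frame(a=rng.random(40) * 0.3 + 0.7)
        model, records = select_model(
            pres, back, rms=(1.0,), class_sets=("L",), categorical_vars=()
        )
        assert len(records) == 1
        assert model.rm == 1.0

    def test_lq_beats_l_on_quadratic_structure(self):
        rng = np.random.default_rng(8)
        back = frame(a=rng.random(1500))
        # presences concentrated at an interior optimum: no linear signal at
        # all, so only the quadratic feature can capture the peak
        pres = frame(a=np.clip(rng.normal(0.5, 0.15, 150), 0, 1))
        model, records = select_model(
            pres, back, rms=(0.1,), class_sets=("L", "LQ"), categorical_vars=()
        )
        by_classes = {r.classes: r.aicc for r in records}
        assert by_classes["LQ"] < by_classes["L"]
        assert _classes(model) == "LQ"

    def test_all_undefined_rejected(self):
        rng = np.random.default_rng(9)
        back = frame(a=rng.random(100), b=rng.random(100), c=rng.random(100))
        pres = frame(a=rng.random(3) * 0.2 + 0.8, b=rng.random(3), c=rng.random(3))
        with pytest.raises(ValueError):
            select_model(pres, back, rms=(0.01,), class_sets=("LQP",),
                         categorical_vars=())


class TestCrossvalidate:
    def test_fold_sizes(self):
        rng = np.random.default_rng(10)
        back = frame(a=rng.random(100))
        pres = frame(a=rng.random(10) * 0.3 + 0.7)
        cv = crossvalidate("L", pres, back, k=2, seed=0, categorical_vars=())
        counts = np.bincount(cv.fold_of_presence)
        assert list(counts) == [5, 5]

    def test_each_presence_tested_once(self):
        rng = np.random.default_rng(11)
        back = frame(a=rng.random(100))
        pres = frame(a=rng.random(12) * 0.4 + 0.6)
        cv = crossvalidate("L", pres, back, k=3, seed=1, categorical_vars=())
        assert len(cv.fold_of_presence) == 12
        assert set(cv.fold_of_presence) == {0, 1, 2}
        assert np.all(np.isfinite(cv.test_scores))

    def test_k_exceeding_presences_rejected(self):
        back = frame(a=np.linspace(0, 1, 50))
        pres = frame(a=np.linspace(0.5, 1, 5))
        with pytest.raises(ValueError):
            crossvalidate("L", pres, back, k=10, categorical_vars=())

    def test_mean_map_is_arithmetic_mean_of_folds(self, grid_factory):
        from streamhab.covariate_builder import LAYER_NAMES, CovariateStack

        rng = np.random.default_rng(12)
        layers = {}
        for name in LAYER_NAMES:
            if name == "landform":
                layers[name] = grid_factory(np.ones((1, 3), dtype=int),
                                            kind="categorical")
            else:
                layers[name] = grid_factory(rng.random((1, 3)))
        stack = CovariateStack(layers)
        back = stack.sample(np.zeros(3, dtype=int), np.arange(3))
        back = pd.concat([back] * 20, ignore_index=True)
        pres = back.iloc[:6].copy()
        cv = crossvalidate("L", pres, back, k=2, seed=3)
        mean_map = cv.mean_map(stack)
        from streamhab.maxent_engine import predict as predict_grid

        manual = np.mean(
            [predict_grid(m, stack).values for m in cv.models], axis=0
        )
        assert np.allclose(mean_map.values, manual)


class TestSampleBackground:
    def _landform(self, grid_factory, n=60, eligible_frac=1.0):
        vals = np.full((n, n), 9)
        return grid_factory(vals, kind="categorical")

    def test_uniform_when_tau_infinite(self, grid_factory):
        lf = self._landform(grid_factory)
        dist = grid_factory(np.random.default_rng(0).random((60, 60)) * 1e4)
        rows, cols = sample_background(lf, dist, n=1200, tau=None, seed=1)
        # chi-square uniformity over 6 column bands
        counts = np.histogram(cols, bins=6, range=(0, 60))[0]
        expected = 1200 / 6
        chi2 = ((counts - expected) ** 2 / expected).sum()
        from scipy.stats import chi2 as chi2_dist

        assert chi2 < chi2_dist.ppf(0.99, df=5)

    def test_all_on_roads_equal_weights(self, grid_factory):
        lf = self._landform(grid_factory)
        dist = grid_factory(np.zeros((60, 60)))
        rows, cols = sample_background(lf, dist, n=600, tau=200.0, seed=2)
        assert len(rows) == 600
        assert len(set(zip(rows.tolist(), cols.tolist()))) == 600  # no repeats

    def test_near_road_cells_oversampled_by_weight_ratio(self, grid_factory):
        n = 100
        lf = self._landform(grid_factory, n=n)
        dvals = np.zeros((n, n))
        dvals[:, n // 2:] = 600.0  # far half
        dist = grid_factory(dvals)
        rows, cols = sample_background(lf, dist, n=500, tau=200.0, seed=3)
        near = (cols < n // 2).sum()
        # weight ratio e^3 ~ 20: expected near fraction ~ 20/21 = 0.952
        p = np.exp(3) / (1 + np.exp(3))
        se = np.sqrt(p * (1 - p) / 500)
        assert abs(near / 500 - p) < 4 * se + 0.01

    def test_fewer_eligible_than_n_warns_and_returns_all(self, grid_factory):
        vals = np.full((10, 10), 1)
        vals[0, :5] = 9
        lf = grid_factory(vals, kind="categorical")
        dist = grid_factory(np.zeros((10, 10)))
        with pytest.warns(UserWarning):
            rows, cols = sample_background(lf, dist, n=100, seed=4)
        assert len(rows) == 5

    def test_no_eligible_cells_rejected(self, grid_factory):
        lf = grid_factory(np.full((5, 5), 1), kind="categorical")
        dist = grid_factory(np.zeros((5, 5)))
        with pytest.raises(ValueError):
            sample_background(lf, dist, n=10, seed=5)


class TestRegularizationPath:
    def test_increasing_rm_shrinks_toward_uniform(self):
        rng = np.random.default_rng(13)
        back = frame(a=rng.random(200))
        pres = frame(a=rng.random(40) * 0.25 + 0.75)
        fs = make_features(pd.concat([pres, back], ignore_index=True),
                           n_presence=40, classes="L", categorical_vars=())
        norms = []
        for rm in (0.5, 2.0, 10.0, 1000.0):
            model = fit(fs, pres, back, rm=rm)
            norms.append(np.abs(model.lam).sum())
        assert norms == sorted(norms, reverse=True)
        assert norms[-1] == 0.0
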