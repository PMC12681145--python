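import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import spearmanr

from habshift.brt import (BRTConfig, bernoulli_deviance, contributions,
                          fit_with_cv, interactions, predict_map,
                          response_curve, simplify, tune)
from habshift.evaluation import auc
from habshift.grid import GridSpec
from habshift.sampling import CalibrationSample
from habshift.stack import PredictorStack

FAST = BRTConfig(n_folds=3, tree_step=50, max_trees=400, seed=0)


def _make_sample(X: dict[str, np.ndarray], y: np.ndarray,
                 seed: int = 0) -> CalibrationSample:
    n = len(y)
    table = pd.DataFrame(X)
    table.insert(0, "label", y.astype(int))
    table.insert(0, "lon", np.linspace(0, 1, n))
    table.insert(0, "lat", np.linspace(40, 41, n))
    table.index.name = "cell"
    return CalibrationSample(table, "random", seed, list(X))


def _logistic_sample(seed: int, n: int = 200, noise: float = 0.0,
                     extra_noise_cols: int = 0) -> CalibrationSample:
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    eta = 2.0 * x1 - 1.5 * x2 + noise * rng.normal(size=n)
    y = rng.random(n) < expit(eta)
    cols = {"x1": x1, "x2": x2}
    for k in range(extra_noise_cols):
        cols[f"noise{k}"] = rng.normal(size=n)
    return _make_sample(cols, y, seed)


class TestFitWithCv:
    def test_null_deviance_closed_form(self):
        y = np.array([1, 1, 1, 0, 0])
        p_bar = 0.6
        expected = -2 * np.mean(y * np.log(p_bar)
                                + (1 - y) * np.log(1 - p_bar))
        assert bernoulli_deviance(y, np.full(5, p_bar)) == pytest.approx(
            expected)

    def test_perfectly_separating_predictor_training_auc(self):
        y = np.repeat([0, 1], 60)
        sample = _make_sample({"x": y.astype(float),
                               "z": np.zeros(120)}, y)
        model = fit_with_cv(sample, None, FAST)
        assert auc(y, model.fitted_values) == pytest.approx(1.0)

    def test_noise_labels_select_few_trees(self):
        rng = np.random.default_rng(42)
        y = rng.integers(0, 2, 200)
        sample = _make_sample({"x1": rng.normal(size=200),
                               "x2": rng.normal(size=200)}, y)
        model = fit_with_cv(sample, None, FAST)
        assert model.n_trees <= 200
        # deviance at the selected count is the curve minimum
        assert model.cv_deviance == pytest.approx(model.cv_curve[:, 1].min())

    def test_learning_happened_on_informative_data(self):
        sample = _logistic_sample(1, n=300)
        model = fit_with_cv(sample, None, FAST)
        first = model.cv_curve[0]   # deviance after the first increment
        assert model.cv_deviance <= first[1]

    def test_reproducible_given_seed(self):
        sample = _logistic_sample(2)
        a = fit_with_cv(sample, None, FAST)
        b = fit_with_cv(sample, None, FAST)
        assert a.n_trees == b.n_trees
        np.testing.assert_array_equal(a.fitted_values, b.fitted_values)

    def test_non_finite_values_rejected(self):
        sample = _logistic_sample(3)
        sample.table.loc[sample.table.index[0], "x1"] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_with_cv(sample, None, FAST)

    def test_single_label_rejected(self):
        y = np.ones(50, dtype=int)
        sample = _make_sample({"x": np.arange(50.0)}, y)
        with pytest.raises(ValueError, match="both labels"):
            fit_with_cv(sample, None, FAST)


class TestTune:
    def test_first_iteration_uses_initial_hyperparameters(self):
        sample = _logistic_sample(4, n=150, noise=1.0)
        cfg = BRTConfig(n_folds=3, tree_step=50, max_trees=600,
                        max_loop_iterations=2, seed=1)
        model = tune(sample, None, cfg)
        first = model.tuning_history[0]
        assert first["learning_rate"] == pytest.approx(0.15)
        assert first["tree_complexity"] == 5
        assert 3 <= model.tree_complexity <= 10

    def test_exhausted_budget_returns_flagged(self):
        # a single informative point pattern cannot reach 1200+ trees in
        # one iteration with max_trees 100
        sample = _logistic_sample(5, n=120)
        cfg = BRTConfig(n_folds=3, tree_step=50, max_trees=100,
                        max_loop_iterations=2, seed=1)
        model = tune(sample, None, cfg)
        assert model.flagged
        assert len(model.tuning_history) == 2


class TestContributions:
    def test_sum_is_100(self):
        model = fit_with_cv(_logistic_sample(6), None, FAST)
        assert sum(contributions(model).values()) == pytest.approx(100.0)

    def test_never_split_predictor_zero(self):
        sample = _logistic_sample(7)
        sample.table["const"] = 1.0
        sample = CalibrationSample(sample.table, "random", 7,
                                   ["x1", "x2", "const"])
        model = fit_with_cv(sample, None, FAST)
        assert contributions(model)["const"] == 0.0

    def test_single_predictor_is_100(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=150)
        y = rng.random(150) < expit(2 * x)
        model = fit_with_cv(_make_sample({"x": x}, y), None, FAST)
        assert contributions(model)["x"] == pytest.approx(100.0)


class TestInteractions:
    def test_symmetry_and_row_sums(self):
        model = fit_with_cv(_logistic_sample(9), None, FAST)
        im = interactions(model, n_grid=10)
        np.testing.assert_allclose(im.matrix, im.matrix.T)
        assert np.all(np.diag(im.matrix) == 0)
        sums = im.sums
        for i, p in enumerate(im.predictors):
            assert sums[p] == pytest.approx(im.matrix[i].sum())
        assert im.size("x1", "x2") == im.size("x2", "x1")

    def test_product_term_yields_larger_interaction(self):
        rng = np.random.default_rng(10)
        n = 400
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y_add = rng.random(n) < expit(1.5 * x1 + 1.5 * x2)
        y_mult = rng.random(n) < expit(3.0 * x1 * x2)
        m_add = fit_with_cv(_make_sample({"x1": x1, "x2": x2}, y_add), None,
                            FAST)
        m_mult = fit_with_cv(_make_sample({"x1": x1, "x2": x2}, y_mult), None,
                             FAST)
        s_add = interactions(m_add, n_grid=10).size("x1", "x2")
        s_mult = interactions(m_mult, n_grid=10).size("x1", "x2")
        assert s_add <= 0.1 * s_mult

    def test_constant_predictor_zero_row(self):
        sample = _logistic_sample(11)
        sample.table["const"] = 5.0
        sample = CalibrationSample(sample.table, "random", 11,
                                   ["x1", "x2", "const"])
        model = fit_with_cv(sample, None, FAST)
        with pytest.warns(UserWarning, match="constant"):
            im = interactions(model, n_grid=8)
        k = im.predictors.index("const")
        assert (im.matrix[k] == 0).all()


class TestResponseCurve:
    def test_values_in_unit_interval_and_monotone_recovery(self):
        rng = np.random.default_rng(12)
        n = 400
        x = rng.uniform(-3, 3, n)
        y = rng.random(n) < expit(2 * x)
        model = fit_with_cv(_make_sample({"x": x, "z": rng.normal(size=n)},
                                         y), None, FAST)
        curve = response_curve(model, "x")
        assert ((curve.response >= 0) & (curve.response <= 1)).all()
        rho = spearmanr(curve.response, expit(2 * curve.x)).statistic
        assert rho >= 0.9

    def test_flat_for_zero_contribution_predictor(self):
        sample = _logistic_sample(13)
        sample.table["const"] = 0.0
        sample = CalibrationSample(sample.table, "random", 13,
                                   ["x1", "x2", "const"])
        model = fit_with_cv(sample, None, FAST)
        curve = response_curve(model, "const")
        assert curve.response.max() - curve.response.min() < 1e-6

    def test_unknown_predictor_rejected(self):
        model = fit_with_cv(_logistic_sample(14), None, FAST)
        with pytest.raises(KeyError):
            response_curve(model, "nope")


class TestSimplify:
    def test_noise_predictor_dropped_across_seeds(self):
        drops = 0
        for seed in range(10):
            sample = _logistic_sample(seed, n=200, extra_noise_cols=1)
            model = fit_with_cv(sample, None, FAST)
            keep = simplify(model, sample)
            if "noise0" not in keep:
                drops += 1
        assert drops >= 8

    def test_strong_independent_predictors_survive(self):
        survived = 0
        for seed in range(3):
            sample = _logistic_sample(100 + seed, n=300)
            model = fit_with_cv(sample, None, FAST)
            if set(simplify(model, sample)) == {"x1", "x2"}:
                survived += 1
        assert survived >= 2

    def test_output_subset_of_input(self):
        sample = _logistic_sample(15, extra_noise_cols=2)
        model = fit_with_cv(sample, None, FAST)
        keep = simplify(model, sample)
        assert set(keep) <= set(model.predictors)
        assert len(keep) >= 1


class TestPredictMap:
    def _stack(self, arrays):
        n = int(np.sqrt(next(iter(arrays.values())).size))
        grid = GridSpec(0, n, 0, n, 1.0)
        return PredictorStack.from_arrays(
            grid, {k: v.reshape(n, n) for k, v in arrays.items()})

    def test_constant_stack_constant_map(self):
        model = fit_with_cv(_logistic_sample(16), None, FAST)
        stack = self._stack({"x1": np.zeros(16), "x2": np.zeros(16)})
        out = predict_map(model, stack)
        assert np.unique(out.values).size == 1

    def test_values_in_unit_interval(self):
        model = fit_with_cv(_logistic_sample(17), None, FAST)
        rng = np.random.default_rng(0)
        stack = self._stack({"x1": rng.normal(size=25),
                             "x2": rng.normal(size=25)})
        out = predict_map(model, stack)
        assert ((out.values >= 0) & (out.values <= 1)).all()

    def test_training_consistency(self):
        model = fit_with_cv(_logistic_sample(18), None, FAST)
        np.testing.assert_allclose(model.predict(model.train_X),
                                   model.fitted_values)

    def test_missing_predictor_named(self):
        model = fit_with_cv(_logistic_sample(19), None, FAST)
        stack = self._stack({"x1": np.zeros(16)})
        with pytest.raises(KeyError, match="x2"):
            predict_map(model, stack)

    def test_mask_preserved(self):
        model = fit_with_cv(_logistic_sample(20), None, FAST)
        grid = GridSpec(0, 4, 0, 4, 1.0)
        mask = np.ones((4, 4), dtype=bool)
        mask[0, 0] = False
        stack = PredictorStack.from_arrays(
            grid, {"x1": np.zeros((4, 4)), "x2": np.zeros((4, 4))},
            mask=mask)
        out = predict_map(model, stack)
        assert np.isnan(out.values[0, 0])
        assert np.isfinite(out.values[1:]).all()
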