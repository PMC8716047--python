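"""Tests for the GP surrogate: designs, training, sampling, metrics."""

import numpy as np
import pytest
from scipy import stats

from ratdrive.fixtures import ThresholdSurrogate
from ratdrive.metamodel import (GPModelHandle, ParameterSpace,
                                adaptive_sample_boundary,
                                adaptive_sample_uncertainty,
                                adaptive_training_loop, drive_parameter_space,
                                evaluate_model, latin_hypercube, predict,
                                train_gp)
from ratdrive.params import DriveType

UNIT2 = ParameterSpace(("x1", "x2"), np.zeros(2), np.ones(2))


class TestLatinHypercube:
    def test_one_point_per_quartile_in_1d(self):
        space = ParameterSpace(("x",), np.zeros(1), np.ones(1))
        pts = latin_hypercube(4, space, seed=0).ravel()
        strata = np.sort(np.floor(pts * 4).astype(int))
        assert np.array_equal(strata, [0, 1, 2, 3])

    def test_marginals_uniform_in_high_dim(self):
        space = drive_parameter_space(DriveType.FEMALE_FERTILITY_HOMING)
        assert space.dim == 11
        pts = latin_hypercube(1000, space, seed=1)
        unit = space.to_unit(pts)
        for k in range(space.dim):
            _, pvalue = stats.kstest(unit[:, k], "uniform")
            assert pvalue > 1e-4

    def test_repeated_seed_reproduces_design(self):
        a = latin_hypercube(50, UNIT2, seed=9)
        b = latin_hypercube(50, UNIT2, seed=9)
        assert np.array_equal(a, b)

    def test_resistance_space_has_13_dims(self):
        space = drive_parameter_space(DriveType.VIABILITY_HOMING,
                                      with_resistance=True)
        assert space.dim == 13
        i = space.names.index("drive_fitness")
        assert space.lower[i] == 0.75


def _linear_fit(iterations=1200):
    x = latin_hypercube(60, UNIT2, seed=1)
    y = x @ np.array([1.0, 2.0])
    xv = latin_hypercube(40, UNIT2, seed=2)
    yv = xv @ np.array([1.0, 2.0])
    model = train_gp(x, y, xv, yv, UNIT2, iterations=iterations,
                     checkpoint_every=iterations // 6)
    return model, x, y, xv, yv


class TestTrainPredict:
    def test_noiseless_linear_function_interpolated(self):
        model, x, y, xv, yv = _linear_fit()
        pred, _ = predict(model, xv)
        rmse = np.sqrt(np.mean((pred - yv) ** 2))
        assert rmse < 0.05 * np.ptp(yv)

    def test_prediction_at_training_point(self):
        model, x, y, *_ = _linear_fit()
        mean, width = model.predict(x[:5])
        assert np.allclose(mean, y[:5], atol=0.05)
        far = np.array([[0.5, 0.5]]) + 0.49  # corner far from most data
        _, width_far = model.predict(far)
        assert np.all(width >= 0)

    def test_uncertainty_grows_away_from_data(self):
        x = np.array([[0.1, 0.1], [0.2, 0.2], [0.15, 0.1], [0.1, 0.2]])
        y = np.array([1.0, 2.0, 1.5, 1.4])
        model = train_gp(x, y, x, y, UNIT2, iterations=300,
                         checkpoint_every=100)
        _, w_near = model.predict(np.array([[0.15, 0.15]]))
        _, w_far = model.predict(np.array([[0.95, 0.95]]))
        assert w_far[0] > w_near[0]

    def test_identical_training_values_give_constant_model(self):
        x = np.array([[0.2, 0.2], [0.8, 0.8]])
        with pytest.warns(UserWarning):
            model = train_gp(x, np.array([3.0, 3.0]), x, np.array([3.0, 3.0]),
                             UNIT2, iterations=100, checkpoint_every=50)
        mean, width = model.predict(np.array([[0.5, 0.5]]))
        assert mean[0] == pytest.approx(3.0)
        assert width[0] == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            train_gp(np.array([[0.5, 0.5]]), np.array([1.0]),
                     np.zeros((1, 2)), np.array([0.0]), UNIT2)

    def test_batch_prediction_finite_and_vectorized(self):
        model, *_ = _linear_fit(iterations=300)
        pts = latin_hypercube(100000, UNIT2, seed=5)
        mean, width = model.predict(pts)
        assert mean.shape == (100000,)
        assert np.all(np.isfinite(mean)) and np.all(np.isfinite(width))

    def test_posterior_matches_sklearn_reference(self):
        # same kernel and hyperparameters: posterior algebra must agree
        sklearn_gp = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process.kernels import Matern, WhiteKernel

        rng = np.random.default_rng(3)
        x = rng.random((40, 2))
        y = np.sin(3 * x[:, 0]) + x[:, 1]
        model = train_gp(x, y, x, y, UNIT2, iterations=400,
                         checkpoint_every=100)
        ls = np.exp(model.log_ls)
        sf2 = np.exp(model.log_sf2)
        sn2 = np.exp(model.log_sn2)
        kernel = sf2 * Matern(length_scale=ls, nu=0.5) + \
            WhiteKernel(noise_level=sn2 + 1e-10)
        kernel.set_params()
        ref = sklearn_gp.GaussianProcessRegressor(
            kernel=kernel, optimizer=None, normalize_y=False, alpha=0.0)
        yz = (y - model.y_mean) / model.y_std
        ref.fit(x, yz)
        xt = rng.random((25, 2))
        ref_mean, ref_std = ref.predict(xt, return_std=True)
        mean, width = model.predict(xt)
        assert np.allclose(mean, ref_mean * model.y_std + model.y_mean,
                           atol=1e-6)
        # sklearn's std includes the white noise term; subtract it
        latent_std = np.sqrt(np.maximum(ref_std ** 2 - sn2 - 1e-10, 0))
        assert np.allclose(width, 2 * 1.959963984540054 * latent_std
                           * model.y_std, atol=1e-5)


class _StubModel(GPModelHandle):
    """Handle with fully controlled predictions, for sampler/metric math."""

    def __init__(self, output_type, means, widths):
        self._means = np.asarray(means, float)
        self._widths = np.asarray(widths, float)
        self.output_type = output_type
        self.space = UNIT2

    def predict(self, x):
        return self._means.copy(), self._widths.copy()


class TestAdaptiveSamplers:
    def test_selection_frequency_proportional_to_ci_width(self, rng):
        widths = np.array([5.0, 1.0, 1.0, 1.0, 2.0])
        model = _StubModel("composite", np.zeros(5), widths)
        cands = np.zeros((5, 2))
        counts = np.zeros(5)
        for _ in range(10000):
            counts[adaptive_sample_uncertainty(model, cands, 1, rng)[0]] += 1
        expected = widths / widths.sum() * 10000
        _, pvalue = stats.chisquare(counts, expected)
        assert pvalue > 1e-4

    def test_boundary_rule_composite(self, rng):
        # equal widths; v = 0 should be chosen twice as often as v = 0.5
        model = _StubModel("composite", np.array([0.0, 0.5]), np.ones(2))
        counts = np.zeros(2)
        for _ in range(6000):
            counts[adaptive_sample_boundary(model, np.zeros((2, 2)), 1,
                                            rng)[0]] += 1
        ratio = counts[0] / counts[1]
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_certain_composite_outcomes_never_drawn(self, rng):
        model = _StubModel("composite", np.array([1.0, -1.0, 0.2]),
                           np.array([10.0, 10.0, 0.1]))
        for _ in range(200):
            idx = adaptive_sample_boundary(model, np.zeros((3, 2)), 1, rng)
            assert idx[0] == 2

    def test_suppression_weight_peaks_at_half(self, rng):
        model = _StubModel("suppression_rate",
                           np.array([0.5, 0.9, 0.1]), np.ones(3))
        counts = np.zeros(3)
        for _ in range(5000):
            counts[adaptive_sample_boundary(model, np.zeros((3, 2)), 1,
                                            rng)[0]] += 1
        assert counts[0] > counts[1] and counts[0] > counts[2]

    def test_equal_weights_fall_back_to_uniform(self, rng):
        model = _StubModel("composite", np.ones(4), np.ones(4))  # all v=1
        idx = adaptive_sample_boundary(model, np.zeros((4, 2)), 4, rng)
        assert sorted(idx) == [0, 1, 2, 3]

    def test_k_equals_pool_returns_all(self, rng):
        model = _StubModel("composite", np.zeros(3), np.ones(3))
        idx = adaptive_sample_uncertainty(model, np.zeros((3, 2)), 3, rng)
        assert sorted(idx) == [0, 1, 2]


class TestEvaluateModel:
    def test_perfect_predictor(self):
        obs = np.array([0.0, 1.0, 1.0, 0.0])
        model = _StubModel("suppression_rate", obs, np.ones(4))
        out = evaluate_model(model, np.zeros((4, 2)), obs)
        assert out["rmse"] == 0.0
        assert out["precision"] == 1.0 and out["recall"] == 1.0

    def test_confusion_table_arithmetic(self):
        # TP=3, FP=1, FN=2 -> precision 0.75, recall 0.6
        preds = np.array([0.9, 0.9, 0.9, 0.9, 0.1, 0.1])
        obs = np.array([1.0, 1.0, 1.0, 0.0, 1.0, 1.0])
        model = _StubModel("suppression_rate", preds, np.ones(6))
        out = evaluate_model(model, np.zeros((6, 2)), obs)
        assert out["precision"] == pytest.approx(0.75)
        assert out["recall"] == pytest.approx(0.6)

    def test_constant_zero_predictor_has_zero_recall_low_rmse(self):
        obs = np.concatenate([np.zeros(95), np.ones(5)])
        model = _StubModel("suppression_rate", np.zeros(100), np.ones(100))
        out = evaluate_model(model, np.zeros((100, 2)), obs)
        assert out["recall"] == 0.0
        assert out["precision"] is None
        assert out["rmse"] < 0.25

    def test_composite_predictions_scaled_before_rmse(self):
        model = _StubModel("composite", np.array([1.0, -1.0]), np.ones(2))
        out = evaluate_model(model, np.zeros((2, 2)),
                             np.array([1.0, 0.0]))
        assert out["rmse"] == 0.0

    def test_threshold_invariant_to_monotone_rescaling(self):
        preds = np.array([-0.4, 0.3, 0.8, -0.1])
        obs = np.array([0.0, 1.0, 1.0, 1.0])
        base = evaluate_model(_StubModel("composite", preds, np.ones(4)),
                              np.zeros((4, 2)), obs)
        squashed = evaluate_model(
            _StubModel("composite", np.tanh(3 * preds), np.ones(4)),
            np.zeros((4, 2)), obs)
        assert base["precision"] == squashed["precision"]
        assert base["recall"] == squashed["recall"]

    def test_rates_outside_unit_interval_rejected(self):
        model = _StubModel("suppression_rate", np.zeros(2), np.ones(2))
        with pytest.raises(ValueError):
            evaluate_model(model, np.zeros((2, 2)), np.array([0.5, 1.2]))


class TestAdaptiveLoop:
    def test_no_adaptive_rounds_when_budget_met(self):
        surrogate = ThresholdSurrogate()
        out = adaptive_training_loop(
            lambda x: surrogate(x), UNIT2, initial_n=60, batch=30,
            final_n=60, candidate_pool_n=500, validation_n=40,
            iterations=200, checkpoint_every=100, seed=1)
        assert len(out["manifest"]) == 1
        assert out["manifest"][0]["strategy"] == "latin_hypercube"
        assert len(out["train_x"]) == 60

    def test_manifest_lists_every_batch_with_strategies(self):
        surrogate = ThresholdSurrogate()
        out = adaptive_training_loop(
            lambda x: surrogate(x), UNIT2, initial_n=50, batch=25,
            final_n=100, candidate_pool_n=400, validation_n=40,
            iterations=200, checkpoint_every=100, seed=2)
        strategies = [m["strategy"] for m in out["manifest"][1:]]
        assert strategies[0] == "uncertainty"
        assert "boundary" in strategies
        assert sum(m["n"] for m in out["manifest"][1:]) == 50
        assert len(out["train_x"]) == 100
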