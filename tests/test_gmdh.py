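import numpy as np
import pytest

from emg_gmdh import (
    GmdhConfig,
    TrainingError,
    external_criterion,
    fit_neuron,
    forecast_fit,
    forecast_predict,
    forecast_predict_series,
    polynomial_terms,
    simulate_polynomial_dataset,
    train,
)


def assert_accepted_scores_decrease(model):
    """Accepted layers must improve the best criterion by more than epsilon."""
    eps = model.config.epsilon
    best = np.inf
    for entry in model.history:
        if entry["accepted"]:
            assert entry["best_score"] < best - eps or best == np.inf
            best = entry["best_score"]


class TestPolynomialTerms:
    def test_basis_values(self):
        np.testing.assert_array_equal(
            polynomial_terms("linear_cov", 2.0, 3.0), [1, 2, 3, 6]
        )
        np.testing.assert_array_equal(
            polynomial_terms("quadratic", 0.0, 0.0), [1, 0, 0, 0, 0, 0]
        )
        np.testing.assert_array_equal(polynomial_terms("linear", 5.0, 5.0), [1, 5, 5])

    def test_vectorized_shape(self, rng):
        u, v = rng.normal(size=10), rng.normal(size=10)
        assert polynomial_terms("quadratic", u, v).shape == (10, 6)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="reference function"):
            polynomial_terms("cubic", 1.0, 1.0)


class TestFitNeuron:
    def test_exact_interpolation_linear(self, rng):
        u, v = rng.normal(size=50), rng.normal(size=50)
        w = fit_neuron(u, v, 1 + 2 * u + 3 * v, "linear", l2=0.0)
        np.testing.assert_allclose(w, [1, 2, 3], atol=1e-9)

    def test_exact_interpolation_covariance(self, rng):
        u, v = rng.normal(size=50), rng.normal(size=50)
        w = fit_neuron(u, v, u * v, "linear_cov", l2=0.0)
        np.testing.assert_allclose(w, [0, 0, 0, 1], atol=1e-9)

    def test_ridge_matches_closed_form_normal_equations(self, rng):
        u, v = rng.normal(size=80), rng.normal(size=80)
        y = 1 + 2 * u + 3 * v
        B = polynomial_terms("linear", u, v)
        oracle = np.linalg.solve(B.T @ B + 0.5 * np.eye(3), B.T @ y)
        w = fit_neuron(u, v, y, "linear", l2=0.5)
        np.testing.assert_allclose(w, oracle, atol=1e-10)
        assert not np.allclose(w, [1, 2, 3])  # shrinkage moved the solution

    def test_l2_zero_limit_is_ols(self, rng):
        u, v = rng.normal(size=60), rng.normal(size=60)
        y = rng.normal(size=60)
        np.testing.assert_allclose(
            fit_neuron(u, v, y, "linear_cov", l2=1e-12),
            fit_neuron(u, v, y, "linear_cov", l2=0.0),
            atol=1e-8,
        )


class TestExternalCriterion:
    def test_noiseless_linear_data_scores_zero(self, rng):
        u, v = rng.normal(size=40), rng.normal(size=40)
        y = 1 + 2 * u - v
        idx_a, idx_b = np.arange(20), np.arange(20, 40)
        wa = fit_neuron(u[idx_a], v[idx_a], y[idx_a], "linear", 0.0)
        wb = fit_neuron(u[idx_b], v[idx_b], y[idx_b], "linear", 0.0)
        for kind in ("validate", "bias", "validate_bias"):
            assert external_criterion(wa, wb, u, v, y, idx_b, kind) < 1e-16

    def test_identical_subsets_have_zero_bias(self, rng):
        u, v = rng.normal(size=30), rng.normal(size=30)
        y = rng.normal(size=30)
        w = fit_neuron(u, v, y, "linear", 0.0)
        assert external_criterion(w, w, u, v, y, np.arange(30), "bias") == 0.0

    def test_matches_brute_force_recomputation(self, rng):
        u, v = rng.normal(size=50), rng.normal(size=50)
        y = rng.normal(size=50)
        idx_a, idx_b = np.arange(25), np.arange(25, 50)
        wa = fit_neuron(u[idx_a], v[idx_a], y[idx_a], "linear_cov", 0.1)
        wb = fit_neuron(u[idx_b], v[idx_b], y[idx_b], "linear_cov", 0.1)
        B = np.column_stack([np.ones(50), u, v, u * v])
        validate = np.mean((B[idx_b] @ wa - y[idx_b]) ** 2)
        bias = np.mean((B @ wa - B @ wb) ** 2)
        got = external_criterion(wa, wb, u, v, y, idx_b, "validate_bias")
        assert got == pytest.approx(validate + bias, rel=1e-12)

    def test_empty_validation_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            external_criterion([0, 0, 0], [0, 0, 0], [1.0], [1.0], [1.0], [], "validate")


class TestTrain:
    def test_single_neuron_recovery(self):
        X, y = simulate_polynomial_dataset(
            "linear_cov", [3, 2, -1, 0.5], 200, 0.0, seed=1
        )
        model = train(X, y, GmdhConfig(ref_function="linear_cov", l2=0.0))
        assert model.selected_output[0] == 0  # best model found in layer 1
        assert model.criterion_score < 1e-10
        np.testing.assert_allclose(
            model.layers[0][model.selected_output[1]].weights,
            [3, 2, -1, 0.5],
            atol=1e-6,
        )
        assert np.mean((model.predict(X) - y) ** 2) < 1e-10
        assert_accepted_scores_decrease(model)

    def test_composed_product_needs_depth(self, rng):
        X = rng.uniform(-1, 1, size=(1_000, 4))
        y = (X[:, 0] * X[:, 1]) * (X[:, 2] * X[:, 3])
        cfg = GmdhConfig(ref_function="linear_cov", l2=0.0, criterion="validate",
                         epsilon=1e-9, max_layers=10)
        model = train(X, y, cfg)
        accepted = sum(h["accepted"] for h in model.history)
        assert accepted >= 2
        # depth strictly improves over the best single layer-1 neuron
        assert model.criterion_score < model.history[0]["best_score"]
        assert_accepted_scores_decrease(model)

    def test_pure_noise_targets_train_without_error(self, rng):
        X = rng.normal(size=(400, 6))
        y = rng.normal(size=400)
        model = train(X, y, GmdhConfig(ref_function="linear", l2=0.0))
        # growth stalls quickly: lookback halts before the layer cap
        assert len(model.history) < model.config.max_layers
        assert sum(h["accepted"] for h in model.history) <= 3
        assert_accepted_scores_decrease(model)

    def test_pruned_model_matches_full_network_evaluation(self, rng):
        X = rng.uniform(-1, 1, size=(300, 5))
        y = X[:, 0] * X[:, 1] + 0.3 * X[:, 2] + 0.1 * rng.normal(size=300)
        cfg = dict(ref_function="linear_cov", l2=0.0, epsilon=1e-6, max_layers=6)
        pruned = train(X, y, GmdhConfig(**cfg, prune=True))
        full = train(X, y, GmdhConfig(**cfg, prune=False))
        probe = rng.uniform(-1, 1, size=(100, 5))
        np.testing.assert_allclose(
            pruned.predict(probe), full.predict(probe), atol=1e-12, rtol=0
        )
        assert pruned.n_neurons() <= full.n_neurons()

    def test_deterministic_given_data_and_config(self, rng):
        X = rng.normal(size=(200, 4))
        y = rng.normal(size=200)
        cfg = GmdhConfig(ref_function="linear", l2=0.1)

        def structure(model):
            d = model.to_dict()
            for entry in d["history"]:  # wall-clock timing is not structural
                entry.pop("wall_time_s")
            return d

        assert structure(train(X, y, cfg)) == structure(train(X, y, cfg))

    def test_constant_targets_are_fit_despite_degenerate_candidates(self):
        X = np.ones((40, 3))
        model = train(X, np.full(40, 5.0), GmdhConfig(ref_function="linear", l2=0.0))
        assert model.predict(np.ones((3, 3))) == pytest.approx(5.0)

    def test_input_validation(self, rng):
        cfg = GmdhConfig(ref_function="linear_cov")
        with pytest.raises(ValueError, match="2 input columns"):
            train(rng.normal(size=(50, 1)), rng.normal(size=50), cfg)
        with pytest.raises(ValueError, match="rows"):
            train(rng.normal(size=(5, 3)), rng.normal(size=5), cfg)
        model = train(rng.normal(size=(50, 3)), rng.normal(size=50),
                      GmdhConfig(ref_function="linear"))
        with pytest.raises(ValueError, match="input columns"):
            model.predict(rng.normal(size=(5, 4)))


class TestForecasting:
    def test_residual_model_exact_on_linear_ramp(self):
        ramp = np.arange(2_000, dtype=float)
        model, meta = forecast_fit(ramp, lag=10, residual=True,
                                   config=GmdhConfig(ref_function="linear", l2=0.0))
        preds, truth = forecast_predict_series(model, meta, ramp)
        assert np.sqrt(np.mean((preds - truth) ** 2)) < 1e-6

    @pytest.mark.parametrize("residual", [False, True])
    def test_constant_series_predicted_exactly(self, residual):
        const = np.full(200, 5.0)
        model, meta = forecast_fit(const, lag=10, residual=residual,
                                   config=GmdhConfig(ref_function="linear", l2=0.0))
        assert forecast_predict(model, meta, const[:10]) == pytest.approx(5.0, abs=1e-9)

    def test_residual_prediction_is_model_output_plus_last_sample(self):
        const = np.full(100, 2.0)
        model, meta = forecast_fit(const, lag=5, residual=True,
                                   config=GmdhConfig(ref_function="linear", l2=0.0))
        window = np.full(5, 42.0)
        out = float(model.predict(window[None, :])[0])
        assert forecast_predict(model, meta, window) == pytest.approx(out + 42.0)

    def test_window_prediction_matches_series_evaluation(self, rng):
        series = np.cumsum(rng.normal(size=500))
        model, meta = forecast_fit(series[:400], lag=10, residual=True)
        preds, _ = forecast_predict_series(model, meta, series)
        for i in (0, 100, 487):
            window = series[i : i + 10]
            assert forecast_predict(model, meta, window) == pytest.approx(
                preds[i], abs=1e-12
            )

    def test_length_validation(self):
        with pytest.raises(ValueError, match="too short"):
            forecast_fit(np.arange(15.0), lag=10)
        model, meta = forecast_fit(np.arange(100.0), lag=10)
        with pytest.raises(ValueError, match="lag"):
            forecast_predict(model, meta, np.zeros(5))
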