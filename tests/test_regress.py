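"""Regression harness tests: preprocessing, metrics, rank costs, optimizer
update rules, the from-scratch MLP and baseline regressors."""

import numpy as np
import pytest

from depchain.chains import bin_chain_sizes
from depchain.optim import OptimizerState, optimizer_step
from depchain.regress import (
    KNNRegressor,
    LinearRegressionOLS,
    baseline_regressors,
    evaluate,
    impute_median,
    rank_cost_matrix,
    split_train_test,
    train_mlp,
)
from depchain.synthetic import sample_chain_lengths


class TestImputation:
    def test_odd_count_median(self):
        X = np.array([[1.0], [np.nan], [3.0]])
        np.testing.assert_array_equal(impute_median(X), [[1], [2], [3]])

    def test_no_missing_is_identity(self):
        X = np.arange(6, dtype=float).reshape(3, 2)
        np.testing.assert_array_equal(impute_median(X), X)

    def test_even_count_mean_of_middle(self):
        X = np.array([[1.0], [2.0], [np.nan], [100.0]])
        assert impute_median(X)[2, 0] == 2.0  # median of {1,2,100} = 2

    def test_fully_missing_column_rejected(self):
        with pytest.raises(ValueError, match="fully missing"):
            impute_median(np.array([[np.nan], [np.nan]]))


class TestSplit:
    def test_80_20_sizes(self):
        X = np.arange(200).reshape(100, 2)
        y = np.arange(100)
        (Xtr, ytr), (Xte, yte) = split_train_test(X, y, 0.8, seed=0)
        assert len(ytr) == 80 and len(yte) == 20

    def test_same_seed_same_split(self):
        X = np.arange(50).reshape(25, 2)
        y = np.arange(25)
        s1 = split_train_test(X, y, seed=3)
        s2 = split_train_test(X, y, seed=3)
        np.testing.assert_array_equal(s1[0][1], s2[0][1])

    def test_partition_property(self):
        y = np.arange(40)
        (_, ytr), (_, yte) = split_train_test(np.zeros((40, 1)), y, 0.8, seed=1)
        assert sorted(np.concatenate([ytr, yte]).tolist()) == list(range(40))

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(np.zeros((10, 1)), np.zeros(10), 1.5)


class TestMetrics:
    def test_hand_computed_example(self):
        rep = evaluate(np.array([1.0, 2, 3]), np.array([2.0, 2, 2]))
        assert rep.mae == pytest.approx(2 / 3)
        assert rep.mse == pytest.approx(2 / 3)
        assert rep.rmse == pytest.approx(np.sqrt(2 / 3))
        assert rep.mre == pytest.approx(4 / 9)
        assert rep.r_squared == pytest.approx(0.0)
        assert rep.accuracy == pytest.approx(1 / 3)

    def test_perfect_prediction(self):
        y = np.array([1.0, 5.0, 9.0])
        rep = evaluate(y, y)
        assert rep.mae == rep.mse == rep.rmse == 0
        assert rep.r_squared == 1 and rep.accuracy == 1 and rep.mre == 0

    def test_null_model_r_squared_zero(self):
        y = np.array([1.0, 2, 3, 4])
        rep = evaluate(y, np.full(4, y.mean()))
        assert rep.r_squared == pytest.approx(0.0)

    def test_metric_identities_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(2, 40)
            y = rng.normal(5, 2, n)
            y_hat = y + rng.normal(0, 1, n)
            rep = evaluate(y, y_hat)
            assert rep.rmse**2 == pytest.approx(rep.mse, rel=1e-12)
            assert rep.mae <= rep.rmse + 1e-12
            assert rep.r_squared <= 1.0

    def test_mre_omitted_for_zero_actuals(self):
        rep = evaluate(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        assert rep.mre is None

    def test_half_volt_band_is_strict(self):
        rep = evaluate(np.array([1.0]), np.array([1.5]))
        assert rep.accuracy == 0.0


class TestRankCost:
    def test_three_rank_example(self):
        C = rank_cost_matrix(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(C, [[0, 1, 2], [1, 0, 1], [2, 1, 0]])

    def test_single_rank(self):
        np.testing.assert_array_equal(rank_cost_matrix(np.array([4.0])), [[0.0]])

    def test_symmetry_and_zero_diagonal(self):
        u = np.sort(np.random.default_rng(0).uniform(0, 10, 6))
        C = rank_cost_matrix(u)
        np.testing.assert_array_equal(C, C.T)
        assert np.diag(C).sum() == 0
        assert (C[~np.eye(6, dtype=bool)] > 0).all()

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            rank_cost_matrix(np.array([1.0, 1.0, 2.0]))


def manual_step(kind, w, dw, s, v, t, alpha, beta, beta1, beta2, eps):
    """Plain transcription of the published update rules, one step."""
    if kind == "sgdm":
        s = beta * s + (1 - beta) * dw
        return w - alpha * s
    if kind == "rmsprop":
        v = beta * v + (1 - beta) * dw**2
        return w - alpha * dw / np.sqrt(v + eps)
    s = beta1 * s + (1 - beta1) * dw
    v = beta2 * v + (1 - beta2) * dw**2
    s_hat = s / (1 - beta1**t)
    v_hat = v / (1 - beta2**t)
    return w - alpha * s_hat / np.sqrt(v_hat + eps)


class TestOptimizers:
    @pytest.mark.parametrize("kind", ["sgdm", "rmsprop", "adam"])
    def test_matches_manual_rule_from_random_states(self, kind):
        rng = np.random.default_rng(1)
        for _ in range(100):
            w = rng.normal(size=4)
            dw = rng.normal(size=4)
            s = rng.normal(size=4)
            v = rng.uniform(0, 1, size=4)
            t = int(rng.integers(1, 50))
            st = OptimizerState(kind=kind, alpha=1e-3)
            st.s_dw, st.v_dw, st.t = s.copy(), v.copy(), t
            got = optimizer_step(st, w, dw)
            want = manual_step(kind, w, dw, s, v, t, 1e-3, 0.9, 0.9, 0.999, 1e-8)
            np.testing.assert_allclose(got, want, atol=1e-12, rtol=0)
            assert st.t == t + 1

    @pytest.mark.parametrize("kind", ["sgdm", "rmsprop", "adam"])
    def test_zero_gradient_keeps_weights(self, kind):
        st = OptimizerState(kind=kind, alpha=0.1)
        w = np.array([1.0, -2.0])
        new_w = optimizer_step(st, w, np.zeros(2))
        np.testing.assert_array_equal(new_w, w)

    def test_sgdm_without_momentum_is_plain_gd(self):
        st = OptimizerState(kind="sgdm", alpha=0.5, beta=0.0)
        w = np.array([1.0])
        dw = np.array([0.2])
        assert optimizer_step(st, w, dw)[0] == pytest.approx(1.0 - 0.5 * 0.2)

    def test_adam_first_step_magnitude_is_learning_rate(self):
        st = OptimizerState(kind="adam", alpha=1e-3)
        w = np.array([0.0])
        new_w = optimizer_step(st, w, np.ones(1))
        assert new_w[0] == pytest.approx(-1e-3, rel=1e-5)

    def test_multi_step_trajectory_matches_sequential_oracle(self):
        rng = np.random.default_rng(2)
        st = OptimizerState(kind="adam", alpha=1e-2)
        w = np.array([0.3, -0.7])
        s = np.zeros(2)
        v = np.zeros(2)
        for t in range(1, 11):
            dw = rng.normal(size=2)
            w_expected = manual_step("adam", w, dw, s, v, t, 1e-2, 0.9, 0.9, 0.999, 1e-8)
            s = 0.9 * s + 0.1 * dw
            v = 0.999 * v + 0.001 * dw**2
            w = optimizer_step(st, w, dw)
            np.testing.assert_allclose(w, w_expected, atol=1e-12)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            OptimizerState(kind="adagrad")


def synthetic_feature_dataset(seed=0, per_voltage=30):
    """Chain-count predictors sampled directly from the length model
    (no imaging), for fast regression tests."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for v in range(1, 11):
        for _ in range(per_voltage):
            lengths = sample_chain_lengths(v, 20, rng)
            X.append(bin_chain_sizes(lengths).as_predictors())
            y.append(float(v))
    return np.array(X), np.array(y)


class TestMLP:
    def test_learns_exact_linear_map(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, (200, 1))
        y = 2 * x[:, 0] + 1
        model = train_mlp(
            x[:160], y[:160], hidden=16, optimizer="adam",
            alpha=1e-3, batch_size=10, epochs=500, seed=1,
        )
        rmse = float(np.sqrt(np.mean((model.predict(x[160:]) - y[160:]) ** 2)))
        assert rmse < 0.05

    def test_zero_epochs_returns_initialization(self):
        X, y = synthetic_feature_dataset()
        model = train_mlp(X, y, epochs=0)
        preds = model.predict(X)
        assert np.isfinite(preds).all()
        assert model.loss_history == []

    def test_training_reduces_loss(self):
        X, y = synthetic_feature_dataset()
        model = train_mlp(X, y, hidden=32, alpha=1e-4, epochs=100, seed=42)
        assert model.loss_history[-1] < model.loss_history[0]

    def test_seeded_training_is_deterministic(self):
        X, y = synthetic_feature_dataset(per_voltage=10)
        m1 = train_mlp(X, y, epochs=5, seed=7)
        m2 = train_mlp(X, y, epochs=5, seed=7)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_mlp(np.zeros((0, 3)), np.zeros(0), epochs=1)


class TestBaselines:
    def test_one_nn_memorizes_training_point(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([5.0, 7.0, 9.0])
        model = KNNRegressor(k=1).fit(X, y)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_full_neighborhood_predicts_mean(self):
        X = np.random.default_rng(0).uniform(0, 1, (10, 2))
        y = np.arange(10.0)
        model = KNNRegressor(k=10).fit(X, y)
        np.testing.assert_allclose(model.predict(X[:3]), y.mean())

    def test_k_exceeding_train_size_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            KNNRegressor(k=5).fit(np.zeros((3, 1)), np.zeros(3))

    def test_ols_recovers_exact_linear_coefficients(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-2, 2, (50, 3))
        beta = np.array([1.5, -2.0, 0.25])
        y = X @ beta + 4.0
        model = LinearRegressionOLS().fit(X, y)
        np.testing.assert_allclose(model.coef_, beta, atol=1e-8)
        assert model.intercept_ == pytest.approx(4.0, abs=1e-8)
        # against the normal-equations oracle
        A = np.column_stack([np.ones(50), X])
        oracle = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(
            np.concatenate([[model.intercept_], model.coef_]), oracle, atol=1e-8
        )

    def test_baseline_factory_returns_fitted_models(self):
        X, y = synthetic_feature_dataset(per_voltage=5)
        models = baseline_regressors(X, y)
        assert set(models) == {"knn", "linear"}
        for model in models.values():
            assert np.isfinite(model.predict(X[:4])).all()
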