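"""LM-trained MLP: forward pass, Jacobian, early stopping, sensitivity."""

import numpy as np
import pytest

from qsrr import ANNConfig, forward, multi_restart, select_architecture, sensitivity, train_lm
from qsrr.ann import ANNModel, _net_forward, jacobian
from qsrr.pretreatment import Scaler


def _toy_model(W1, w2, d):
    return ANNModel(
        hidden_units=W1.shape[0],
        input_weights=W1,
        output_weights=w2,
        x_scaler=Scaler(np.zeros(d), np.ones(d), np.arange(1)),
        y_mean=0.0,
        y_sd=1.0,
        best_val_rmse=np.nan,
        epochs_run=0,
        restart_seed=0,
    )


def _linear_toy(rng, n=60, n_val=20):
    x = rng.uniform(-1, 1, size=(n, 1))
    xv = rng.uniform(-1, 1, size=(n_val, 1))
    return x, 2 * x[:, 0] + 1, xv, 2 * xv[:, 0] + 1


class TestForward:
    def test_zero_weights(self):
        m = _toy_model(np.zeros((3, 4)), np.zeros(4), d=3)
        assert forward(m, np.zeros(3)) == 0.0

    def test_output_bias_only(self, rng):
        m = _toy_model(np.zeros((2, 3)), np.array([0.7, 0.0, 0.0]), d=2)
        assert forward(m, rng.normal(size=2)) == pytest.approx(0.7)

    def test_hand_computed_single_unit(self):
        # 1 hidden unit: out = b2 + v * tanh(w1_bias) at x = 0
        W1 = np.array([[0.3, 1.2]])
        w2 = np.array([0.1, 0.5])
        m = _toy_model(W1, w2, d=1)
        expected = 0.1 + 0.5 * np.tanh(0.3)
        assert forward(m, np.zeros(1)) == pytest.approx(expected, abs=1e-12)

    def test_parameter_count_7_4_1(self):
        m = _toy_model(np.zeros((4, 8)), np.zeros(5), d=7)
        assert m.n_parameters == 37


class TestJacobian:
    def test_matches_central_differences(self, rng):
        h, d, n = 3, 4, 12
        w = rng.uniform(-0.5, 0.5, size=h * (d + 1) + h + 1)
        X = rng.normal(size=(n, d))
        J = jacobian(w, X, h)
        Jfd = np.empty_like(J)
        eps = 1e-6
        for p in range(w.size):
            wp, wm = w.copy(), w.copy()
            wp[p] += eps
            wm[p] -= eps
            Jfd[:, p] = (_net_forward(wp, X, h)[0] - _net_forward(wm, X, h)[0]) / (2 * eps)
        assert np.abs(J - Jfd).max() / np.abs(Jfd).max() < 1e-6


class TestTrainLM:
    def test_linear_target_converges(self, rng):
        x, y, xv, yv = _linear_toy(rng)
        m = train_lm(x, y, xv, yv, 2, ANNConfig(), seed=1)
        rmse = np.sqrt(np.mean((y - m.predict(x)) ** 2))
        assert rmse < 1e-3
        assert m.epochs_run <= 150

    def test_deterministic_given_seed(self, rng):
        x, y, xv, yv = _linear_toy(rng)
        a = train_lm(x, y, xv, yv, 3, ANNConfig(max_epochs=30), seed=9)
        b = train_lm(x, y, xv, yv, 3, ANNConfig(max_epochs=30), seed=9)
        np.testing.assert_array_equal(a.input_weights, b.input_weights)
        np.testing.assert_array_equal(a.output_weights, b.output_weights)

    def test_patience_stops_early(self, rng):
        # validation target unrelated to training: val error cannot improve
        # systematically, so patience must trigger well before max_epochs
        x, y, _, _ = _linear_toy(rng)
        xv = rng.uniform(-1, 1, size=(20, 1))
        yv = rng.normal(size=20) * 50 + 100
        m = train_lm(x, y, xv, yv, 2, ANNConfig(patience=3), seed=2)
        assert m.epochs_run < 150

    def test_best_weights_contract(self, rng):
        x, y, xv, yv = _linear_toy(rng)
        yv_noisy = yv + rng.normal(size=yv.size) * 0.2
        m = train_lm(x, y, xv, yv_noisy, 4, ANNConfig(), seed=3)
        assert m.best_val_rmse <= min(m.val_history) + 1e-12


class TestMultiRestart:
    def test_single_restart(self, rng):
        x, y, xv, yv = _linear_toy(rng)
        model, table = multi_restart(x, y, xv, yv, 2, ANNConfig(n_restarts=1, seed=4))
        assert (table["restart"] != "mean").sum() - (table["restart"] == "sd").sum() >= 1
        runs = table[~table["restart"].isin(["mean", "sd"])]
        assert len(runs) == 1
        assert model.best_val_rmse == pytest.approx(runs["val_rmse"].iloc[0])

    def test_noiseless_linear_stable_across_restarts(self, rng):
        x, y, xv, yv = _linear_toy(rng)
        _, table = multi_restart(x, y, xv, yv, 2, ANNConfig(n_restarts=15, seed=5))
        runs = table[~table["restart"].isin(["mean", "sd"])]
        assert runs["train_rmse"].std(ddof=1) < 1e-2

    def test_reproducible_table(self, rng):
        x, y, xv, yv = _linear_toy(rng)
        cfg = ANNConfig(n_restarts=4, max_epochs=30, seed=6)
        _, t1 = multi_restart(x, y, xv, yv, 2, cfg)
        _, t2 = multi_restart(x, y, xv, yv, 2, cfg)
        assert t1.equals(t2)


class TestSelectArchitecture:
    def test_single_size_range(self, rng):
        x, y, xv, yv = _linear_toy(rng)
        h, table = select_architecture(
            x, y, xv, yv, ANNConfig(hidden_range=(3, 3), max_epochs=30, seed=7)
        )
        assert h == 3 and len(table) == 1

    def test_argmin_self_consistency(self, rng):
        x, y, xv, yv = _linear_toy(rng)
        h, table = select_architecture(
            x, y, xv, yv, ANNConfig(hidden_range=(2, 5), max_epochs=40, seed=8)
        )
        assert h == int(table.loc[table["median_val_rmse"].idxmin(), "hidden"])

    def test_linear_target_no_gain_from_width(self, rng):
        x, y, xv, yv = _linear_toy(rng, n=80, n_val=30)
        _, table = select_architecture(
            x, y, xv, yv, ANNConfig(hidden_range=(2, 10), max_epochs=60, seed=9)
        )
        base = table.loc[table["hidden"] == 2, "median_val_rmse"].iloc[0]
        # all sizes fit a line essentially perfectly: any median-RMSE gain
        # from widening is below 5% of the response scale
        assert base - table["median_val_rmse"].min() < 0.05 * yv.std(ddof=1)


class TestSensitivity:
    def test_zero_weight_descriptor_ranked_last(self, rng):
        # unit 1 reads input 0 only; input 1 has zero weights everywhere
        W1 = np.array([[0.0, 1.0, 0.0]])
        w2 = np.array([0.0, 1.0])
        m = _toy_model(W1, w2, d=2)
        X = rng.normal(size=(30, 2))
        rep = sensitivity([m], X, descriptor_names=["a", "b"])
        assert rep.table.loc[rep.table["descriptor"] == "b", "mean_abs_change"].iloc[0] == 0.0
        assert rep.ranks()["b"] == 2

    def test_linear_net_closed_form(self, rng):
        # near-linear regime: tiny weights keep tanh(z) ~ z, so
        # |delta yhat| ~ |v w delta x| exactly as in a linear model
        w_in = 1e-4
        W1 = np.array([[0.0, w_in]])
        w2 = np.array([0.0, 1.0])
        m = _toy_model(W1, w2, d=1)
        X = rng.normal(size=(50, 1))
        delta = 0.05
        rep = sensitivity([m], X, deltas=(delta,))
        expected = np.mean(np.abs(w_in * delta * X[:, 0]))
        got = rep.table["mean_abs_change"].iloc[0]
        assert got == pytest.approx(expected, rel=1e-6)

    def test_duplicate_models_do_not_change_report(self, rng):
        W1 = rng.uniform(-0.5, 0.5, size=(3, 4))
        w2 = rng.uniform(-0.5, 0.5, size=4)
        m = _toy_model(W1, w2, d=3)
        X = rng.normal(size=(20, 3))
        one = sensitivity([m], X)
        two = sensitivity([m, m], X)
        np.testing.assert_allclose(
            one.table["mean_abs_change"], two.table["mean_abs_change"], atol=1e-12
        )
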