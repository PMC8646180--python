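"""Network correctness: forward pass, loss, analytic gradients, training,
degenerate equivalences (logistic regression, plain gradient descent),
survival curves, and the nonlinear prognostic index."""

import numpy as np
import pandas as pd
import pytest

import plannsim as ps
from plannsim import plann_models as pm
from plannsim.errors import InvalidArgumentError


def _weights(rng, J, H):
    return pm.NetworkWeights(
        W1=rng.normal(scale=0.3, size=(J, H)),
        b1=rng.normal(scale=0.3, size=H),
        w2=rng.normal(scale=0.3, size=H),
        b2=float(rng.normal(scale=0.3)),
    )


class TestForward:
    def test_zero_weights_give_half(self):
        w = pm.NetworkWeights(np.zeros((4, 3)), np.zeros(3), np.zeros(3), 0.0)
        X = np.random.default_rng(0).normal(size=(6, 4))
        assert np.allclose(pm.forward(w, X), 0.5)

    def test_large_negative_bias_saturates_to_zero(self):
        w = pm.NetworkWeights(np.zeros((2, 1)), np.zeros(1), np.zeros(1), -50.0)
        assert pm.forward(w, np.ones((3, 2))).max() < 1e-20

    @pytest.mark.parametrize("activation", pm.ACTIVATIONS)
    def test_matches_hand_rolled_two_layer(self, activation):
        rng = np.random.default_rng(7)
        w = _weights(rng, J=4, H=3)
        X = rng.normal(size=(3, 4))
        got = pm.forward(w, X, activation)
        # independent re-implementation, scalar arithmetic row by row
        def act(v):
            if activation == "logistic":
                return 1 / (1 + np.exp(-v))
            if activation == "relu":
                return max(0.0, v)
            return np.tanh(v)
        for i in range(3):
            hidden = [
                act(w.b1[h] + sum(X[i, j] * w.W1[j, h] for j in range(4)))
                for h in range(3)
            ]
            eta = w.b2 + sum(hidden[h] * w.w2[h] for h in range(3))
            expected = 1 / (1 + np.exp(-eta))
            assert got[i] == pytest.approx(expected, abs=1e-12)

    def test_width_mismatch_raises(self):
        w = pm.NetworkWeights(np.zeros((4, 2)), np.zeros(2), np.zeros(2), 0.0)
        with pytest.raises(InvalidArgumentError):
            pm.forward(w, np.ones((2, 5)))

    def test_nonfinite_weights_raise(self):
        w = pm.NetworkWeights(np.full((2, 1), np.nan), np.zeros(1), np.zeros(1), 0.0)
        with pytest.raises(FloatingPointError):
            pm.forward(w, np.ones((1, 2)))


class TestLoss:
    def test_perfect_predictions_vanish(self):
        d = np.array([1.0, 0.0, 1.0])
        h = np.array([1 - 1e-12, 1e-12, 1 - 1e-12])
        # predictions are clipped at 1e-7, bounding the attainable loss below
        assert pm.loss(h, d) < 1e-5

    def test_half_predictions_closed_form(self):
        n = 11
        assert pm.loss(np.full(n, 0.5), np.zeros(n)) == pytest.approx(n * np.log(2))

    def test_class_weight_adds_event_row_contribution(self):
        h = np.array([0.3, 0.6, 0.2, 0.9])
        d = np.array([0.0, 1.0, 0.0, 0.0])
        base = pm.loss(h, d)
        weighted = pm.loss(h, d, row_weights=np.where(d == 1, 2.0, 1.0))
        event_term = -np.log(0.6)
        assert weighted - base == pytest.approx(event_term, abs=1e-12)

    def test_boundary_predictions_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            value = pm.loss(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert np.isfinite(value)


class TestGradients:
    # H = 0 has no hidden layer, so only the logistic case is meaningful there
    @pytest.mark.parametrize(
        "activation,H",
        [("logistic", 0), ("logistic", 3), ("relu", 3), ("tanh", 3)],
    )
    def test_analytic_gradient_matches_finite_differences(self, activation, H):
        rng = np.random.default_rng(42)
        n, J = 10, 4
        X = rng.normal(size=(n, J))
        d = (rng.random(n) < 0.3).astype(float)
        w = np.where(d == 1, 1.05, 1.0)
        n_params = J + 1 if H == 0 else J * H + 2 * H + 1
        theta = rng.normal(scale=0.4, size=n_params)
        value, grad = pm._loss_and_grad(theta, X, d, w, J, H, activation, decay=0.02)
        eps = 1e-6
        for k in range(n_params):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += eps
            tm[k] -= eps
            fp, _ = pm._loss_and_grad(tp, X, d, w, J, H, activation, decay=0.02)
            fm, _ = pm._loss_and_grad(tm, X, d, w, J, H, activation, decay=0.02)
            numeric = (fp - fm) / (2 * eps)
            assert grad[k] == pytest.approx(numeric, rel=1e-6, abs=1e-8)

    def test_class_weight_scales_event_row_gradient(self):
        """An event row's gradient contribution scales exactly by the weight."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(1, 3))
        d = np.ones(1)
        theta = rng.normal(scale=0.3, size=3 * 2 + 2 * 2 + 1)
        _, g1 = pm._loss_and_grad(theta, X, d, np.array([1.0]), 3, 2, "tanh")
        _, g2 = pm._loss_and_grad(theta, X, d, np.array([1.05]), 3, 2, "tanh")
        assert np.allclose(g2, 1.05 * g1, rtol=1e-12)


class TestTrainOriginal:
    def test_seed_determinism(self, train_long):
        spec = ps.PlannOriginalSpec(hidden_size=2, decay=0.1, max_iterations=80)
        a = ps.train_plann_original(train_long, spec, np.random.default_rng(3))
        b = ps.train_plann_original(train_long, spec, np.random.default_rng(3))
        assert np.array_equal(a.weights.W1, b.weights.W1)
        assert a.final_loss == b.final_loss

    def test_full_batch_loss_monotone(self, train_long):
        spec = ps.PlannOriginalSpec(hidden_size=2, decay=0.05, max_iterations=150)
        model = ps.train_plann_original(train_long, spec, np.random.default_rng(4))
        diffs = np.diff(model.loss_history)
        assert (diffs <= 1e-8).all()

    def test_no_hidden_layer_matches_irls_logistic(self, train_long):
        """With no hidden layer the fit reproduces logistic regression."""
        import statsmodels.api as sm

        spec = ps.PlannOriginalSpec(hidden_size=0, decay=0.0, max_iterations=4000)
        model = ps.train_plann_original(train_long, spec, np.random.default_rng(5))
        X, _ = pm.build_features(train_long.data, "original", model.scheme,
                                 scaler=model.scaler)
        d = train_long.data["d_target"].to_numpy(dtype=float)
        oracle = sm.Logit(d, sm.add_constant(X)).fit(disp=0)
        fitted = np.concatenate([[model.weights.b2], model.weights.direct])
        assert np.max(np.abs(fitted - oracle.params)) < 1e-3

    def test_low_hazard_interval_learned(self, yearly):
        """With no events in interval 1 the network's hazard there is smallest."""
        rng = np.random.default_rng(6)
        n = 400
        X = ps.sample_covariates(n, ps.default_strata(), rng)
        df = X.copy()
        df.insert(0, "id", range(n))
        # events only in intervals 3-5; censoring spread over intervals 1-8
        is_event = rng.random(n) < 0.5
        df["time"] = np.where(is_event, rng.uniform(2.2, 4.8, n), rng.uniform(0.2, 7.8, n))
        df["event"] = is_event.astype(int)
        df["latent_survival_time"] = df["time"]
        ds = ps.TrialDataset(df)
        long = ps.to_long_train(ds, yearly)
        spec = ps.PlannOriginalSpec(hidden_size=3, decay=0.01, max_iterations=300)
        model = ps.train_plann_original(long, spec, np.random.default_rng(7))
        hazards = ps.predict_hazards(model, ds)
        mean_h = hazards.mean(axis=0)
        assert mean_h[0] == min(mean_h[:5])


class TestTrainExtended:
    def test_plain_gradient_descent_equivalence(self, train_long):
        """dropout=0, momentum=0, full batch: the SGD trajectory equals plain
        gradient descent on the mean weighted cross-entropy."""
        n = train_long.n_rows
        spec = ps.PlannExtendedSpec(
            nodesize=2, dropout_rate=0.0, learning_rate=0.05, momentum=0.0,
            class_weight=1.05, hidden_activation="tanh", epochs=5, batch_size=n,
        )
        model = ps.train_plann_extended(train_long, spec, np.random.default_rng(8))

        # independent plain-GD re-implementation with identical initialization
        X, _ = pm.build_features(train_long.data, "extended", spec.scheme)
        d = train_long.data["d_target"].to_numpy(dtype=float)
        w = np.where(d == 1, 1.05, 1.0)
        J, H = X.shape[1], 2
        rng = np.random.default_rng(8)
        lim1, lim2 = np.sqrt(6 / (J + H)), np.sqrt(6 / (H + 1))
        theta = np.concatenate([
            rng.uniform(-lim1, lim1, J * H), np.zeros(H),
            rng.uniform(-lim2, lim2, H), [0.0],
        ])
        for _ in range(5):
            rng.permutation(n)  # the trainer shuffles once per epoch
            _, grad = pm._loss_and_grad(theta, X, d, w, J, H, "tanh", normalize=True)
            theta = theta - 0.05 * grad
        fitted = pm._pack(model.weights)
        assert np.max(np.abs(fitted - theta)) < 1e-10

    @pytest.mark.parametrize("activation", pm.ACTIVATIONS)
    def test_activation_sweep_trains(self, train_long, train_test, activation):
        spec = ps.PlannExtendedSpec(
            nodesize=3, dropout_rate=0.1, learning_rate=0.05, momentum=0.5,
            class_weight=1.05, hidden_activation=activation, epochs=20, batch_size=64,
        )
        model = ps.train_plann_extended(train_long, spec, np.random.default_rng(9))
        h = ps.predict_hazards(model, train_test[1])
        assert np.all((h > 0) & (h < 1))
        assert np.all(np.isfinite(pm._pack(model.weights)))

    def test_seed_determinism_with_dropout(self, train_long, train_test):
        spec = ps.PlannExtendedSpec(epochs=10)
        a = ps.train_plann_extended(train_long, spec, np.random.default_rng(10))
        b = ps.train_plann_extended(train_long, spec, np.random.default_rng(10))
        ha = ps.predict_hazards(a, train_test[1])
        hb = ps.predict_hazards(b, train_test[1])
        assert np.array_equal(ha, hb)


class TestPrediction:
    def test_zero_weight_model_predicts_half(self, yearly, dataset):
        w = pm.NetworkWeights(np.zeros((6, 2)), np.zeros(2), np.zeros(2), 0.0)
        model = pm.PlannModel("original", w, yearly,
                              scaler={"midpoint": (0.0, 1.0), "age": (0.0, 1.0)},
                              hidden_activation="logistic")
        h = ps.predict_hazards(model, dataset)
        assert h.shape == (dataset.n, 8)
        assert np.allclose(h, 0.5)

    def test_identical_covariates_identical_hazards(self, train_long, yearly):
        spec = ps.PlannOriginalSpec(hidden_size=2, decay=0.1, max_iterations=60)
        model = ps.train_plann_original(train_long, spec, np.random.default_rng(11))
        X = ps.sample_covariates(1, ps.default_strata(), np.random.default_rng(1))
        df = pd.concat([X, X], ignore_index=True)
        df.insert(0, "id", [0, 1])
        df["time"], df["event"], df["latent_survival_time"] = [1.0, 2.0], [1, 0], [1.0, 2.0]
        h = ps.predict_hazards(model, ps.TrialDataset(df))
        assert np.array_equal(h[0], h[1])

    def test_save_load_round_trip(self, tmp_path, train_long, train_test):
        spec = ps.PlannOriginalSpec(hidden_size=2, decay=0.1, max_iterations=60)
        model = ps.train_plann_original(train_long, spec, np.random.default_rng(12))
        path = tmp_path / "model.json"
        model.save(path)
        back = pm.PlannModel.load(path)
        assert np.array_equal(
            ps.predict_hazards(model, train_test[1]),
            ps.predict_hazards(back, train_test[1]),
        )


class TestSurvivalCurve:
    def test_product_formula(self, yearly):
        h = np.full((1, 8), 0.5)
        curves = ps.survival_curve(h, yearly)
        assert curves.at(2.0)[0] == pytest.approx(0.25)

    def test_tiny_hazards_give_unit_survival(self, yearly):
        h = np.full((2, 8), 1e-7)
        curves = ps.survival_curve(h, yearly)
        assert curves.at(5.0) == pytest.approx([1.0, 1.0], abs=1e-5)

    def test_boundary_bookkeeping(self, yearly):
        """t0 = 2.5 uses exactly the intervals with upper boundary <= 2.5."""
        rng = np.random.default_rng(13)
        h = rng.uniform(0.1, 0.4, size=(3, 8))
        curves = ps.survival_curve(h, yearly)
        expected = (1 - h[:, 0]) * (1 - h[:, 1])
        assert np.allclose(curves.at(2.5), expected)

    def test_monotone_and_normalized(self, yearly):
        rng = np.random.default_rng(14)
        h = rng.uniform(0.05, 0.6, size=(5, 8))
        curves = ps.survival_curve(h, yearly)
        ts = np.linspace(0, 9, 40)
        S = curves.grid(ts)
        assert np.allclose(S[:, 0], 1.0)
        assert (np.diff(S, axis=1) <= 1e-12).all()
        assert ((S >= 0) & (S <= 1)).all()

    def test_rejects_degenerate_hazards(self, yearly):
        with pytest.raises(InvalidArgumentError):
            ps.survival_curve(np.full((1, 8), 1.0), yearly)


class TestNonlinearPI:
    def _model_with(self, weights, scheme):
        return pm.PlannModel("original", weights, scheme,
                             scaler={"midpoint": (0.0, 1.0), "age": (0.0, 1.0)},
                             hidden_activation="logistic")

    def test_half_hazards_zero_pi(self, yearly, dataset):
        w = pm.NetworkWeights(np.zeros((6, 1)), np.zeros(1), np.zeros(1), 0.0)
        pi = ps.nonlinear_pi(self._model_with(w, yearly), dataset)
        assert np.allclose(pi, 0.0)

    def test_logit_of_logistic_identity(self, yearly, dataset):
        # output bias 1 with zero weights: hazard = f(1), so PI = logit(f(1)) = 1
        w = pm.NetworkWeights(np.zeros((6, 1)), np.zeros(1), np.zeros(1), 1.0)
        pi = ps.nonlinear_pi(self._model_with(w, yearly), dataset)
        assert np.allclose(pi, 1.0, atol=1e-9)

    def test_time_ignoring_model_pi_invariant_to_midpoints(self, dataset):
        """If the time-input weights are zero, the PI does not depend on the
        scheme's midpoint values (only on L through the average)."""
        rng = np.random.default_rng(15)
        W1 = rng.normal(scale=0.4, size=(6, 2))
        W1[0, :] = 0.0  # kill the midpoint input
        w = pm.NetworkWeights(W1, rng.normal(size=2), rng.normal(size=2), 0.1)
        yearly = ps.make_scheme("yearly")
        shifted = ps.IntervalScheme(
            kind="yearly",
            boundaries=yearly.boundaries,
            midpoints=tuple(m + 3.0 for m in yearly.midpoints),
        )
        pi_a = ps.nonlinear_pi(self._model_with(w, yearly), dataset)
        pi_b = ps.nonlinear_pi(self._model_with(w, shifted), dataset)
        assert np.allclose(pi_a, pi_b)
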