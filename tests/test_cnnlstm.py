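"""CNN-LSTM operators, gradients and training behaviour."""

import math

import numpy as np
import pytest

from aircast.cnnlstm import (
    CNNLSTMRegressor,
    ForecastModelSpec,
    LSTMState,
    LSTMWeights,
    conv1d_forward,
    lstm_cell_step,
    max_pool,
)


class TestConv1d:
    def test_identity_kernel_is_relu(self):
        x = np.array([[-1.0], [2.0], [-3.0], [4.0]])
        out = conv1d_forward(x, np.array([[[1.0]]]), np.zeros(1))
        assert np.allclose(out[:, 0], [0.0, 2.0, 0.0, 4.0])

    def test_difference_kernel_on_ramp(self):
        x = np.array([[1.0], [2.0], [3.0], [4.0]])
        k = np.array([[[1.0], [-1.0]]])  # finite difference x_t - x_{t+1}
        pre = conv1d_forward(x, k, np.zeros(1), activation="linear")
        assert np.allclose(pre[:, 0], [-1.0, -1.0, -1.0])
        post = conv1d_forward(x, k, np.zeros(1), activation="relu")
        assert np.allclose(post, 0.0)

    def test_matches_nested_loop_oracle(self, rng):
        B, n, C, F, k = 3, 7, 3, 4, 2
        X = rng.normal(size=(B, n, C))
        W = rng.normal(size=(F, k, C))
        b = rng.normal(size=F)
        got = conv1d_forward(X, W, b, activation="linear")
        expect = np.zeros((B, n - k + 1, F))
        for bi in range(B):
            for t in range(n - k + 1):
                for f in range(F):
                    s = b[f]
                    for d in range(k):
                        for c in range(C):
                            s += X[bi, t + d, c] * W[f, d, c]
                    expect[bi, t, f] = s
        assert np.max(np.abs(got - expect)) < 1e-10

    def test_shape_mismatch_reports_dims(self):
        with pytest.raises(ValueError, match="channel mismatch"):
            conv1d_forward(np.zeros((4, 2)), np.zeros((1, 2, 3)), np.zeros(1))


class TestMaxPool:
    def test_basic_windows(self):
        out = max_pool(np.array([[1.0], [3.0], [2.0], [5.0]]), 2)
        assert np.allclose(out[:, 0], [3.0, 5.0])

    def test_pool_one_is_identity(self, rng):
        x = rng.normal(size=(6, 3))
        assert np.array_equal(max_pool(x, 1), x)

    def test_trailing_partial_window_kept(self):
        out = max_pool(np.array([[1.0], [3.0], [2.0]]), 2)
        assert np.allclose(out[:, 0], [3.0, 2.0])

    def test_max_is_conserved(self, rng):
        x = rng.normal(size=(9, 4))
        assert max_pool(x, 3).max() == x.max()


def _scalar_weights(**kw):
    """cells=1, input dim 1 weights as 1x1 arrays."""
    def arr(v):
        return np.array([[v]])

    def vec(v):
        return np.array([v])

    return LSTMWeights(
        W_xi=arr(kw["W_xi"]), W_hi=arr(kw["W_hi"]), b_i=vec(kw["b_i"]),
        W_xf=arr(kw["W_xf"]), W_hf=arr(kw["W_hf"]), b_f=vec(kw["b_f"]),
        W_xc=arr(kw["W_xc"]), W_hc=arr(kw["W_hc"]), b_c=vec(kw["b_c"]),
        W_xo=arr(kw["W_xo"]), W_ho=arr(kw["W_ho"]), b_o=vec(kw["b_o"]),
        w_co=vec(kw["w_co"]),
    )


class TestLSTMCell:
    def test_zero_weights_zero_state(self):
        w = _scalar_weights(
            W_xi=0, W_hi=0, b_i=0, W_xf=0, W_hf=0, b_f=0,
            W_xc=0, W_hc=0, b_c=0, W_xo=0, W_ho=0, b_o=0, w_co=0,
        )
        state, h = lstm_cell_step(np.array([1.7]), LSTMState.zeros(1), w)
        assert np.allclose(state.c, 0.0)
        assert np.allclose(h, 0.0)  # o = 0.5 but tanh(c)=0

    def test_scalar_hand_computation(self):
        # independent scalar evaluation of the gate equations
        p = dict(
            W_xi=0.3, W_hi=-0.2, b_i=0.1, W_xf=0.5, W_hf=0.4, b_f=-0.3,
            W_xc=0.7, W_hc=0.2, b_c=0.05, W_xo=-0.6, W_ho=0.3, b_o=0.2, w_co=0.15,
        )
        x, h_prev, c_prev = 0.8, 0.4, -0.25
        sig = lambda z: 1.0 / (1.0 + math.exp(-z))
        i = sig(p["W_hi"] * h_prev + p["W_xi"] * x + p["b_i"])
        f = sig(p["W_hf"] * h_prev + p["W_xf"] * x + p["b_f"])
        g = math.tanh(p["W_xc"] * x + p["W_hc"] * h_prev + p["b_c"])
        c = f * c_prev + i * g
        o = sig(p["W_xo"] * x + p["W_ho"] * h_prev + p["w_co"] * c + p["b_o"])
        h = o * math.tanh(c)

        state = LSTMState(np.array([c_prev]), np.array([h_prev]))
        new_state, h_got = lstm_cell_step(np.array([x]), state, _scalar_weights(**p))
        assert abs(new_state.c[0] - c) < 1e-12
        assert abs(h_got[0] - h) < 1e-12

    def test_hidden_state_tanh_bounded(self, rng):
        H, F = 6, 4
        w = LSTMWeights.from_stacked(
            rng.normal(size=(4 * H, F)) * 3,
            rng.normal(size=(4 * H, H)) * 3,
            rng.normal(size=4 * H),
            rng.normal(size=H),
        )
        state = LSTMState.zeros(H)
        for _ in range(10):
            state, h = lstm_cell_step(rng.normal(size=F) * 5, state, w)
        assert (np.abs(h) < 1.0).all()

    def test_input_dimension_mismatch_rejected(self):
        w = LSTMWeights.from_stacked(
            np.zeros((8, 3)), np.zeros((8, 2)), np.zeros(8), np.zeros(2)
        )
        with pytest.raises(ValueError, match="dimension mismatch"):
            lstm_cell_step(np.zeros(5), LSTMState.zeros(2), w)


class TestAssembledNetwork:
    def test_forward_equals_operator_composition(self, rng):
        spec = ForecastModelSpec(window=8, cells=5, conv_filters=3, kernel_size=2, seed=11)
        model = CNNLSTMRegressor(spec, n_channels=4)
        X = rng.normal(size=(6, 8, 4))
        p = model.params
        w = model.lstm_weights()
        expect = np.empty(6)
        for b in range(6):
            a1 = conv1d_forward(X[b], p["conv_W"], p["conv_b"])
            pooled = max_pool(a1, spec.effective_pool)
            state = LSTMState.zeros(spec.cells)
            for u in range(pooled.shape[0]):
                state, h = lstm_cell_step(pooled[u], state, w)
            expect[b] = h @ p["W_out"] + p["b_out"][0]
        got = model.predict(X)
        assert np.max(np.abs(got - expect)) < 1e-8

    def test_analytic_gradients_match_numerical(self, rng):
        spec = ForecastModelSpec(window=6, cells=4, conv_filters=3, kernel_size=2, seed=3)
        model = CNNLSTMRegressor(spec, n_channels=2)
        X = rng.normal(size=(5, 6, 2))
        y = rng.normal(size=5)
        _, grads = model._loss_and_grads(X, y)
        eps = 1e-6
        for name, p in model.params.items():
            flat = p.reshape(-1)
            for k in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[k]
                flat[k] = orig + eps
                lp, _ = model._loss_and_grads(X, y)
                flat[k] = orig - eps
                lm, _ = model._loss_and_grads(X, y)
                flat[k] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name].reshape(-1)[k]
                assert abs(num - ana) < 1e-4 * max(1.0, abs(num)), name

    def test_predict_is_deterministic_and_batch_consistent(self, rng):
        spec = ForecastModelSpec(window=4, cells=3, seed=5)
        model = CNNLSTMRegressor(spec, n_channels=2)
        X = rng.normal(size=(7, 4, 2))
        a, b = model.predict(X), model.predict(X)
        assert np.array_equal(a, b)
        singles = np.array([model.predict(X[i][None])[0] for i in range(7)])
        assert np.allclose(singles, a, atol=1e-12)

    def test_channel_mismatch_rejected(self, rng):
        model = CNNLSTMRegressor(ForecastModelSpec(window=4, cells=3), n_channels=2)
        with pytest.raises(ValueError, match="channel mismatch"):
            model.predict(rng.normal(size=(3, 4, 5)))


class TestTraining:
    def test_constant_target_learned(self, rng):
        X = np.full((64, 3, 1), 0.5)
        y = np.full(64, 0.5)
        spec = ForecastModelSpec(window=3, cells=8, epochs=60, seed=0)
        model = CNNLSTMRegressor(spec, 1)
        model.fit(X, y)
        assert np.max(np.abs(model.predict(X) - 0.5)) < 1e-2

    def test_sinusoid_component_learned(self):
        from aircast.pipeline import make_windows

        t = np.arange(600)
        comp = np.sin(2 * np.pi * t / 50.0)
        sw = make_windows(comp, None, n=4, fit_rows=500)
        train = sw.rows(np.arange(4, 500))
        test = sw.rows(np.arange(500, 600))
        spec = ForecastModelSpec(window=4, cells=32, epochs=60, seed=0)
        model = CNNLSTMRegressor(spec, 1)
        model.fit(sw.X[train], sw.y[train])
        pred = sw.inverse_scale_y(model.predict(sw.X[test]))
        rmse = float(np.sqrt(np.mean((pred - comp[500:600]) ** 2)))
        assert rmse < 0.1  # < 10% of the unit amplitude

    def test_loss_decreases_and_is_reproducible(self, rng):
        X = rng.normal(size=(128, 4, 2))
        y = X[:, -1, 0] * 0.5 + 0.1
        spec = ForecastModelSpec(window=4, cells=8, epochs=20, seed=2)
        h1 = CNNLSTMRegressor(spec, 2).fit(X, y)
        h2 = CNNLSTMRegressor(spec, 2).fit(X, y)
        assert h1["train"][-1] <= h1["train"][0]
        assert h1["train"] == h2["train"]

    def test_nan_loss_aborts_with_diagnostic(self):
        X = np.full((16, 2, 1), 1e200)
        y = np.full(16, 1e200)  # squared error overflows to inf
        spec = ForecastModelSpec(window=2, cells=2, epochs=2, learning_rate=1e-3, seed=0)
        with pytest.raises(RuntimeError, match="learning rate"):
            CNNLSTMRegressor(spec, 1).fit(X, y)

    def test_save_load_round_trip(self, rng, tmp_path):
        spec = ForecastModelSpec(window=3, cells=4, epochs=2, seed=1)
        model = CNNLSTMRegressor(spec, 2)
        X = rng.normal(size=(20, 3, 2))
        model.fit(X, rng.normal(size=20))
        model.save(tmp_path / "m")
        clone = CNNLSTMRegressor.load(tmp_path / "m")
        assert np.allclose(clone.predict(X), model.predict(X), atol=1e-12)
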