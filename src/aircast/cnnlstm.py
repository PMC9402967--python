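"""Component forecaster: 1-D convolution + pooling feeding an LSTM.

The network predicts the next value of one series from a multichannel
window of the previous ``window`` days:

    input (window x channels)
      -> 1-D valid convolution, ReLU         (feature extraction)
      -> non-overlapping max pooling          (compression / screening)
      -> LSTM over the pooled feature steps   (temporal dynamics)
      -> linear head on the last hidden state (one-step-ahead value)

Gate equations (sigmoid = s):

    i_t = s(W_hi h_{t-1} + W_xi x_t + b_i)
    f_t = s(W_hf h_{t-1} + W_xf x_t + b_f)
    c_t = f_t * c_{t-1} + i_t * tanh(W_xc x_t + W_hc h_{t-1} + b_c)
    o_t = s(W_xo x_t + W_ho h_{t-1} + w_co * c_t + b_o)
    h_t = o_t * tanh(c_t)

(w_co is a diagonal peephole from the freshly updated cell state into the
output gate.)  Everything is plain NumPy with hand-derived gradients and an
Adam optimiser, so seeded training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit as _sigmoid


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForecastModelSpec:
    """Tunable hyperparameters plus fixed architecture settings.

    ``window`` (the time step n, 1-20 days) and ``cells`` (LSTM hidden
    units, 1-100) are the two searched hyperparameters; the rest are fixed
    architecture/training settings.  The convolution kernel is shrunk to
    the window length when ``window < kernel_size`` so one-day windows
    remain valid; pooling uses size 2 when the convolution output has at
    least 4 steps, else 1.
    """

    window: int = 2
    cells: int = 32
    conv_filters: int = 16
    kernel_size: int = 2
    pool_size: int | None = None  # None = auto (2 if conv output >= 4 steps)
    epochs: int = 60
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.window <= 20:
            raise ValueError("window must be in [1, 20]")
        if not 1 <= self.cells <= 100:
            raise ValueError("cells must be in [1, 100]")
        if self.conv_filters < 1 or self.kernel_size < 1:
            raise ValueError("conv_filters and kernel_size must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def effective_kernel(self) -> int:
        return min(self.kernel_size, self.window)

    @property
    def conv_steps(self) -> int:
        return self.window - self.effective_kernel + 1

    @property
    def effective_pool(self) -> int:
        if self.pool_size is not None:
            if self.pool_size < 1:
                raise ValueError("pool_size must be >= 1")
            return min(self.pool_size, self.conv_steps)
        return 2 if self.conv_steps >= 4 else 1

    @property
    def lstm_steps(self) -> int:
        p = self.effective_pool
        return -(-self.conv_steps // p)  # ceil: trailing partial window kept


# ---------------------------------------------------------------------------
# elementary operators (unit-testable contracts)
# ---------------------------------------------------------------------------

def conv1d_forward(
    window: np.ndarray,
    kernels: np.ndarray,
    biases: np.ndarray,
    activation: str = "relu",
) -> np.ndarray:
    """Valid (no padding) 1-D cross-correlation over the time axis.

    ``window`` is (n, channels) or (batch, n, channels); ``kernels`` is
    (filters, k, channels); output is (..., n-k+1, filters) after the
    activation (``"relu"`` or ``"linear"``).
    """
    x = np.asarray(window, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    k = np.asarray(kernels, dtype=float)
    b = np.asarray(biases, dtype=float)
    if x.ndim != 3 or k.ndim != 3:
        raise ValueError("window must be (batch, n, channels), kernels (filters, k, channels)")
    if k.shape[2] != x.shape[2]:
        raise ValueError(f"channel mismatch: window has {x.shape[2]}, kernels expect {k.shape[2]}")
    if k.shape[1] > x.shape[1]:
        raise ValueError(f"kernel size {k.shape[1]} exceeds window length {x.shape[1]}")
    if b.shape != (k.shape[0],):
        raise ValueError(f"biases must have shape ({k.shape[0]},), got {b.shape}")
    win = np.lib.stride_tricks.sliding_window_view(x, k.shape[1], axis=1)  # (B, L, C, k)
    z = np.einsum("blck,fkc->blf", win, k) + b
    if activation == "relu":
        z = np.maximum(z, 0.0)
    elif activation != "linear":
        raise ValueError(f"unknown activation {activation!r}")
    return z[0] if squeeze else z


def max_pool(feature_map: np.ndarray, pool_size: int) -> np.ndarray:
    """Non-overlapping maxima along the time axis; a trailing partial
    window is pooled as-is."""
    pooled, _ = _max_pool_argmax(np.asarray(feature_map, dtype=float), pool_size)
    return pooled


def _max_pool_argmax(x: np.ndarray, pool_size: int) -> tuple[np.ndarray, np.ndarray]:
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    b_dim, length, f_dim = x.shape
    n_out = -(-length // pool_size)
    pooled = np.empty((b_dim, n_out, f_dim))
    argmax = np.empty((b_dim, n_out, f_dim), dtype=int)
    for u in range(n_out):
        seg = x[:, u * pool_size: (u + 1) * pool_size]
        idx = seg.argmax(axis=1)
        argmax[:, u] = idx + u * pool_size
        pooled[:, u] = np.take_along_axis(seg, idx[:, None], axis=1)[:, 0]
    if squeeze:
        return pooled[0], argmax[0]
    return pooled, argmax


@dataclass
class LSTMState:
    """Cell and hidden state; shapes (..., cells)."""

    c: np.ndarray
    h: np.ndarray

    @classmethod
    def zeros(cls, cells: int, batch: int | None = None) -> "LSTMState":
        shape = (cells,) if batch is None else (batch, cells)
        return cls(np.zeros(shape), np.zeros(shape))


@dataclass
class LSTMWeights:
    """Per-gate weights in the contract's naming; shapes (cells, in) for
    W_x*, (cells, cells) for W_h*, (cells,) for biases and the peephole."""

    W_xi: np.ndarray
    W_hi: np.ndarray
    b_i: np.ndarray
    W_xf: np.ndarray
    W_hf: np.ndarray
    b_f: np.ndarray
    W_xc: np.ndarray
    W_hc: np.ndarray
    b_c: np.ndarray
    W_xo: np.ndarray
    W_ho: np.ndarray
    b_o: np.ndarray
    w_co: np.ndarray

    @classmethod
    def from_stacked(cls, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray, w_co: np.ndarray) -> "LSTMWeights":
        h = Wh.shape[1]
        parts_x = [Wx[i * h:(i + 1) * h] for i in range(4)]
        parts_h = [Wh[i * h:(i + 1) * h] for i in range(4)]
        parts_b = [b[i * h:(i + 1) * h] for i in range(4)]
        return cls(
            parts_x[0], parts_h[0], parts_b[0],
            parts_x[1], parts_h[1], parts_b[1],
            parts_x[2], parts_h[2], parts_b[2],
            parts_x[3], parts_h[3], parts_b[3],
            w_co,
        )


def lstm_cell_step(
    x_t: np.ndarray,
    state: LSTMState,
    weights: LSTMWeights,
) -> tuple[LSTMState, np.ndarray]:
    """One gate update; returns the new state and the hidden output h_t."""
    x = np.asarray(x_t, dtype=float)
    w = weights
    if w.W_xi.shape[1] != x.shape[-1]:
        raise ValueError(
            f"input dimension mismatch: expected {w.W_xi.shape[1]}, got {x.shape[-1]}"
        )
    h_prev, c_prev = state.h, state.c
    i = _sigmoid(x @ w.W_xi.T + h_prev @ w.W_hi.T + w.b_i)
    f = _sigmoid(x @ w.W_xf.T + h_prev @ w.W_hf.T + w.b_f)
    g = np.tanh(x @ w.W_xc.T + h_prev @ w.W_hc.T + w.b_c)
    c = f * c_prev + i * g
    o = _sigmoid(x @ w.W_xo.T + h_prev @ w.W_ho.T + w.w_co * c + w.b_o)
    h = o * np.tanh(c)
    return LSTMState(c, h), h


# ---------------------------------------------------------------------------
# assembled network
# ---------------------------------------------------------------------------

class CNNLSTMRegressor:
    """Conv -> pool -> LSTM -> linear head, trained with Adam on MSE.

    Parameters
    ----------
    spec
        Hyperparameters and training settings.
    n_channels
        Input channels per time step (target component plus covariates).
    """

    def __init__(self, spec: ForecastModelSpec, n_channels: int):
        self.spec = spec
        self.n_channels = int(n_channels)
        rng = np.random.default_rng(spec.seed)
        k, F, H = spec.effective_kernel, spec.conv_filters, spec.cells

        def glorot(*shape):
            fan_in, fan_out = shape[-1], shape[0]
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        self.params: dict[str, np.ndarray] = {
            "conv_W": glorot(F, k, self.n_channels) / np.sqrt(k),
            "conv_b": np.zeros(F),
            "Wx": np.concatenate([glorot(H, F) for _ in range(4)], axis=0),
            "Wh": np.concatenate([glorot(H, H) for _ in range(4)], axis=0),
            "b": np.zeros(4 * H),
            "w_co": np.zeros(H),
            "W_out": glorot(1, H)[0],
            "b_out": np.zeros(1),
        }
        # forget-gate bias starts at 1 so early training retains memory
        self.params["b"][H:2 * H] = 1.0
        self._adam_m = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_v = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_t = 0
        self.history: dict[str, list[float]] = {"train": [], "val": []}
        self._rng = rng

    # -- forward ---------------------------------------------------------

    def lstm_weights(self) -> LSTMWeights:
        p = self.params
        return LSTMWeights.from_stacked(p["Wx"], p["Wh"], p["b"], p["w_co"])

    def _forward(self, X: np.ndarray, cache: bool = False):
        p, H = self.params, self.spec.cells
        B = X.shape[0]
        F, k, C = p["conv_W"].shape
        win = np.lib.stride_tricks.sliding_window_view(X, k, axis=1)  # (B, L1, C, k)
        L1 = win.shape[1]
        win2 = np.ascontiguousarray(win).reshape(B, L1, C * k)
        W2 = p["conv_W"].transpose(0, 2, 1).reshape(F, C * k)
        Z1 = win2 @ W2.T + p["conv_b"]
        A1 = np.maximum(Z1, 0.0)
        P, argmax = _max_pool_argmax(A1, self.spec.effective_pool)
        L2 = P.shape[1]

        h = np.zeros((B, H))
        c = np.zeros((B, H))
        # input-side gate projections for all steps at once
        Zx = P @ p["Wx"].T + p["b"]
        steps = []
        for u in range(L2):
            Z = Zx[:, u] + h @ p["Wh"].T
            i = _sigmoid(Z[:, :H])
            f = _sigmoid(Z[:, H:2 * H])
            g = np.tanh(Z[:, 2 * H:3 * H])
            c_new = f * c + i * g
            o = _sigmoid(Z[:, 3 * H:] + p["w_co"] * c_new)
            h_new = o * np.tanh(c_new)
            if cache:
                steps.append((h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
        pred = h @ p["W_out"] + p["b_out"][0]
        if not cache:
            return pred
        return pred, (win2, Z1, argmax, A1.shape, P, steps, h)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """One prediction per window row; deterministic."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.shape[2] != self.n_channels:
            raise ValueError(
                f"window channel mismatch: model expects {self.n_channels}, got {X.shape[2]}"
            )
        if X.shape[1] != self.spec.window:
            raise ValueError(
                f"window length mismatch: model expects {self.spec.window}, got {X.shape[1]}"
            )
        return self._forward(X)

    # -- backward --------------------------------------------------------

    def _loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        p, H = self.params, self.spec.cells
        B = X.shape[0]
        pred, (win2, Z1, argmax, a1_shape, P, steps, h_last) = self._forward(X, cache=True)
        err = pred - y
        loss = float(np.mean(err ** 2))

        g: dict[str, np.ndarray] = {k_: np.zeros_like(v) for k_, v in p.items()}
        dpred = 2.0 * err / B
        g["W_out"] = h_last.T @ dpred
        g["b_out"] = np.array([dpred.sum()])
        dh = np.outer(dpred, p["W_out"])
        dc = np.zeros_like(dh)
        L2 = len(steps)
        dZ_all = np.empty((B, L2, 4 * H))

        Wx, Wh, w_co = p["Wx"], p["Wh"], p["w_co"]
        for u in range(L2 - 1, -1, -1):
            h_prev, c_prev, i, f, gg, o, c = steps[u]
            tc = np.tanh(c)
            do = dh * tc
            dzo = do * o * (1.0 - o)
            dc = dc + dh * o * (1.0 - tc ** 2) + dzo * w_co
            g["w_co"] += (dzo * c).sum(axis=0)
            dZ = dZ_all[:, u]
            dZ[:, :H] = dc * gg * i * (1.0 - i)
            dZ[:, H:2 * H] = dc * c_prev * f * (1.0 - f)
            dZ[:, 2 * H:3 * H] = dc * i * (1.0 - gg ** 2)
            dZ[:, 3 * H:] = dzo
            g["Wh"] += dZ.T @ h_prev
            dh = dZ @ Wh
            dc = dc * f
        g["Wx"] = np.einsum("buk,buf->kf", dZ_all, P)
        g["b"] = dZ_all.sum(axis=(0, 1))
        dP = dZ_all @ Wx

        # unpool: route gradients to the argmax positions
        dA1 = np.zeros(a1_shape)
        bi = np.arange(B)[:, None, None]
        fi = np.arange(a1_shape[2])[None, None, :]
        np.add.at(dA1, (bi, argmax, fi), dP)
        dZ1 = dA1 * (Z1 > 0.0)
        F, k, C = p["conv_W"].shape
        gW2 = dZ1.reshape(-1, F).T @ win2.reshape(-1, C * k)  # (F, C*k)
        g["conv_W"] = gW2.reshape(F, C, k).transpose(0, 2, 1)
        g["conv_b"] = dZ1.sum(axis=(0, 1))
        return loss, g

    def _adam_step(self, grads: dict[str, np.ndarray], lr: float,
                   beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k_, gr in grads.items():
            m = self._adam_m[k_] = beta1 * self._adam_m[k_] + (1 - beta1) * gr
            v = self._adam_v[k_] = beta2 * self._adam_v[k_] + (1 - beta2) * gr ** 2
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            self.params[k_] -= lr * mhat / (np.sqrt(vhat) + eps)

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> dict[str, list[float]]:
        """Minimise MSE with Adam; returns per-epoch loss history.

        Reproducible under a fixed spec seed (data order, init and updates
        are all driven by the same generator).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        if len(X) < 1:
            raise ValueError("no training samples")
        spec = self.spec
        n = len(X)
        bs = min(spec.batch_size, n)
        for epoch in range(spec.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                loss, grads = self._loss_and_grads(X[idx], y[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"NaN/inf training loss at epoch {epoch}; "
                        "try a smaller learning rate"
                    )
                self._adam_step(grads, spec.learning_rate)
                epoch_loss += loss * len(idx)
            self.history["train"].append(epoch_loss / n)
            if X_val is not None and len(X_val):
                v_err = self._forward(np.asarray(X_val, dtype=float)) - y_val
                self.history["val"].append(float(np.mean(v_err ** 2)))
        return self.history

    # -- persistence -----------------------------------------------------

    def save(self, directory) -> None:
        """Write spec JSON + one .npy per weight array into *directory*."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {"spec": asdict(self.spec), "n_channels": self.n_channels}
        (d / "model.json").write_text(json.dumps(meta, indent=2))
        for k_, v in self.params.items():
            np.save(d / f"{k_}.npy", v)

    @classmethod
    def load(cls, directory) -> "CNNLSTMRegressor":
        import json
        from pathlib import Path

        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        spec = ForecastModelSpec(**meta["spec"])
        model = cls(spec, meta["n_channels"])
        for k_ in model.params:
            model.params[k_] = np.load(d / f"{k_}.npy")
        return model


def train(
    spec: ForecastModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    n_channels: int | None = None,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> tuple[CNNLSTMRegressor, dict[str, list[float]]]:
    """Convenience wrapper: build a seeded model, fit, return it + history."""
    channels = n_channels if n_channels is not None else np.asarray(X).shape[2]
    model = CNNLSTMRegressor(spec, channels)
    history = model.fit(X, y, X_val, y_val)
    return model, history
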