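"""Minimal recurrent-network machinery: an LSTM layer with full
backpropagation-through-time, dense feed-forward layers, mean-squared-error
loss and an RMSprop optimizer — all in numpy, fully deterministic given a
seed.

The two motion networks share one architecture family: an LSTM over the
input window followed by a stack of dense layers.  The follow-net reads the
hidden state of the last time step; the lead-net applies the readout at every
time step (sequence-to-sequence).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Dense", "LSTM", "RecurrentRegressor", "RMSProp", "fit"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Dense:
    """Affine layer with optional tanh/relu nonlinearity."""

    def __init__(self, d_in: int, d_out: int, activation: str, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.W = rng.uniform(-limit, limit, size=(d_in, d_out))
        self.b = np.zeros(d_out)
        if activation not in ("linear", "tanh", "relu"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "tanh":
            z = np.tanh(z)
        elif self.activation == "relu":
            z = np.maximum(z, 0.0)
        self._out = z
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.activation == "tanh":
            dout = dout * (1.0 - self._out**2)
        elif self.activation == "relu":
            dout = dout * (self._out > 0)
        self.dW += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class LSTM:
    """Single-layer LSTM; gate order i, f, g, o; forget-gate bias starts at 1."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (d_in + 4 * hidden))
        self.Wx = rng.uniform(-limit, limit, size=(d_in, 4 * hidden))
        limit = np.sqrt(6.0 / (hidden + 4 * hidden))
        self.Wh = rng.uniform(-limit, limit, size=(hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0
        self.hidden = hidden
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, T, D) -> hidden states (B, T, H)."""
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        hs = np.empty((B, T, H))
        for t in range(T):
            z = x[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            ct = np.tanh(c_new)
            h_new = o * ct
            self._cache.append((x[:, t, :], h, c, i, f, g, o, c_new, ct))
            h, c = h_new, c_new
            hs[:, t, :] = h
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        """dhs: (B, T, H) upstream gradient on every hidden state."""
        B, T, H = dhs.shape
        dx = np.empty((B, T, self.Wx.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c_new, ct = self._cache[t]
            dh = dhs[:, t, :] + dh_next
            do = dh * ct
            dc = dc_next + dh * o * (1.0 - ct**2)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.dWx += x_t.T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
        return dx

    def params(self):
        return [(self.Wx, self.dWx), (self.Wh, self.dWh), (self.b, self.db)]


class RecurrentRegressor:
    """LSTM followed by a dense stack; last-step or per-step readout.

    ``return_sequences=False`` reads out only the final hidden state
    (window-to-next-frame, the follow-net shape); ``True`` applies the same
    readout to every time step (chunk-to-chunk, the lead-net shape).
    """

    def __init__(
        self,
        d_in: int,
        hidden: int,
        dense_widths: tuple[int, ...],
        d_out: int,
        return_sequences: bool,
        seed: int,
    ):
        rng = np.random.default_rng(seed)
        self.config = {
            "d_in": d_in,
            "hidden": hidden,
            "dense_widths": list(dense_widths),
            "d_out": d_out,
            "return_sequences": return_sequences,
            "seed": seed,
        }
        self.lstm = LSTM(d_in, hidden, rng)
        widths = [hidden, *dense_widths, d_out]
        self.dense = [
            Dense(widths[k], widths[k + 1], "relu" if k < len(widths) - 2 else "linear", rng)
            for k in range(len(widths) - 1)
        ]
        self.return_sequences = return_sequences

    def forward(self, x: np.ndarray) -> np.ndarray:
        hs = self.lstm.forward(x)
        if self.return_sequences:
            B, T, H = hs.shape
            out = hs.reshape(B * T, H)
            for layer in self.dense:
                out = layer.forward(out)
            return out.reshape(B, T, -1)
        out = hs[:, -1, :]
        for layer in self.dense:
            out = layer.forward(out)
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(x, dtype=float))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.return_sequences:
            B, T, _ = dout.shape
            d = dout.reshape(B * T, -1)
            for layer in reversed(self.dense):
                d = layer.backward(d)
            dhs = d.reshape(B, T, -1)
        else:
            d = dout
            for layer in reversed(self.dense):
                d = layer.backward(d)
            B, H = d.shape
            T = len(self.lstm._cache)
            dhs = np.zeros((B, T, H))
            dhs[:, -1, :] = d
        return self.lstm.backward(dhs)

    def params(self):
        out = self.lstm.params()
        for layer in self.dense:
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {f"p{k}": p for k, (p, _) in enumerate(self.params())}
        np.savez(Path(path), config=json.dumps(self.config), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "RecurrentRegressor":
        data = np.load(Path(path), allow_pickle=False)
        cfg = json.loads(str(data["config"]))
        model = cls(
            cfg["d_in"],
            cfg["hidden"],
            tuple(cfg["dense_widths"]),
            cfg["d_out"],
            cfg["return_sequences"],
            cfg["seed"],
        )
        for k, (p, _) in enumerate(model.params()):
            p[...] = data[f"p{k}"]
        return model


class RMSProp:
    """RMSprop with the standard decay-0.9 running mean of squared gradients."""

    def __init__(self, lr: float = 1e-3, decay: float = 0.9, eps: float = 1e-8):
        self.lr = lr
        self.decay = decay
        self.eps = eps
        self._cache: list[np.ndarray] | None = None

    def step(self, params) -> None:
        if self._cache is None:
            self._cache = [np.zeros_like(p) for p, _ in params]
        for cache, (p, g) in zip(self._cache, params):
            cache *= self.decay
            cache += (1.0 - self.decay) * g**2
            p -= self.lr * g / (np.sqrt(cache) + self.eps)


@dataclass
class FitResult:
    losses: list[float]  # mean MSE per epoch


def fit(
    model: RecurrentRegressor,
    X: np.ndarray,
    Y: np.ndarray,
    epochs: int,
    lr: float = 1e-3,
    batch_size: int = 64,
    seed: int = 0,
    input_noise_sd: float = 0.0,
    clip_norm: float = 5.0,
) -> FitResult:
    """Mini-batch RMSprop training on mean squared error.

    ``input_noise_sd`` adds Gaussian noise to the inputs during training
    only (the lead-net's regularization); evaluation always sees clean
    inputs.  Deterministic given *seed*.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if len(X) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    opt = RMSProp(lr=lr)
    losses = []
    n = len(X)
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb = X[idx]
            if input_noise_sd > 0:
                xb = xb + rng.normal(0.0, input_noise_sd, size=xb.shape)
            yb = Y[idx]
            model.zero_grad()
            pred = model.forward(xb)
            diff = pred - yb
            epoch_loss += float(np.sum(diff**2))
            dloss = 2.0 * diff / diff.size
            model.backward(dloss)
            params = model.params()
            total = np.sqrt(sum(float(np.sum(g**2)) for _, g in params))
            if clip_norm and total > clip_norm:
                scale = clip_norm / total
                for _, g in params:
                    g *= scale
            opt.step(params)
        losses.append(epoch_loss / (n * int(np.prod(Y.shape[1:]))))
    return FitResult(losses=losses)
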