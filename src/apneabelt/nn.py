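"""Minimal numpy LSTM for per-minute binary sequence classification.

Stacked LSTM layers feed a fully connected head (ReLU hidden layers, one
sigmoid output) that reads the last-timestep hidden state of the top layer.
Training is full backpropagation through time with Adam and global-norm
gradient clipping; the loss is the numerically stable logit form of binary
cross-entropy. Pure numpy keeps training bit-reproducible for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["LSTMClassifier", "save_model", "load_model"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


@dataclass
class _LSTMLayer:
    W: np.ndarray   # (in+hidden, 4*hidden), gate order i, f, g, o
    b: np.ndarray   # (4*hidden,)

    @property
    def hidden(self) -> int:
        return self.b.size // 4

    def forward(self, x: np.ndarray):
        """x: (B, T, D) -> h sequence (B, T, H) plus caches for BPTT."""
        B, T, D = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        caches = []
        for t in range(T):
            xt = x[:, t, :]
            z = np.concatenate([xt, h], axis=1) @ self.W + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            caches.append((xt, h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, t, :] = h
        return hs, caches

    def backward(self, caches, dhs: np.ndarray):
        """dhs: (B, T, H) gradient on the output sequence. Returns gradient
        on the input sequence plus parameter gradients."""
        B, T, H = dhs.shape
        D = self.W.shape[0] - H
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        dx = np.empty((B, T, D))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tc = caches[t]
            dh = dhs[:, t, :] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=1)
            inp = np.concatenate([xt, h_prev], axis=1)
            dW += inp.T @ dz
            db += dz.sum(axis=0)
            dinp = dz @ self.W.T
            dx[:, t, :] = dinp[:, :D]
            dh_next = dinp[:, D:]
            dc_next = dc * f
        return dx, dW, db


class LSTMClassifier:
    """Stacked-LSTM binary classifier over fixed-length multichannel
    sequences, with a dense ReLU head ending in one sigmoid unit."""

    def __init__(self, n_channels: int, num_lstm_layers: int = 3,
                 lstm_hidden: int = 64,
                 dense_sizes: tuple[int, ...] = (128, 64, 32, 1),
                 seed: int = 0):
        if dense_sizes[-1] != 1:
            raise ValueError("final dense layer must have one unit")
        rng = np.random.default_rng(seed)
        self.n_channels = n_channels
        self.lstm_hidden = lstm_hidden
        self.dense_sizes = tuple(dense_sizes)
        self.layers: list[_LSTMLayer] = []
        d = n_channels
        for _ in range(num_lstm_layers):
            scale = 1.0 / np.sqrt(d + lstm_hidden)
            W = rng.uniform(-scale, scale, size=(d + lstm_hidden, 4 * lstm_hidden))
            b = np.zeros(4 * lstm_hidden)
            b[lstm_hidden:2 * lstm_hidden] = 1.0  # forget-gate bias
            self.layers.append(_LSTMLayer(W=W, b=b))
            d = lstm_hidden
        self.dense: list[tuple[np.ndarray, np.ndarray]] = []
        for size in dense_sizes:
            scale = np.sqrt(2.0 / d)
            self.dense.append((rng.normal(0.0, scale, size=(d, size)),
                               np.zeros(size)))
            d = size
        self._adam_state = None
        self._rng = rng

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray):
        hs = X
        lstm_caches = []
        for layer in self.layers:
            hs, caches = layer.forward(hs)
            lstm_caches.append(caches)
        a = hs[:, -1, :]
        dense_caches = []
        for k, (W, b) in enumerate(self.dense):
            z = a @ W + b
            dense_caches.append((a, z))
            a = z if k == len(self.dense) - 1 else np.maximum(z, 0.0)
        logits = a[:, 0]
        return logits, lstm_caches, dense_caches

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid probabilities for X of shape (B, T, n_channels)."""
        X = self._check_shape(X)
        logits, _, _ = self._forward(X)
        return _sigmoid(logits)

    def _check_shape(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != self.n_channels:
            raise ValueError(
                f"expected input of shape (batch, T, {self.n_channels}), "
                f"got {X.shape}")
        return X

    def _loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        B = X.shape[0]
        logits, lstm_caches, dense_caches = self._forward(X)
        loss = float(np.mean(_softplus(logits) - y * logits))
        dlogit = (_sigmoid(logits) - y) / B

        grads_dense = []
        da = dlogit[:, None]
        for k in range(len(self.dense) - 1, -1, -1):
            W, _ = self.dense[k]
            a_in, z = dense_caches[k]
            dz = da if k == len(self.dense) - 1 else da * (z > 0)
            grads_dense.append((a_in.T @ dz, dz.sum(axis=0)))
            da = dz @ W.T
        grads_dense.reverse()

        T = X.shape[1]
        dhs = np.zeros((B, T, self.lstm_hidden))
        dhs[:, -1, :] = da
        grads_lstm = []
        for layer, caches in zip(reversed(self.layers), reversed(lstm_caches)):
            dhs, dW, db = layer.backward(caches, dhs)
            grads_lstm.append((dW, db))
        grads_lstm.reverse()
        return loss, grads_lstm, grads_dense

    # -- optimisation -------------------------------------------------------

    def _params(self):
        for layer in self.layers:
            yield layer.W
            yield layer.b
        for W, b in self.dense:
            yield W
            yield b

    def _apply_adam(self, grads: list[np.ndarray], lr: float,
                    beta1=0.9, beta2=0.999, eps=1e-8, clip=5.0) -> None:
        norm = np.sqrt(sum(float(np.sum(g ** 2)) for g in grads))
        if clip and norm > clip:
            grads = [g * (clip / norm) for g in grads]
        params = list(self._params())
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": [np.zeros_like(p) for p in params],
                "v": [np.zeros_like(p) for p in params],
            }
        st = self._adam_state
        st["t"] += 1
        t = st["t"]
        for p, g, m, v in zip(params, grads, st["m"], st["v"]):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g ** 2
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def train_step(self, X: np.ndarray, y: np.ndarray, lr: float = 1e-3) -> float:
        loss, grads_lstm, grads_dense = self._loss_and_grads(X, y)
        flat: list[np.ndarray] = []
        for dW, db in grads_lstm:
            flat += [dW, db]
        for dW, db in grads_dense:
            flat += [dW, db]
        self._apply_adam(flat, lr)
        return loss

    def evaluate(self, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """(mean BCE loss, accuracy) without updating parameters."""
        X = self._check_shape(X)
        logits, _, _ = self._forward(X)
        loss = float(np.mean(_softplus(logits) - y * logits))
        acc = float(np.mean((logits >= 0.0).astype(int) == y))
        return loss, acc


def save_model(model: LSTMClassifier, path) -> None:
    arrays = {}
    for k, layer in enumerate(model.layers):
        arrays[f"lstm{k}_W"] = layer.W
        arrays[f"lstm{k}_b"] = layer.b
    for k, (W, b) in enumerate(model.dense):
        arrays[f"dense{k}_W"] = W
        arrays[f"dense{k}_b"] = b
    meta = {
        "n_channels": model.n_channels,
        "num_lstm_layers": len(model.layers),
        "lstm_hidden": model.lstm_hidden,
        "dense_sizes": list(model.dense_sizes),
    }
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> LSTMClassifier:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    model = LSTMClassifier(n_channels=meta["n_channels"],
                           num_lstm_layers=meta["num_lstm_layers"],
                           lstm_hidden=meta["lstm_hidden"],
                           dense_sizes=tuple(meta["dense_sizes"]))
    for k, layer in enumerate(model.layers):
        layer.W = data[f"lstm{k}_W"]
        layer.b = data[f"lstm{k}_b"]
    model.dense = [(data[f"dense{k}_W"], data[f"dense{k}_b"])
                   for k in range(len(model.dense))]
    return model
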