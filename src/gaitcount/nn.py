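"""Minimal 1-D convolutional networks for window-level learning.

A small, dependency-free CNN (conv -> ReLU -> max-pool stacks with a
dense head, trained by Adam on mini-batches with early stopping) sized
for 60-sample windows.  The classifier uses 2 conv + 2 pool layers and
one dense layer; the regressor 4 conv + 4 pool layers and two dense
layers.  Committed defaults: kernel width 5, pool width 2.

The layer gradients are exact (verified against finite differences in
the test suite); the implementation favours clarity over throughput,
which is ample at this input size.
"""

from __future__ import annotations

import copy

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_is_fitted


class _Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(_Layer):
    """Same-padded 1-D convolution, odd kernel width."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel width must be odd for same padding")
        self.kernel = kernel
        scale = np.sqrt(2.0 / (c_in * kernel))  # He init for ReLU stacks
        self.params = {
            "W": rng.normal(0.0, scale, size=(kernel, c_in, c_out)),
            "b": np.zeros(c_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (n, L, c_in)
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        self._win = sliding_window_view(xp, self.kernel, axis=1)  # (n, L, c_in, k)
        return np.einsum("nlck,kco->nlo", self._win, self.params["W"]) + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        k, p = self.kernel, self.kernel // 2
        n, L, _ = dout.shape
        self.grads["b"] = dout.sum(axis=(0, 1))
        self.grads["W"] = np.einsum("nlck,nlo->kco", self._win, dout)
        c_in = W.shape[1]
        dxp = np.zeros((n, L + 2 * p, c_in))
        for kk in range(k):
            dxp[:, kk : kk + L, :] += np.einsum("nlo,co->nlc", dout, W[kk])
        return dxp[:, p : p + L, :]


class ReLU(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool1d(_Layer):
    """Width-2, stride-2 pooling; a trailing odd sample is dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, L, c = x.shape
        L2 = L // 2
        xr = x[:, : 2 * L2].reshape(n, L2, 2, c)
        self._arg = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, L2, c = dout.shape
        dxr = np.zeros((n, L2, 2, c))
        ni, li, ci = np.ogrid[:n, :L2, :c]
        dxr[ni, li, self._arg, ci] = dout
        dx = np.zeros(self._in_shape)
        dx[:, : 2 * L2] = dxr.reshape(n, 2 * L2, c)
        return dx


class Flatten(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params = {"W": rng.normal(0.0, scale, size=(n_in, n_out)), "b": np.zeros(n_out)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class _Adam:
    def __init__(self, layers: list[_Layer], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        for i, layer in enumerate(self.layers):
            for k, g in layer.grads.items():
                self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mhat = self.m[i][k] / (1 - self.b1**self.t)
                vhat = self.v[i][k] / (1 - self.b2**self.t)
                layer.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _forward(layers: list[_Layer], x: np.ndarray) -> np.ndarray:
    for layer in layers:
        x = layer.forward(x)
    return x


def _backward(layers: list[_Layer], dout: np.ndarray) -> None:
    for layer in reversed(layers):
        dout = layer.backward(dout)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _ConvNetBase(BaseEstimator):
    """Shared training loop: Adam, mini-batches, early stopping on a
    validation split with best-weight restoration."""

    def __init__(self, kernel_size=5, epochs=40, batch_size=64, lr=1e-3,
                 val_fraction=0.1, patience=8, random_state=0):
        self.kernel_size = kernel_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.val_fraction = val_fraction
        self.patience = patience
        self.random_state = random_state

    # subclasses define _build(rng, length, n_out), _loss_grad(logits, target)
    # and _val_loss(logits, target)

    def _fit_net(self, X: np.ndarray, target: np.ndarray, n_out: int) -> None:
        X = np.asarray(X, dtype=float)
        n, length = X.shape
        self._mu = float(X.mean())
        self._sigma = float(X.std()) or 1.0
        Xs = ((X - self._mu) / self._sigma)[:, :, None]
        rng = np.random.default_rng(self.random_state)
        self.layers_ = self._build(rng, length, n_out)
        opt = _Adam(self.layers_, lr=self.lr)

        n_val = int(round(self.val_fraction * n))
        n_val = min(max(n_val, 1 if n >= 10 else 0), n - 1) if n > 1 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ttr = Xs[tr_idx], target[tr_idx]
        Xval, tval = Xs[val_idx], target[val_idx]

        best_loss = np.inf
        best_params = None
        stale = 0
        bs = max(1, self.batch_size)
        for _epoch in range(self.epochs):
            order = rng.permutation(len(Xtr))
            for start in range(0, len(Xtr), bs):
                idx = order[start : start + bs]
                logits = _forward(self.layers_, Xtr[idx])
                dout = self._loss_grad(logits, ttr[idx])
                _backward(self.layers_, dout)
                opt.step()
            if n_val:
                vloss = self._val_loss(_forward(self.layers_, Xval), tval)
                if vloss < best_loss - 1e-6:
                    best_loss = vloss
                    best_params = [copy.deepcopy(l.params) for l in self.layers_]
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
        if best_params is not None:
            for layer, params in zip(self.layers_, best_params):
                layer.params = params

    def _net_output(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "layers_")
        X = np.asarray(X, dtype=float)
        Xs = ((X - self._mu) / self._sigma)[:, :, None]
        return _forward(self.layers_, Xs)


class Conv1dClassifier(_ConvNetBase, ClassifierMixin):
    """2 conv + 2 max-pool + 1 dense softmax classifier."""

    def __init__(self, kernel_size=5, epochs=40, batch_size=64, lr=1e-3,
                 val_fraction=0.1, patience=8, random_state=0, channels=(8, 16)):
        super().__init__(kernel_size, epochs, batch_size, lr, val_fraction,
                         patience, random_state)
        self.channels = channels

    def _build(self, rng, length, n_out):
        c1, c2 = self.channels
        layers = [
            Conv1d(1, c1, self.kernel_size, rng), ReLU(), MaxPool1d(),
            Conv1d(c1, c2, self.kernel_size, rng), ReLU(), MaxPool1d(),
            Flatten(),
        ]
        flat = (length // 2 // 2) * c2
        layers.append(Dense(flat, n_out, rng))
        return layers

    def _loss_grad(self, logits, y_idx):
        p = _softmax(logits)
        p[np.arange(len(y_idx)), y_idx] -= 1.0
        return p / len(y_idx)

    def _val_loss(self, logits, y_idx):
        p = _softmax(logits)
        return float(-np.log(p[np.arange(len(y_idx)), y_idx] + 1e-12).mean())

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self._fit_net(np.asarray(X, dtype=float), y_idx, len(self.classes_))
        return self

    def predict_proba(self, X):
        return _softmax(self._net_output(X))

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class Conv1dRegressor(_ConvNetBase, RegressorMixin):
    """4 conv + 4 max-pool + 2 dense regression network."""

    def __init__(self, kernel_size=5, epochs=40, batch_size=64, lr=1e-3,
                 val_fraction=0.1, patience=8, random_state=0,
                 channels=(8, 16, 24, 32), hidden=32):
        super().__init__(kernel_size, epochs, batch_size, lr, val_fraction,
                         patience, random_state)
        self.channels = channels
        self.hidden = hidden

    def _build(self, rng, length, n_out):
        layers: list[_Layer] = []
        c_prev = 1
        L = length
        for c in self.channels:
            layers += [Conv1d(c_prev, c, self.kernel_size, rng), ReLU(), MaxPool1d()]
            c_prev = c
            L //= 2
        if L < 1:
            raise ValueError("input too short for four pooling stages")
        layers += [Flatten(), Dense(L * c_prev, self.hidden, rng), ReLU(),
                   Dense(self.hidden, n_out, rng)]
        return layers

    def _loss_grad(self, pred, y):
        return 2.0 * (pred - y[:, None]) / len(y)

    def _val_loss(self, pred, y):
        return float(np.mean((pred[:, 0] - y) ** 2))

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        self._y_mu = float(y.mean())
        self._y_sigma = float(y.std()) or 1.0
        self._fit_net(np.asarray(X, dtype=float), (y - self._y_mu) / self._y_sigma, 1)
        return self

    def predict(self, X):
        return self._net_output(X)[:, 0] * self._y_sigma + self._y_mu
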