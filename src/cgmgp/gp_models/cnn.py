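"""1-D convolutional genotype-to-phenotype regression.

A compact convolutional network written directly in numpy: five strided
1-D convolution layers (kernel sizes 11, 11, 9, 13, 9; strides 1, 3, 5, 5,
5; 'same' padding), a flatten, a 32-unit dense layer, and a sigmoid output
head of size m (8 when predicting the growth-model parameters, 1 for the
direct trait).  Hidden activations are ReLU by default, switchable to an
alternating ReLU/softmax scheme.  Targets are affinely scaled to [0, 1]
(the sigmoid's range); training minimizes the NRMSE of the scaled targets
with the Adam optimizer, mini-batches, and early stopping on a validation
split.  Forward and backward passes are exact (hand-derived) and the whole
procedure is deterministic given the seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .base import GPModel, TargetScaler

__all__ = ["CNNSettings", "CNNModel", "feature_lengths"]


@dataclass(frozen=True)
class CNNSettings:
    kernels: tuple[int, ...] = (11, 11, 9, 13, 9)
    strides: tuple[int, ...] = (1, 3, 5, 5, 5)
    channels: tuple[int, ...] = (16, 32, 32, 64, 64)
    dense_units: int = 32
    hidden_activation: str = "relu"   # "relu" or "relu_softmax" alternation
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 200
    patience: int = 20
    val_fraction: float = 0.1
    seed: int = 0
    eps: float = 1e-6                 # guard in the relative-error loss
    loss_floor: float = 0.05          # min |target| entering the relative error


def feature_lengths(p: int, strides=(1, 3, 5, 5, 5)) -> list[int]:
    """Per-layer feature lengths under 'same' padding: L -> ceil(L/stride)."""
    lengths = []
    length = p
    for s in strides:
        length = math.ceil(length / s)
        lengths.append(length)
    return lengths


def _pad_amounts(L: int, k: int, stride: int) -> tuple[int, int, int]:
    out = math.ceil(L / stride)
    total = max((out - 1) * stride + k - L, 0)
    left = total // 2
    return out, left, total


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int):
    B, L, cin = x.shape
    k, _, cout = W.shape
    out, left, total = _pad_amounts(L, k, stride)
    xp = np.zeros((B, L + total, cin))
    xp[:, left:left + L] = x
    patches = np.empty((B, out, k, cin))
    for j in range(k):
        patches[:, :, j, :] = xp[:, j:j + stride * out:stride, :]
    z = patches.reshape(B * out, k * cin) @ W.reshape(k * cin, cout)
    z = z.reshape(B, out, cout) + b
    return z, patches


def _conv_backward(dz: np.ndarray, patches: np.ndarray, W: np.ndarray,
                   stride: int, L: int):
    B, out, cout = dz.shape
    k, cin, _ = W.shape
    _, left, total = _pad_amounts(L, k, stride)
    dz_flat = dz.reshape(B * out, cout)
    dW = (patches.reshape(B * out, k * cin).T @ dz_flat).reshape(k, cin, cout)
    db = dz.sum(axis=(0, 1))
    dpatches = (dz_flat @ W.reshape(k * cin, cout).T).reshape(B, out, k, cin)
    dxp = np.zeros((B, L + total, cin))
    for j in range(k):
        dxp[:, j:j + stride * out:stride, :] += dpatches[:, :, j, :]
    return dW, db, dxp[:, left:left + L]


def _relu(z):
    return np.maximum(z, 0.0)


def _softmax(z):
    # softmax over the channel axis (last), positionwise
    zs = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(zs)
    return ez / ez.sum(axis=-1, keepdims=True)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class CNNModel(GPModel):
    """Convolutional engine; predicts all targets jointly."""

    def __init__(self, settings: CNNSettings | None = None,
                 scaler: TargetScaler | None = None):
        self.settings = settings or CNNSettings()
        if len(self.settings.kernels) != len(self.settings.strides) or \
                len(self.settings.kernels) != len(self.settings.channels):
            raise ValueError("kernels, strides and channels must align")
        self.scaler = scaler
        self.params_: list[np.ndarray] | None = None
        self.history_: dict | None = None

    # -- architecture ------------------------------------------------------
    def _activations(self):
        n = len(self.settings.kernels) + 1  # conv layers + dense
        if self.settings.hidden_activation == "relu":
            return ["relu"] * n
        if self.settings.hidden_activation == "relu_softmax":
            return [("relu" if i % 2 == 0 else "softmax") for i in range(n)]
        raise ValueError("hidden_activation must be 'relu' or 'relu_softmax'")

    def _init_params(self, p: int, m: int, rng: np.random.Generator):
        s = self.settings
        params = []
        cin = 1
        for k, cout in zip(s.kernels, s.channels):
            fan_in = k * cin
            params.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, cin, cout)))
            params.append(np.zeros(cout))
            cin = cout
        flat = feature_lengths(p, s.strides)[-1] * s.channels[-1]
        params.append(rng.normal(0.0, np.sqrt(2.0 / flat), size=(flat, s.dense_units)))
        params.append(np.zeros(s.dense_units))
        limit = np.sqrt(6.0 / (s.dense_units + m))
        params.append(rng.uniform(-limit, limit, size=(s.dense_units, m)))
        params.append(np.zeros(m))
        return params

    def _forward(self, X: np.ndarray, params: list[np.ndarray]):
        s = self.settings
        acts = self._activations()
        x = X[:, :, None]
        caches = []
        for i, (k, stride) in enumerate(zip(s.kernels, s.strides)):
            W, b = params[2 * i], params[2 * i + 1]
            z, patches = _conv_forward(x, W, b, stride)
            h = _relu(z) if acts[i] == "relu" else _softmax(z)
            caches.append((x.shape[1], patches, z, h))
            x = h
        B = X.shape[0]
        flat = x.reshape(B, -1)
        Wd, bd = params[-4], params[-3]
        zd = flat @ Wd + bd
        hd = _relu(zd) if acts[-1] == "relu" else _softmax(zd)
        Wo, bo = params[-2], params[-1]
        zo = hd @ Wo + bo
        out = _sigmoid(zo)
        return out, (caches, x.shape, flat, zd, hd, zo)

    def _backward(self, X, dout, params, cache):
        s = self.settings
        acts = self._activations()
        caches, conv_shape, flat, zd, hd, zo = cache
        grads = [None] * len(params)
        dzo = dout * _sigmoid(zo) * (1.0 - _sigmoid(zo))
        grads[-2] = hd.T @ dzo
        grads[-1] = dzo.sum(axis=0)
        dhd = dzo @ params[-2].T
        if acts[-1] == "relu":
            dzd = dhd * (zd > 0)
        else:
            sm = _softmax(zd)
            dzd = sm * (dhd - (dhd * sm).sum(axis=-1, keepdims=True))
        grads[-4] = flat.T @ dzd
        grads[-3] = dzd.sum(axis=0)
        dx = (dzd @ params[-4].T).reshape(conv_shape)
        for i in reversed(range(len(s.kernels))):
            L, patches, z, h = caches[i]
            if acts[i] == "relu":
                dz = dx * (z > 0)
            else:
                sm = _softmax(z)
                dz = sm * (dx - (dx * sm).sum(axis=-1, keepdims=True))
            dW, db, dx = _conv_backward(dz, patches, params[2 * i], s.strides[i], L)
            grads[2 * i], grads[2 * i + 1] = dW, db
        return grads

    def _loss_grad(self, pred: np.ndarray, target: np.ndarray):
        """NRMSE on scaled targets.

        The denominator is floored: scaled targets reach 0 exactly (the
        training-fold minimum), where a raw relative error would let a
        single sample dominate every gradient.
        """
        eps = self.settings.eps
        w = 1.0 / (np.maximum(target, self.settings.loss_floor) + eps) ** 2
        diff = pred - target
        mse = np.mean(w * diff**2)
        loss = np.sqrt(mse)
        if loss < 1e-12:
            return loss, np.zeros_like(pred)
        grad = w * diff / (diff.size * loss)
        return loss, grad

    # -- training ----------------------------------------------------------
    def _fit(self, X: np.ndarray, Y: np.ndarray) -> None:
        s = self.settings
        n, p = X.shape
        m = Y.shape[1]
        if m not in (1, 8):
            warnings.warn(f"unusual output size m={m} (expected 1 or 8)", stacklevel=2)
        if self.scaler is None:
            self.scaler = TargetScaler.from_data(Y)
        T = self.scaler.transform(Y)
        rng = np.random.default_rng(s.seed)
        params = self._init_params(p, m, rng)
        adam = _Adam(params, s.learning_rate)

        n_val = int(round(s.val_fraction * n)) if n >= 20 else 0
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        Xtr, Ttr = X[train_idx], T[train_idx]
        Xval, Tval = X[val_idx], T[val_idx]

        best = [w.copy() for w in params]
        best_loss, patience_left = np.inf, s.patience
        history = {"train": [], "val": []}
        for epoch in range(s.epochs):
            order = rng.permutation(len(Xtr))
            epoch_loss = 0.0
            for start in range(0, len(Xtr), s.batch_size):
                idx = order[start:start + s.batch_size]
                pred, cache = self._forward(Xtr[idx], params)
                loss, dout = self._loss_grad(pred, Ttr[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError("non-finite training loss")
                grads = self._backward(Xtr[idx], dout, params, cache)
                adam.step(params, grads)
                epoch_loss += loss * len(idx)
            epoch_loss /= len(Xtr)
            if n_val:
                pred, _ = self._forward(Xval, params)
                monitor, _ = self._loss_grad(pred, Tval)
            else:
                monitor = epoch_loss
            history["train"].append(epoch_loss)
            history["val"].append(monitor if n_val else np.nan)
            if monitor < best_loss - 1e-6:
                best_loss = monitor
                best = [w.copy() for w in params]
                patience_left = s.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        self.params_ = best
        self.history_ = history

    def _predict(self, X: np.ndarray) -> np.ndarray:
        out_batches = []
        for start in range(0, len(X), 256):
            pred, _ = self._forward(X[start:start + 256], self.params_)
            out_batches.append(pred)
        return self.scaler.inverse(np.concatenate(out_batches, axis=0))
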