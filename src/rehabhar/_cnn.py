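"""Minimal 1-D convolutional network in numpy.

Implements exactly the recognizer architecture: two valid
convolutions along the time axis (sensor channels as input depth)
with ReLU and non-overlapping max-pooling, a fully connected ReLU
layer, and a softmax output head, trained by mini-batch Adam on
cross-entropy.  Everything is plain numpy, single-threaded and
deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid 1-D convolution. x: (N, T, C), w: (k, C, F) -> (N, T-k+1, F)."""
    k = w.shape[0]
    xw = sliding_window_view(x, k, axis=1)  # (N, To, C, k)
    return np.einsum("ntck,kcf->ntf", xw, w, optimize=True) + b


def _conv_backward(
    x: np.ndarray, w: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a valid 1-D convolution: returns (dx, dw, db)."""
    k = w.shape[0]
    xw = sliding_window_view(x, k, axis=1)
    dw = np.einsum("ntck,ntf->kcf", xw, dy, optimize=True)
    db = dy.sum(axis=(0, 1))
    pad = np.pad(dy, ((0, 0), (k - 1, k - 1), (0, 0)))
    dyw = sliding_window_view(pad, k, axis=1)  # (N, T, F, k)
    dx = np.einsum("ntfk,kcf->ntc", dyw, w[::-1], optimize=True)
    return dx, dw, db


def _pool_forward(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping max pool along time; trailing remainder dropped."""
    n, t, f = x.shape
    to = t // p
    xr = x[:, : to * p].reshape(n, to, p, f)
    arg = xr.argmax(axis=2)
    out = np.take_along_axis(xr, arg[:, :, None, :], axis=2)[:, :, 0, :]
    return out, arg


def _pool_backward(dy: np.ndarray, arg: np.ndarray, t_in: int, p: int) -> np.ndarray:
    n, to, f = dy.shape
    dxr = np.zeros((n, to, p, f), dtype=dy.dtype)
    np.put_along_axis(dxr, arg[:, :, None, :], dy[:, :, None, :], axis=2)
    dx = np.zeros((n, t_in, f), dtype=dy.dtype)
    dx[:, : to * p] = dxr.reshape(n, to * p, f)
    return dx


class SmallCNN:
    """Two conv blocks + dense layer + softmax classifier head."""

    def __init__(
        self,
        input_len: int,
        in_channels: int,
        n_classes: int,
        conv1_maps: int = 8,
        conv2_maps: int = 16,
        dense_units: int = 32,
        kernel_size: int = 5,
        pool_size: int = 2,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        k, p = kernel_size, pool_size
        t1 = input_len - k + 1
        if t1 < 1:
            raise ValueError("input shorter than first kernel")
        t1p = t1 // p
        t2 = t1p - k + 1
        if t2 < 1:
            raise ValueError("input too short for second conv block")
        t2p = t2 // p
        if t2p < 1:
            raise ValueError("input too short for second pooling")
        self.kernel_size = k
        self.pool_size = p
        self.shapes = (input_len, t1, t1p, t2, t2p)
        flat = t2p * conv2_maps

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "w1": he((k, in_channels, conv1_maps), k * in_channels),
            "b1": np.zeros(conv1_maps),
            "w2": he((k, conv1_maps, conv2_maps), k * conv1_maps),
            "b2": np.zeros(conv2_maps),
            "w3": he((flat, dense_units), flat),
            "b3": np.zeros(dense_units),
            "w4": he((dense_units, n_classes), dense_units),
            "b4": np.zeros(n_classes),
        }
        self._adam_m = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_v = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_t = 0

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Logits for x of shape (N, T, C); fills ``cache`` if given."""
        p = self.params
        z1 = _conv_forward(x, p["w1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        p1, arg1 = _pool_forward(a1, self.pool_size)
        z2 = _conv_forward(p1, p["w2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        p2, arg2 = _pool_forward(a2, self.pool_size)
        flat = p2.reshape(x.shape[0], -1)
        z3 = flat @ p["w3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        logits = a3 @ p["w4"] + p["b4"]
        if cache is not None:
            cache.update(
                x=x, z1=z1, a1=a1, arg1=arg1, p1=p1, z2=z2, a2=a2,
                arg2=arg2, p2=p2, flat=flat, z3=z3, a3=a3,
            )
        return logits

    def _gradients(self, cache: dict, dlogits: np.ndarray) -> dict:
        p = self.params
        g = {}
        g["w4"] = cache["a3"].T @ dlogits
        g["b4"] = dlogits.sum(axis=0)
        da3 = dlogits @ p["w4"].T
        dz3 = da3 * (cache["z3"] > 0)
        g["w3"] = cache["flat"].T @ dz3
        g["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["w3"].T
        dp2 = dflat.reshape(cache["p2"].shape)
        da2 = _pool_backward(dp2, cache["arg2"], cache["a2"].shape[1], self.pool_size)
        dz2 = da2 * (cache["z2"] > 0)
        dp1, g["w2"], g["b2"] = _conv_backward(cache["p1"], p["w2"], dz2)
        da1 = _pool_backward(dp1, cache["arg1"], cache["a1"].shape[1], self.pool_size)
        dz1 = da1 * (cache["z1"] > 0)
        _, g["w1"], g["b1"] = _conv_backward(cache["x"], p["w1"], dz1)
        return g

    def _adam_step(self, grads: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k_, g in grads.items():
            m = self._adam_m[k_] = beta1 * self._adam_m[k_] + (1 - beta1) * g
            v = self._adam_v[k_] = beta2 * self._adam_v[k_] + (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k_] -= lr * mhat / (np.sqrt(vhat) + eps)

    def train_step(self, x: np.ndarray, y: np.ndarray, lr: float) -> float:
        """One mini-batch step; y is int class indices. Returns CE loss."""
        cache: dict = {}
        logits = self.forward(x, cache)
        probs = softmax(logits)
        n = x.shape[0]
        loss = -np.mean(np.log(probs[np.arange(n), y] + 1e-12))
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        self._adam_step(self._gradients(cache, dlogits), lr)
        return float(loss)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int,
        lr: float,
        rng: np.random.Generator,
    ) -> list[float]:
        """Epoch loop with seeded shuffling; returns per-epoch mean loss."""
        n = x.shape[0]
        history = []
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                losses.append(self.train_step(x[idx], y[idx], lr))
            history.append(float(np.mean(losses)))
        return history

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = []
        for start in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[start : start + batch_size])))
        return np.concatenate(out)

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k_: v.copy() for k_, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k_ in self.params:
            self.params[k_] = np.asarray(weights[k_], dtype=float).copy()
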