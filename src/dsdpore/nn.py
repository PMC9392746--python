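"""A small, deterministic CPU convolutional-network engine (pure numpy).

Provides exactly what the barcode classifiers need: 2D convolutions
(shift-accumulate, 'same' padding), ReLU / log-sigmoid activations, max and
average pooling, dense layers, residual blocks, softmax cross-entropy and
Adam.  Everything is float32 and seeded, so training and inference are
bit-reproducible on a given machine; weights serialize to ``.npz``.

This is intentionally minimal — no autograd graph, just explicit
forward/backward per layer — but fully vectorized so that desk-scale
training (tens of thousands of 2D windows, tens of epochs) runs in minutes
on one CPU core.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "LogSigmoid",
    "MaxPool2",
    "AvgPool",
    "Flatten",
    "Dense",
    "ResidualBlock",
    "Network",
    "softmax",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, value, gradient) triples; empty for stateless layers."""
        return []


class Conv2D(Layer):
    """k x k convolution, stride 1, zero 'same' padding (im2col + GEMM)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        fan_in = c_in * kernel * kernel
        self.w = (rng.standard_normal((c_out, c_in, kernel, kernel)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = kernel
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def _wmat(self) -> np.ndarray:
        # (C*k*k, O), column order matches the im2col patch layout
        return self.w.transpose(1, 2, 3, 0).reshape(-1, self.w.shape[0])

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (B, C, H, W, k, k) -> (B*H*W, C*k*k)
        cols = np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B * H * W, C * k * k
        )
        self._cols = cols
        self._dims = (B, C, H, W)
        y = cols @ self._wmat() + self.b
        return np.ascontiguousarray(
            y.reshape(B, H, W, -1).transpose(0, 3, 1, 2), dtype=np.float32
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        B, C, H, W = self._dims
        O = self.w.shape[0]
        dym = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(B * H * W, O)
        dwm = self._cols.T @ dym  # (C*k*k, O)
        self.dw[:] = dwm.reshape(C, k, k, O).transpose(3, 0, 1, 2)
        self.db[:] = dym.sum(axis=0)
        dcols = (dym @ self._wmat().T).reshape(B, H, W, C, k, k)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + H, dj : dj + W] += dcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        self._cols = None
        return dxp[:, :, p : p + H, p : p + W] if p else dxp

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class LogSigmoid(Layer):
    """log(sigmoid(x)) = -softplus(-x); numerically stable."""

    def forward(self, x):
        self._x = x
        return (-np.logaddexp(0.0, -x)).astype(np.float32)

    def backward(self, dy):
        # d/dx logsigmoid = sigmoid(-x)
        return (dy / (1.0 + np.exp(self._x))).astype(np.float32)


class MaxPool2(Layer):
    """2x2 max pooling (trailing odd row/column dropped)."""

    def forward(self, x):
        B, C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        xc = x[:, :, : H2 * 2, : W2 * 2]
        self._in_shape = x.shape
        r = xc.reshape(B, C, H2, 2, W2, 2)
        y = r.max(axis=(3, 5))
        mask = r == y[:, :, :, None, :, None]
        self._mask = mask / np.maximum(mask.sum(axis=(3, 5), keepdims=True), 1)
        return y.astype(np.float32)

    def backward(self, dy):
        B, C, H, W = self._in_shape
        H2, W2 = H // 2, W // 2
        dr = self._mask * dy[:, :, :, None, :, None]
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, :, : H2 * 2, : W2 * 2] = dr.reshape(B, C, H2 * 2, W2 * 2)
        return dx


class AvgPool(Layer):
    """k x k average pooling (used to downsample the raw 2D window)."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x):
        B, C, H, W = x.shape
        k = self.k
        H2, W2 = H // k, W // k
        self._in_shape = x.shape
        xc = x[:, :, : H2 * k, : W2 * k]
        return xc.reshape(B, C, H2, k, W2, k).mean(axis=(3, 5)).astype(np.float32)

    def backward(self, dy):
        B, C, H, W = self._in_shape
        k = self.k
        H2, W2 = H // k, W // k
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dr = np.broadcast_to(
            dy[:, :, :, None, :, None] / (k * k), (B, C, H2, k, W2, k)
        )
        dx[:, :, : H2 * k, : W2 * k] = dr.reshape(B, C, H2 * k, W2 * k)
        return dx


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw[:] = self._x.T @ dy
        self.db[:] = dy.sum(axis=0)
        self._x = None
        return dy @ self.w.T

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class ResidualBlock(Layer):
    """y = relu(x + conv(relu(conv(x)))), channel-preserving."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        self.conv1 = Conv2D(channels, channels, kernel, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(channels, channels, kernel, rng)
        self.relu_out = ReLU()

    def forward(self, x):
        h = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu_out.forward(x + h)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dh = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        return d + dh

    def params(self):
        return [
            (f"conv1.{n}", v, g) for n, v, g in self.conv1.params()
        ] + [(f"conv2.{n}", v, g) for n, v, g in self.conv2.params()]


class Network:
    """Sequential network with softmax cross-entropy loss and Adam."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self._adam_state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # -- inference ---------------------------------------------------------
    def logits(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            h = x[i : i + batch_size]
            for layer in self.layers:
                h = layer.forward(h)
            outs.append(h)
        return np.concatenate(outs, axis=0)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return softmax(self.logits(x, batch_size))

    # -- training ----------------------------------------------------------
    def _step(self, xb: np.ndarray, yb: np.ndarray, lr: float) -> float:
        h = xb
        for layer in self.layers:
            h = layer.forward(h)
        probs = softmax(h)
        n = len(xb)
        loss = -float(np.mean(np.log(probs[np.arange(n), yb] + 1e-12)))
        dy = probs
        dy[np.arange(n), yb] -= 1.0
        dy = (dy / n).astype(np.float32)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        self._adam_update(lr)
        return loss

    def _adam_update(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        i = 0
        for layer in self.layers:
            for _, value, grad in layer.params():
                if i not in self._adam_state:
                    self._adam_state[i] = (np.zeros_like(value), np.zeros_like(value))
                m, v = self._adam_state[i]
                m[:] = beta1 * m + (1 - beta1) * grad
                v[:] = beta2 * v + (1 - beta2) * grad * grad
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                value -= lr * mhat / (np.sqrt(vhat) + eps)
                i += 1

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int = 128,
        lr: float = 1e-3,
        seed: int = 0,
    ) -> list[float]:
        """Train with shuffled minibatches; returns the per-epoch mean loss."""
        rng = np.random.default_rng(seed)
        history = []
        n = len(x)
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                losses.append(self._step(x[idx], y[idx], lr))
            history.append(float(np.mean(losses)))
        return history

    # -- serialization -----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for li, layer in enumerate(self.layers):
            for name, value, _ in layer.params():
                out[f"layer{li}.{name}"] = value
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for name, value, _ in layer.params():
                value[:] = state[f"layer{li}.{name}"]
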