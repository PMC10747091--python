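"""A compact convolutional network for 50x50 grayscale gesture images.

Architecture (fixed, asserted at construction):

    input 50x50x1
    conv 16 filters 2x2, same padding, ReLU   -> 50x50x16
    max-pool 2x2 / stride 2                   -> 25x25x16
    conv 32 filters 3x3, same padding, ReLU   -> 25x25x32
    max-pool 3x3 / stride 3                   -> 8x8x32
    conv 64 filters 5x5, same padding, ReLU   -> 8x8x64
    max-pool 8x8 / stride 8                   -> 1x1x64
    dense 128, ReLU
    dense n_classes, softmax

With 29 output classes this is 68,045 trainable parameters
(80 + 4,640 + 51,264 + 8,320 + 3,741).  Implemented directly on NumPy:
im2col convolutions, non-overlapping max pooling (trailing rows/columns
that do not fill a window are dropped, e.g. 25 -> 8 under a 3x3/3 pool),
softmax cross-entropy loss and an Adam optimizer.  Everything is
deterministic given the seed and a fixed BLAS configuration.

Even-sized kernels pad asymmetrically (one extra row/column at the
bottom/right), the usual "same" convention.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GestureNet", "softmax"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _im2col(x: np.ndarray, kh: int, kw: int, pad: tuple[int, int, int, int]):
    """Extract kh x kw patches (stride 1) as a matrix of rows.

    Returns (cols, padded_shape, out_h, out_w) with cols of shape
    (N * out_h * out_w, kh * kw * C).
    """
    pt, pb, pl, pr = pad
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    n, hp, wp, c = xp.shape
    out_h = hp - kh + 1
    out_w = wp - kw + 1
    s0, s1, s2, s3 = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (n, out_h, out_w, kh, kw, c), (s0, s1, s2, s1, s2, s3)
    )
    return win.reshape(n * out_h * out_w, kh * kw * c), xp.shape, out_h, out_w


def _col2im(dcols, padded_shape, kh, kw, pad, out_h, out_w):
    """Scatter-add patch gradients back onto the (unpadded) input."""
    n, hp, wp, c = padded_shape
    dxp = np.zeros(padded_shape, dtype=dcols.dtype)
    d6 = dcols.reshape(n, out_h, out_w, kh, kw, c)
    for i in range(kh):
        for j in range(kw):
            dxp[:, i : i + out_h, j : j + out_w, :] += d6[:, :, :, i, j, :]
    pt, pb, pl, pr = pad
    return dxp[:, pt : hp - pb, pl : wp - pr, :]


def _same_pad(k: int) -> tuple[int, int]:
    total = k - 1
    return total // 2, total - total // 2


class _Conv:
    def __init__(self, kh, kw, c_in, c_out, rng, dtype):
        fan_in = kh * kw * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (kh * kw * c_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.kh, self.kw = kh, kw
        self.pad = _same_pad(kh) + _same_pad(kw)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x):
        cols, padded_shape, oh, ow = _im2col(x, self.kh, self.kw, self.pad)
        y = cols @ self.W + self.b
        self._cache = (cols, padded_shape, oh, ow, x.shape[0])
        return y.reshape(x.shape[0], oh, ow, -1)

    def backward(self, dy):
        cols, padded_shape, oh, ow, n = self._cache
        dyf = dy.reshape(n * oh * ow, -1)
        self.dW = cols.T @ dyf
        self.db = dyf.sum(axis=0)
        dcols = dyf @ self.W.T
        return _col2im(dcols, padded_shape, self.kh, self.kw, self.pad, oh, ow)


class _MaxPool:
    """Non-overlapping k x k max pooling; trailing remainder is dropped."""

    def __init__(self, k):
        self.k = k

    def forward(self, x):
        n, h, w, c = x.shape
        k = self.k
        oh, ow = h // k, w // k
        xc = x[:, : oh * k, : ow * k, :]
        win = xc.reshape(n, oh, k, ow, k, c)
        y = win.max(axis=(2, 4))
        # gradient mask: 1 at every element equal to its window max
        self._cache = (x.shape, win, y)
        return y

    def backward(self, dy):
        x_shape, win, y = self._cache
        n, h, w, c = x_shape
        k = self.k
        oh, ow = h // k, w // k
        mask = win == y[:, :, None, :, None, :]
        # share gradient among ties to keep backward well-defined
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dwin = mask * (dy[:, :, None, :, None, :] / counts)
        dx = np.zeros(x_shape, dtype=dy.dtype)
        dx[:, : oh * k, : ow * k, :] = dwin.reshape(n, oh * k, ow * k, c)
        return dx


class _Dense:
    def __init__(self, n_in, n_out, rng, dtype):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T


class GestureNet:
    """The realized network; see the module docstring for the architecture.

    Parameters
    ----------
    n_classes : int
        Number of softmax outputs (>= 2); 29 for the full alphabet task.
    seed : int
        Seed for He-normal weight initialization.
    dtype : numpy dtype
        float32 by default; float64 is used by the gradient-check tests.
    """

    INPUT_SHAPE = (50, 50, 1)
    FC1_UNITS = 128

    def __init__(self, n_classes: int = 29, seed: int = 0, dtype=np.float32):
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        rng = np.random.default_rng(seed)
        self.dtype = np.dtype(dtype)
        self.n_classes = n_classes
        self.conv1 = _Conv(2, 2, 1, 16, rng, self.dtype)
        self.pool1 = _MaxPool(2)
        self.conv2 = _Conv(3, 3, 16, 32, rng, self.dtype)
        self.pool2 = _MaxPool(3)
        self.conv3 = _Conv(5, 5, 32, 64, rng, self.dtype)
        self.pool3 = _MaxPool(8)
        self.fc1 = _Dense(64, self.FC1_UNITS, rng, self.dtype)
        self.fc2 = _Dense(self.FC1_UNITS, n_classes, rng, self.dtype)
        self._check_shapes()
        self._adam_state = None

    # -- bookkeeping ------------------------------------------------------

    @property
    def _param_layers(self):
        return [self.conv1, self.conv2, self.conv3, self.fc1, self.fc2]

    def layer_parameter_counts(self) -> dict[str, int]:
        names = ["conv1", "conv2", "conv3", "fc1", "fc2"]
        return {n: l.n_params for n, l in zip(names, self._param_layers)}

    def n_parameters(self) -> int:
        return sum(self.layer_parameter_counts().values())

    def _check_shapes(self) -> None:
        x = np.zeros((1, *self.INPUT_SHAPE), dtype=self.dtype)
        expected = [(50, 50, 16), (25, 25, 16), (25, 25, 32), (8, 8, 32),
                    (8, 8, 64), (1, 1, 64)]
        seen = []
        for layer in (self.conv1, self.pool1, self.conv2, self.pool2,
                      self.conv3, self.pool3):
            x = layer.forward(x)
            seen.append(x.shape[1:])
        if seen != expected:
            raise AssertionError(f"shape chain {seen} != expected {expected}")

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of shape (N, 50, 50) or (N, 50, 50, 1)."""
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1:] != self.INPUT_SHAPE:
            raise ValueError(
                f"expected input of shape (N, 50, 50[, 1]), got {x.shape}"
            )
        x = np.ascontiguousarray(x, dtype=self.dtype)
        a1 = self.conv1.forward(x)
        r1 = np.maximum(a1, 0)
        p1 = self.pool1.forward(r1)
        a2 = self.conv2.forward(p1)
        r2 = np.maximum(a2, 0)
        p2 = self.pool2.forward(r2)
        a3 = self.conv3.forward(p2)
        r3 = np.maximum(a3, 0)
        p3 = self.pool3.forward(r3)
        flat = p3.reshape(x.shape[0], -1)
        h = self.fc1.forward(flat)
        rh = np.maximum(h, 0)
        self._fc2_in = rh
        logits = self.fc2.forward(rh)
        if train:
            self._relu_masks = (a1 > 0, a2 > 0, a3 > 0, h > 0)
        return logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    def loss_and_grads(self, x: np.ndarray, y_idx: np.ndarray) -> float:
        """Mean softmax cross-entropy on (x, integer labels); stores grads."""
        n = x.shape[0]
        logits = self.forward(x, train=True)
        p = softmax(logits)
        eps = np.finfo(self.dtype).tiny
        loss = -np.log(np.maximum(p[np.arange(n), y_idx], eps)).mean()
        dlogits = p.astype(self.dtype)
        dlogits[np.arange(n), y_idx] -= 1.0
        dlogits /= n
        m1, m2, m3, mh = self._relu_masks
        d = self.fc2.backward(dlogits)
        d = d * mh
        d = self.fc1.backward(d)
        d = d.reshape(-1, 1, 1, 64)
        d = self.pool3.backward(d)
        d = self.conv3.backward(d * m3)
        d = self.pool2.backward(d)
        d = self.conv2.backward(d * m2)
        d = self.pool1.backward(d)
        self.conv1.backward(d * m1)
        return float(loss)

    # -- optimization -----------------------------------------------------

    def adam_step(self, lr: float = 1e-3, beta1: float = 0.9,
                  beta2: float = 0.999, eps: float = 1e-8) -> None:
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": [np.zeros_like(p) for l in self._param_layers for p in (l.W, l.b)],
                "v": [np.zeros_like(p) for l in self._param_layers for p in (l.W, l.b)],
            }
        st = self._adam_state
        st["t"] += 1
        t = st["t"]
        params = [p for l in self._param_layers for p in (l.W, l.b)]
        grads = [g for l in self._param_layers for g in (l.dW, l.db)]
        for i, (p, g) in enumerate(zip(params, grads)):
            g = g.astype(p.dtype)
            st["m"][i] = beta1 * st["m"][i] + (1 - beta1) * g
            st["v"][i] = beta2 * st["v"][i] + (1 - beta2) * g * g
            mhat = st["m"][i] / (1 - beta1**t)
            vhat = st["v"][i] / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def sgd_step(self, lr: float = 1e-2) -> None:
        for l in self._param_layers:
            l.W -= lr * l.dW.astype(l.W.dtype)
            l.b -= lr * l.db.astype(l.b.dtype)

    # -- persistence ------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {"n_classes": np.array(self.n_classes)}
        for name, l in zip(["conv1", "conv2", "conv3", "fc1", "fc2"],
                           self._param_layers):
            out[f"{name}.W"] = l.W
            out[f"{name}.b"] = l.b
        return out

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path) -> "GestureNet":
        data = np.load(path)
        net = cls(n_classes=int(data["n_classes"]))
        for name, l in zip(["conv1", "conv2", "conv3", "fc1", "fc2"],
                           net._param_layers):
            l.W = data[f"{name}.W"].astype(net.dtype)
            l.b = data[f"{name}.b"].astype(net.dtype)
        return net
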