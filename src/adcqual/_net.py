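"""Minimal CPU neural-network engine: conv/pool/dense layers with manual
backprop, decoupled-weight-decay Adam, adaptive sharpness-aware perturbation
and a cosine learning-rate schedule.

All arrays are float32. Layers store their parameters in ``.params`` and the
gradients of the last backward pass in ``.grads`` (same keys). The engine is
deliberately small: it exists to train the compact ordinal-regression
backbones of this package on phantom-scale images, not to compete with a
general framework.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ConvNet",
    "Adam",
    "asam_perturbation",
    "cosine_lr",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(_Layer):
    """Same-padding stride-1 convolution via im2col + BLAS matmul."""

    def __init__(self, c_in, c_out, kernel, rng):
        super().__init__()
        k = kernel
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(c_out, np.float32)}
        self.k = k
        self._cache = None

    def forward(self, x, train=False):
        k = self.k
        p = k // 2
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k
        )
        wmat = self.params["W"].reshape(-1, c * k * k).T  # (c*k*k, c_out)
        out = cols @ wmat + self.params["b"]
        out = out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, dout):
        cols, xshape = self._cache
        n, c, h, w = xshape
        k, p = self.k, self.k // 2
        c_out = dout.shape[1]
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, c_out)
        self.grads["W"] = (dmat.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] = dmat.sum(axis=0)
        dcols = dmat @ self.params["W"].reshape(c_out, -1)  # (n*h*w, c*k*k)
        dcols = dcols.reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + h, p : p + w]


class ReLU(_Layer):
    def forward(self, x, train=False):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(_Layer):
    """2x2 max pooling; spatial dims must be even."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        # contiguous window corners: pairwise maxima beat a strided reduce
        a = np.ascontiguousarray(xr[:, :, :, 0, :, 0])
        b = np.ascontiguousarray(xr[:, :, :, 0, :, 1])
        cc = np.ascontiguousarray(xr[:, :, :, 1, :, 0])
        d = np.ascontiguousarray(xr[:, :, :, 1, :, 1])
        out = np.maximum(np.maximum(a, b), np.maximum(cc, d))
        if train:
            self._cache = ((a, b, cc, d), out, x.shape)
        return out

    def backward(self, dout):
        corners, out, xshape = self._cache
        n, c, h, w = xshape
        dx = np.zeros(xshape, np.float32)
        dxr = dx.reshape(n, c, h // 2, 2, w // 2, 2)
        # route each window's gradient to its first maximal corner
        taken = np.zeros(out.shape, bool)
        for (i, j), corner in zip(((0, 0), (0, 1), (1, 0), (1, 1)), corners):
            win = (corner == out) & ~taken
            taken |= win
            dxr[:, :, :, i, :, j] = np.where(win, dout, 0.0)
        return dx


class GlobalAvgPool(_Layer):
    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(
            dout[:, :, None, None] / (h * w), self._shape
        ).astype(np.float32)


class Dense(_Layer):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(n_out, np.float32)}

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class ConvNet:
    """Compact convolutional backbone with a small dense head.

    Architecture: [conv-relu-pool] x3, conv-relu, global average pooling,
    dense-relu, dense(n_out). Works for any input side divisible by 8.
    ``channels`` sets the widths of the four conv blocks.
    """

    def __init__(
        self,
        input_px: int,
        channels=(8, 16, 32, 32),
        first_kernel: int = 3,
        hidden: int = 32,
        n_out: int = 2,
        seed: int = 0,
    ):
        if input_px % 8 != 0:
            raise ValueError("input_px must be divisible by 8")
        rng = np.random.default_rng(seed)
        c1, c2, c3, c4 = channels
        self.input_px = input_px
        self.layers = [
            Conv2d(1, c1, first_kernel, rng),
            ReLU(),
            MaxPool2(),
            Conv2d(c1, c2, 3, rng),
            ReLU(),
            MaxPool2(),
            Conv2d(c2, c3, 3, rng),
            ReLU(),
            MaxPool2(),
            Conv2d(c3, c4, 3, rng),
            ReLU(),
            GlobalAvgPool(),
            Dense(c4, hidden, rng),
            ReLU(),
            Dense(hidden, n_out, rng),
        ]

    # -- parameter plumbing ------------------------------------------------
    def parameters(self):
        """Flat list of (layer, key) handles for every trainable array."""
        return [(ly, k) for ly in self.layers for k in ly.params]

    def get_params(self):
        return [ly.params[k] for ly, k in self.parameters()]

    def set_params(self, values):
        for (ly, k), v in zip(self.parameters(), values):
            ly.params[k] = v.astype(np.float32)

    def copy_params(self):
        return [ly.params[k].copy() for ly, k in self.parameters()]

    def n_parameters(self):
        return int(sum(p.size for p in self.get_params()))

    # -- compute -----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, 1, H, W) float32 -> logits (N, n_out) float64."""
        out = np.asarray(x, np.float32)
        for ly in self.layers:
            out = ly.forward(out, train=train)
        return out.astype(np.float64)

    def backward(self, dlogits: np.ndarray):
        d = dlogits.astype(np.float32)
        for ly in reversed(self.layers):
            d = ly.backward(d)
        return d

    def gradients(self):
        return [ly.grads[k] for ly, k in self.parameters()]


class Adam:
    """Adam with decoupled weight decay (applied to weight matrices only)."""

    def __init__(self, net: ConvNet, weight_decay: float = 0.0, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net = net
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in net.get_params()]
        self.v = [np.zeros_like(p) for p in net.get_params()]

    def step(self, grads, lr: float):
        self.t += 1
        b1, b2 = self.b1, self.b2
        handles = self.net.parameters()
        for i, ((ly, key), g) in enumerate(zip(handles, grads)):
            g = g.astype(np.float32)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p = ly.params[key]
            if self.wd and key == "W":
                p -= lr * self.wd * p
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def asam_perturbation(params, grads, rho: float, eta: float = 1e-12):
    """Adaptive-SAM ascent direction.

    Element-wise scaling T_w = |w|; epsilon = rho * T_w^2 g / ||T_w g||_2,
    with the norm taken over all parameters jointly. Returns a list of
    perturbations (zeros when rho == 0 or the gradient vanishes).
    """
    tg_sq = 0.0
    scaled = []
    for p, g in zip(params, grads):
        t = np.abs(p)
        tg = t * g
        scaled.append(t * tg)  # T_w^2 g
        tg_sq += float(np.sum(tg * tg))
    norm = np.sqrt(tg_sq)
    if rho == 0.0 or norm < eta:
        return [np.zeros_like(p) for p in params]
    return [rho * s / norm for s in scaled]


def cosine_lr(epoch: int, total_epochs: int, lr_init: float, lr_min: float) -> float:
    """Cosine annealing from lr_init (epoch 0) to lr_min (last epoch)."""
    if total_epochs <= 1:
        return lr_init
    frac = epoch / (total_epochs - 1)
    return lr_min + 0.5 * (lr_init - lr_min) * (1.0 + np.cos(np.pi * frac))
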