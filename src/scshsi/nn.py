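"""Minimal numpy neural-network layers with exact analytic backward passes.

All image tensors are NHWC ``(n, h, w, c)`` float64; dense tensors are
``(n, d)``. Every layer caches what its backward pass needs on ``forward`` and
exposes trainable arrays through ``params``/``grads`` dicts keyed by name.
Determinism: given the same seed and data, forward/backward/Adam are pure
numpy and reproduce bit-identical training histories on the same machine.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Dense", "ReLU", "Flatten", "BatchNorm", "Conv2D",
    "MaxPool2D", "AvgPool2D", "AbsMaxPool2D", "SCSLayer", "Sequential",
    "Adam", "softmax", "softmax_cross_entropy",
]


def _windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(n, h', w', k, k, c) strided view of spatial windows of NHWC input."""
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    return win[:, ::stride, ::stride].transpose(0, 1, 2, 4, 5, 3)


def _scatter_windows(dwin: np.ndarray, in_shape: tuple, k: int, stride: int
                     ) -> np.ndarray:
    """Adjoint of `_windows`: accumulate window grads back onto the input."""
    dx = np.zeros(in_shape)
    n, hp, wp = dwin.shape[:3]
    for ki in range(k):
        for kj in range(k):
            dx[:, ki:ki + hp * stride:stride, kj:kj + wp * stride:stride, :] += \
                dwin[:, :, :, ki, kj, :]
    return dx


class Layer:
    """Base layer: stateless by default, trainable arrays in ``params``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def constrain(self) -> None:
        """Clamp parameters to their feasible region after an optimizer step."""


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (in_dim + out_dim))
        self.params = {"W": rng.uniform(-limit, limit, (in_dim, out_dim)),
                       "b": np.zeros(out_dim)}

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads = {"W": self._x.T @ g, "b": g.sum(axis=0)}
        return g @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class BatchNorm(Layer):
    """Batch normalization over the feature axis of (n, d) inputs."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(dim), "beta": np.zeros(dim)}
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, g):
        xhat, std = self._xhat, self._std
        self.grads = {"gamma": (g * xhat).sum(axis=0), "beta": g.sum(axis=0)}
        gx = g * self.params["gamma"]
        if not self._training:
            return gx / std
        n = g.shape[0]
        return (gx - gx.mean(axis=0) - xhat * (gx * xhat).mean(axis=0)) / std


class Conv2D(Layer):
    """Valid or 'same' 2-D convolution (stride 1) with bias."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 padding: str = "valid"):
        super().__init__()
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        self.k, self.padding = k, padding
        scale = np.sqrt(2.0 / (k * k * in_ch))
        self.params = {"W": rng.standard_normal((out_ch, k, k, in_ch)) * scale,
                       "b": np.zeros(out_ch)}

    def _pad(self, x):
        if self.padding == "valid":
            return x, (0, 0)
        total = self.k - 1
        lo, hi = total // 2, total - total // 2
        return np.pad(x, ((0, 0), (lo, hi), (lo, hi), (0, 0))), (lo, hi)

    def forward(self, x, training=False):
        xp, self._pads = self._pad(x)
        self._in_shape, self._pad_shape = x.shape, xp.shape
        wins = _windows(xp, self.k, 1)
        self._cols = wins.reshape(*wins.shape[:3], -1)  # (n,h',w',k*k*in)
        W = self.params["W"].reshape(self.params["W"].shape[0], -1)
        return self._cols @ W.T + self.params["b"]

    def backward(self, g):
        out_ch = self.params["W"].shape[0]
        W = self.params["W"].reshape(out_ch, -1)
        self.grads = {
            "W": np.einsum("nhwu,nhwl->ul", g, self._cols).reshape(self.params["W"].shape),
            "b": g.sum(axis=(0, 1, 2)),
        }
        dcols = g @ W  # (n,h',w',k*k*in)
        dwin = dcols.reshape(*dcols.shape[:3], self.k, self.k, -1)
        dxp = _scatter_windows(dwin, self._pad_shape, self.k, 1)
        lo, hi = self._pads
        if (lo, hi) == (0, 0):
            return dxp
        return dxp[:, lo:dxp.shape[1] - hi, lo:dxp.shape[2] - hi, :]


class _Pool(Layer):
    def __init__(self, window: int, stride: int | None = None):
        super().__init__()
        self.window = window
        self.stride = window if stride is None else stride

    def _check(self, x):
        if self.window > min(x.shape[1], x.shape[2]):
            raise ValueError(
                f"pool window {self.window} exceeds spatial dims {x.shape[1:3]}"
            )


class MaxPool2D(_Pool):
    def forward(self, x, training=False):
        self._check(x)
        self._in_shape = x.shape
        wins = _windows(x, self.window, self.stride)
        flat = wins.reshape(*wins.shape[:3], self.window ** 2, x.shape[3])
        self._idx = np.argmax(flat, axis=3)
        self._out_spatial = flat.shape[:3]
        return np.take_along_axis(flat, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, g):
        n, hp, wp = self._out_spatial
        c = self._in_shape[3]
        dflat = np.zeros((n, hp, wp, self.window ** 2, c))
        np.put_along_axis(dflat, self._idx[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        dwin = dflat.reshape(n, hp, wp, self.window, self.window, c)
        return _scatter_windows(dwin, self._in_shape, self.window, self.stride)


class AbsMaxPool2D(MaxPool2D):
    """Keeps the signed entry of largest magnitude; gradient flows only to it."""

    def forward(self, x, training=False):
        self._check(x)
        self._in_shape = x.shape
        wins = _windows(x, self.window, self.stride)
        flat = wins.reshape(*wins.shape[:3], self.window ** 2, x.shape[3])
        self._idx = np.argmax(np.abs(flat), axis=3)  # first tie in row-major order
        self._out_spatial = flat.shape[:3]
        return np.take_along_axis(flat, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]


class AvgPool2D(_Pool):
    def forward(self, x, training=False):
        self._check(x)
        self._in_shape = x.shape
        wins = _windows(x, self.window, self.stride)
        return wins.mean(axis=(3, 4))

    def backward(self, g):
        k = self.window
        dwin = np.broadcast_to(g[:, :, :, None, None, :] / (k * k),
                               (*g.shape[:3], k, k, g.shape[3]))
        return _scatter_windows(dwin, self._in_shape, k, self.stride)


class SCSLayer(Layer):
    """Trainable sharpened-cosine-similarity layer (NHWC in/out).

    Per unit: weights on the unit sphere at init, a stabilizer ``q`` (clamped
    at ``q_floor``) and a sharpening exponent ``p`` (clamped at 1). No bias,
    no activation — the normalized score is the feature.
    """

    def __init__(self, in_ch: int, n_units: int, k: int, rng: np.random.Generator,
                 stride: int = 1, q_init: float = 0.1, p_init: float = 1.0,
                 q_trainable: bool = True, p_trainable: bool = True,
                 q_floor: float = 1e-6):
        super().__init__()
        L = k * k * in_ch
        W = rng.standard_normal((n_units, L))
        W /= np.linalg.norm(W, axis=1, keepdims=True)
        self.params = {"W": W}
        self.q = np.full(n_units, float(q_init))
        self.p = np.full(n_units, float(p_init))
        if q_trainable:
            self.params["q"] = self.q
        if p_trainable:
            self.params["p"] = self.p
        self.k, self.stride, self.q_floor = k, stride, q_floor

    def forward(self, x, training=False):
        n = x.shape[0]
        if self.k > min(x.shape[1], x.shape[2]):
            raise ValueError(
                f"kernel size {self.k} exceeds input spatial dims {x.shape[1:3]}"
            )
        wins = _windows(x, self.k, self.stride)      # (n,h',w',k,k,c)
        self._hp, self._wp = wins.shape[1:3]
        self._in_shape = x.shape
        flat = wins.reshape(n, self._hp * self._wp, -1)  # (n,P,L)
        W, q, p = self.params["W"], self.q, self.p
        self._flat = flat
        self._xnorm = np.linalg.norm(flat, axis=2)       # (n,P)
        self._wnorm = np.linalg.norm(W, axis=1)          # (U,)
        self._d = (self._xnorm[:, :, None] + q) * (self._wnorm + q)
        u = flat @ W.T                                   # (n,P,U)
        self._c = u / self._d
        absc = np.abs(self._c)
        self._s = np.sign(self._c) * absc ** p
        return self._s.reshape(n, self._hp, self._wp, -1)

    def backward(self, g):
        n = g.shape[0]
        g = g.reshape(n, self._hp * self._wp, -1)        # (n,P,U)
        W, q, p = self.params["W"], self.q, self.p
        flat, xnorm, wnorm = self._flat, self._xnorm, self._wnorm
        c, d, s = self._c, self._d, self._s
        absc = np.abs(c)
        safe = np.where(absc > 0, absc, 1.0)
        ds_dc = np.where(absc > 0, p * safe ** (p - 1.0), np.where(p == 1.0, 1.0, 0.0))
        dc = g * ds_dc
        du = dc / d
        dd = -dc * c / d
        self.grads = {"W": np.einsum("npu,npl->ul", du, flat)}
        dwnorm = np.einsum("npu,npu->u", dd, np.broadcast_to(
            xnorm[:, :, None] + q, dd.shape))
        self.grads["W"] += (dwnorm / wnorm)[:, None] * W
        if "q" in self.params:
            self.grads["q"] = np.einsum(
                "npu,npu->u", dd,
                np.broadcast_to(xnorm[:, :, None] + wnorm + 2 * q, dd.shape))
        if "p" in self.params:
            logc = np.where(absc > 0, np.log(safe), 0.0)
            self.grads["p"] = np.einsum("npu,npu->u", g, s * logc)
        # input gradient: through the dot product and through ||x||
        dflat = np.einsum("npu,ul->npl", du, W)
        dxnorm = np.einsum("npu,u->np", dd, wnorm + q)
        nz = xnorm > 0
        dflat += np.where(nz, dxnorm / np.where(nz, xnorm, 1.0), 0.0)[:, :, None] * flat
        dwin = dflat.reshape(n, self._hp, self._wp, self.k, self.k, -1)
        return _scatter_windows(dwin, self._in_shape, self.k, self.stride)

    def constrain(self):
        np.maximum(self.q, self.q_floor, out=self.q)
        np.maximum(self.p, 1.0, out=self.p)


class Sequential:
    """Plain layer stack with forward/backward and named parameters."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self):
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                yield f"{i}.{name}", layer, name, arr

    def n_parameters(self) -> int:
        return sum(arr.size for _, _, _, arr in self.parameters())

    def get_weights(self) -> dict[str, np.ndarray]:
        return {key: arr.copy() for key, _, _, arr in self.parameters()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for key, _, _, arr in self.parameters():
            arr[...] = weights[key]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class Adam:
    """Adam with bias correction; calls each layer's ``constrain`` after a step."""

    def __init__(self, model: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(a) for k, _, _, a in model.parameters()}
        self.v = {k: np.zeros_like(a) for k, _, _, a in model.parameters()}

    def step(self) -> None:
        self.t += 1
        for key, layer, name, arr in self.model.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            m = self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            v = self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
        for layer in self.model.layers:
            layer.constrain()
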