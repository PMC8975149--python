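"""Minimal neural-network toolkit with reverse-mode gradients.

Implements exactly the layers the model zoo in :mod:`canet.models`
needs -- 2-D and 3-D convolution, max pooling, dense layers, a gated
recurrent unit and batched slice-wise attention -- plus Glorot
initialisation, a fused softmax/cross-entropy loss and the Adam
optimiser.  Everything operates on float64 ``numpy`` arrays.

Convolutions use a shift-and-matmul scheme: for each kernel offset the
padded input is shifted and multiplied by the corresponding weight
slice.  This keeps peak memory at one copy of the activation (no im2col
buffer) while remaining BLAS-bound, which matters for the 3-D layers.

Layers cache forward activations when ``train=True``; a layer instance
is therefore not reentrant and backward must follow the matching
forward.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Sequential",
    "Conv2D",
    "Conv3D",
    "MaxPool2D",
    "MaxPool3D",
    "AvgPool2D",
    "AvgPool3D",
    "ReLU",
    "InputScale",
    "Flatten",
    "Dense",
    "GRU",
    "SliceAttention",
    "Adam",
    "glorot_uniform",
    "softmax",
    "cross_entropy",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform draw on [-sqrt(6/(fan_in+fan_out)), +]."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (max-subtracted)."""
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer ``labels`` under ``softmax(logits)``.

    Returns the scalar loss and the gradient w.r.t. the logits.
    """
    p = softmax(logits, axis=-1)
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.log(np.clip(p[np.arange(n), labels], eps, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Layer:
    """Base layer: a dict of parameters, a dict of their gradients."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def param_count(self):
        return sum(layer.param_count() for layer in self.layers)

    def named_params(self, prefix: str = ""):
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                out[f"{prefix}{i}.{k}"] = v
        return out

    def named_grads(self, prefix: str = ""):
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.grads.items():
                out[f"{prefix}{i}.{k}"] = v
        return out


class Conv2D(Layer):
    """k x k same-padded 2-D convolution (cross-correlation), stride 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan = c_in * k * k
        self.params = {
            "W": glorot_uniform(rng, (c_out, c_in, k, k), fan, c_out * k * k),
            "b": np.zeros(c_out),
        }

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        if C != self.c_in:
            raise ValueError(f"Conv2D expects {self.c_in} input channels, got {C}")
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        Wt = self.params["W"]
        y = np.zeros((B, self.c_out, H * W))
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i : i + H, j : j + W].reshape(B, C, H * W)
                y += np.matmul(Wt[:, :, i, j], xs)
        if train:
            self._cache = (xp, x.shape)
        return y.reshape(B, self.c_out, H, W) + self.params["b"][None, :, None, None]

    def backward(self, dy):
        xp, xshape = self._cache
        B, C, H, W = xshape
        k, p = self.k, self.k // 2
        dyf = dy.reshape(B, self.c_out, H * W)
        dyt = np.ascontiguousarray(dyf.transpose(1, 0, 2)).reshape(self.c_out, -1)
        Wt = self.params["W"]
        dW = np.zeros_like(Wt)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i : i + H, j : j + W].reshape(B, C, H * W)
                dW[:, :, i, j] = dyt @ xs.transpose(0, 2, 1).reshape(-1, C)
                dxp[:, :, i : i + H, j : j + W] += np.matmul(
                    Wt[:, :, i, j].T, dyf
                ).reshape(B, C, H, W)
        self.grads = {"W": dW, "b": dy.sum(axis=(0, 2, 3))}
        return dxp[:, :, p : p + H, p : p + W]


class Conv3D(Layer):
    """k x k x k same-padded 3-D convolution, stride 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan = c_in * k**3
        self.params = {
            "W": glorot_uniform(rng, (c_out, c_in, k, k, k), fan, c_out * k**3),
            "b": np.zeros(c_out),
        }

    def forward(self, x, train=False):
        B, C, D, H, W = x.shape
        if C != self.c_in:
            raise ValueError(f"Conv3D expects {self.c_in} input channels, got {C}")
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        Wt = self.params["W"]
        L = D * H * W
        y = np.zeros((B, self.c_out, L))
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = xp[:, :, i : i + D, j : j + H, l : l + W].reshape(B, C, L)
                    y += np.matmul(Wt[:, :, i, j, l], xs)
        if train:
            self._cache = (xp, x.shape)
        return y.reshape(B, self.c_out, D, H, W) + self.params["b"][None, :, None, None, None]

    def backward(self, dy):
        xp, xshape = self._cache
        B, C, D, H, W = xshape
        k, p = self.k, self.k // 2
        L = D * H * W
        dyf = dy.reshape(B, self.c_out, L)
        dyt = np.ascontiguousarray(dyf.transpose(1, 0, 2)).reshape(self.c_out, -1)
        Wt = self.params["W"]
        dW = np.zeros_like(Wt)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = xp[:, :, i : i + D, j : j + H, l : l + W].reshape(B, C, L)
                    dW[:, :, i, j, l] = dyt @ xs.transpose(0, 2, 1).reshape(-1, C)
                    dxp[:, :, i : i + D, j : j + H, l : l + W] += np.matmul(
                        Wt[:, :, i, j, l].T, dyf
                    ).reshape(B, C, D, H, W)
        self.grads = {"W": dW, "b": dy.sum(axis=(0, 2, 3, 4))}
        return dxp[:, :, p : p + D, p : p + H, p : p + W]


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/cols that do not fill a
    window are dropped (and receive zero gradient)."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        p = self.pool
        h2, w2 = H // p, W // p
        xw = (
            x[:, :, : h2 * p, : w2 * p]
            .reshape(B, C, h2, p, w2, p)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, h2, w2, p * p)
        )
        idx = xw.argmax(axis=-1)
        y = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, dy):
        idx, xshape = self._cache
        B, C, H, W = xshape
        p = self.pool
        h2, w2 = H // p, W // p
        dxw = np.zeros((B, C, h2, w2, p * p))
        np.put_along_axis(dxw, idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros(xshape)
        dx[:, :, : h2 * p, : w2 * p] = (
            dxw.reshape(B, C, h2, w2, p, p)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, h2 * p, w2 * p)
        )
        return dx


class AvgPool2D(Layer):
    """Non-overlapping average pooling; preserves areal (count-like)
    signal that max pooling discards."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        p = self.pool
        h2, w2 = H // p, W // p
        y = x[:, :, : h2 * p, : w2 * p].reshape(B, C, h2, p, w2, p).mean(axis=(3, 5))
        if train:
            self._shape = x.shape
        return y

    def backward(self, dy):
        B, C, H, W = self._shape
        p = self.pool
        h2, w2 = H // p, W // p
        dx = np.zeros(self._shape)
        dx[:, :, : h2 * p, : w2 * p] = np.repeat(
            np.repeat(dy, p, axis=2), p, axis=3
        ) / (p * p)
        return dx


class MaxPool3D(Layer):
    """Non-overlapping 3-D max pooling with a per-axis pool size, so an
    axis whose extent has shrunk to 1 can be left unpooled."""

    def __init__(self, pool: tuple[int, int, int] = (2, 2, 2)):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=False):
        B, C, D, H, W = x.shape
        pd, ph, pw = self.pool
        d2, h2, w2 = D // pd, H // ph, W // pw
        xw = (
            x[:, :, : d2 * pd, : h2 * ph, : w2 * pw]
            .reshape(B, C, d2, pd, h2, ph, w2, pw)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(B, C, d2, h2, w2, pd * ph * pw)
        )
        idx = xw.argmax(axis=-1)
        y = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, dy):
        idx, xshape = self._cache
        B, C, D, H, W = xshape
        pd, ph, pw = self.pool
        d2, h2, w2 = D // pd, H // ph, W // pw
        dxw = np.zeros((B, C, d2, h2, w2, pd * ph * pw))
        np.put_along_axis(dxw, idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros(xshape)
        dx[:, :, : d2 * pd, : h2 * ph, : w2 * pw] = (
            dxw.reshape(B, C, d2, h2, w2, pd, ph, pw)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(B, C, d2 * pd, h2 * ph, w2 * pw)
        )
        return dx


class AvgPool3D(Layer):
    """Non-overlapping 3-D average pooling with per-axis pool sizes."""

    def __init__(self, pool: tuple[int, int, int] = (2, 2, 2)):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=False):
        B, C, D, H, W = x.shape
        pd, ph, pw = self.pool
        d2, h2, w2 = D // pd, H // ph, W // pw
        y = (
            x[:, :, : d2 * pd, : h2 * ph, : w2 * pw]
            .reshape(B, C, d2, pd, h2, ph, w2, pw)
            .mean(axis=(3, 5, 7))
        )
        if train:
            self._shape = x.shape
        return y

    def backward(self, dy):
        B, C, D, H, W = self._shape
        pd, ph, pw = self.pool
        d2, h2, w2 = D // pd, H // ph, W // pw
        dx = np.zeros(self._shape)
        up = np.repeat(np.repeat(np.repeat(dy, pd, axis=2), ph, axis=3), pw, axis=4)
        dx[:, :, : d2 * pd, : h2 * ph, : w2 * pw] = up / (pd * ph * pw)
        return dx


class InputScale(Layer):
    """Fixed affine input standardisation, y = (x - shift) * scale."""

    def __init__(self, shift: float, scale: float):
        super().__init__()
        self.shift, self.scale = shift, scale

    def forward(self, x, train=False):
        return (x - self.shift) * self.scale

    def backward(self, dy):
        return dy * self.scale


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.d_in, self.d_out = d_in, d_out
        self.params = {
            "W": glorot_uniform(rng, (d_in, d_out), d_in, d_out),
            "b": np.zeros(d_out),
        }

    def forward(self, x, train=False):
        if x.shape[-1] != self.d_in:
            raise ValueError(f"Dense expects input width {self.d_in}, got {x.shape[-1]}")
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads = {"W": self._x.T @ dy, "b": dy.sum(axis=0)}
        return dy @ self.params["W"].T


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class GRU(Layer):
    """Single-layer unidirectional GRU over a (batch, steps, features)
    sequence; forward returns the final hidden state."""

    def __init__(self, d_in: int, width: int, rng: np.random.Generator):
        super().__init__()
        self.d_in, self.width = d_in, width
        p = {}
        for gate in ("z", "r", "h"):
            p[f"W{gate}"] = glorot_uniform(rng, (d_in, width), d_in, width)
            p[f"U{gate}"] = glorot_uniform(rng, (width, width), width, width)
            p[f"b{gate}"] = np.zeros(width)
        self.params = p

    def forward(self, x, train=False):
        B, N, D = x.shape
        p = self.params
        h = np.zeros((B, self.width))
        cache = []
        for t in range(N):
            xt = x[:, t, :]
            z = _sigmoid(xt @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = _sigmoid(xt @ p["Wr"] + h @ p["Ur"] + p["br"])
            c = np.tanh(xt @ p["Wh"] + (r * h) @ p["Uh"] + p["bh"])
            h_new = (1.0 - z) * h + z * c
            if train:
                cache.append((xt, h, z, r, c))
            h = h_new
        if train:
            self._cache = (cache, x.shape)
        return h

    def backward(self, dh):
        cache, xshape = self._cache
        B, N, D = xshape
        p = self.params
        g = {k: np.zeros_like(v) for k, v in p.items()}
        dx = np.zeros(xshape)
        for t in range(N - 1, -1, -1):
            xt, h_prev, z, r, c = cache[t]
            dz = dh * (c - h_prev)
            dc = dh * z
            dh_prev = dh * (1.0 - z)
            dah = dc * (1.0 - c * c)
            daz = dz * z * (1.0 - z)
            drh = dah @ p["Uh"].T
            dr = drh * h_prev
            dh_prev += drh * r
            dar = dr * r * (1.0 - r)
            g["Wh"] += xt.T @ dah
            g["Uh"] += (r * h_prev).T @ dah
            g["bh"] += dah.sum(axis=0)
            g["Wr"] += xt.T @ dar
            g["Ur"] += h_prev.T @ dar
            g["br"] += dar.sum(axis=0)
            g["Wz"] += xt.T @ daz
            g["Uz"] += h_prev.T @ daz
            g["bz"] += daz.sum(axis=0)
            dh_prev += dar @ p["Ur"].T + daz @ p["Uz"].T
            dx[:, t, :] = dah @ p["Wh"].T + dar @ p["Wr"].T + daz @ p["Wz"].T
            dh = dh_prev
        self.grads = g
        return dx


class SliceAttention(Layer):
    """Batched slice-wise attention pooling.

    Scores each slice feature with a shared affine map + tanh, softmax-
    normalises the scores along the slice axis and returns the weighted
    sum of slice features.  Exactly D + 1 trainable scalars.  The last
    forward pass stores the attention weights in :attr:`alpha` for
    inspection/visualisation.
    """

    def __init__(self, d_in: int, rng: np.random.Generator):
        super().__init__()
        self.d_in = d_in
        self.params = {
            "w": glorot_uniform(rng, (d_in,), d_in, 1),
            "b": np.zeros(1),
        }
        self.alpha: np.ndarray | None = None

    def forward(self, f, train=False):
        # f: (batch, slices, features)
        s = np.tanh(f @ self.params["w"] + self.params["b"][0])
        a = softmax(s, axis=1)
        d = np.einsum("bn,bnd->bd", a, f)
        self.alpha = a
        if train:
            self._cache = (f, s, a)
        return d

    def backward(self, dd):
        f, s, a = self._cache
        da = np.einsum("bd,bnd->bn", dd, f)
        df = a[:, :, None] * dd[:, None, :]
        ds = a * (da - (da * a).sum(axis=1, keepdims=True))
        dpre = ds * (1.0 - s * s)
        self.grads = {
            "w": np.einsum("bn,bnd->d", dpre, f),
            "b": np.array([dpre.sum()]),
        }
        df += dpre[:, :, None] * self.params["w"][None, None, :]
        return df


class Adam:
    """Adam optimiser over a flat name->array parameter dict.

    Updates arrays in place so that layer-held references stay valid.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
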