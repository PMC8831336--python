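"""Minimal numpy building blocks for densely-connected convolutional nets.

Implements exactly what the slice classifier needs — im2col convolutions,
ReLU, average pooling, dense (concatenative) layers, global average pooling,
a linear head, softmax cross-entropy with class weights, and an AdamW
optimizer. Tensors are NCHW float32. No batch normalization: the compact
backbone is shallow enough to train without it and inputs are z-scored.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "ReLU",
    "AvgPool2d",
    "GlobalAvgPool",
    "Linear",
    "DenseLayer",
    "Transition",
    "Flatten",
    "Network",
    "AdamW",
    "weighted_cross_entropy",
    "softmax",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d:
    """2-D convolution via im2col. Weight layout (out_ch, in_ch*k*k)."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1, pad: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.stride, self.pad = in_ch, out_ch, k, stride, pad
        self.w = Param(_he_init(rng, (out_ch, in_ch * k * k), in_ch * k * k))
        self.b = Param(np.zeros(out_ch, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def _cols(self, x: np.ndarray):
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (N, C, Ho, Wo, k, k)
        n, c, ho, wo = win.shape[:4]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        return np.ascontiguousarray(cols), (n, ho, wo, x.shape)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (n, ho, wo, padded_shape) = self._cols(x)
        out = cols @ self.w.value.T + self.b.value
        self._cache = (cols, n, ho, wo, padded_shape, x.shape)
        return out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols, n, ho, wo, padded_shape, x_shape = self._cache
        k, s, p = self.k, self.stride, self.pad
        gcols = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_ch)
        self.w.grad += gcols.T @ cols
        self.b.grad += gcols.sum(axis=0)
        dcols = (gcols @ self.w.value).reshape(n, ho, wo, self.in_ch, k, k)
        dxp = np.zeros(padded_shape, dtype=np.float32)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (N, C, Ho, Wo, k, k)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += dcols[:, :, :, :, i, j]
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        # stride>1 can leave trailing rows/cols of x unvisited; pad back to x shape
        if dxp.shape != x_shape:
            out = np.zeros(x_shape, dtype=np.float32)
            out[:, :, : dxp.shape[2], : dxp.shape[3]] = dxp
            dxp = out
        self._cache = None
        return dxp


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class AvgPool2d:
    """Non-overlapping average pooling; spatial dims must divide by k."""

    def __init__(self, k: int):
        self.k = k
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        if h % k or w % k:
            raise ValueError(f"spatial size {(h, w)} not divisible by pool size {k}")
        self._shape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, g: np.ndarray) -> np.ndarray:
        k = self.k
        g = g / (k * k)
        return np.repeat(np.repeat(g, k, axis=2), k, axis=3).reshape(self._shape)


class Flatten:
    """Flatten NCHW features to (N, C*H*W), keeping spatial identity.

    Used as the compact backbone's head: anatomy-guided crops are centered on
    the vertebral centroid, so absolute in-plane position is meaningful
    (aorta vs liver vs bone) and must survive into the linear classifier.
    """

    def __init__(self):
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class GlobalAvgPool:
    def __init__(self):
        self._hw = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, g: np.ndarray) -> np.ndarray:
        h, w = self._hw
        return np.broadcast_to(g[:, :, None, None], g.shape + (h, w)).copy() / (h * w)


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(_he_init(rng, (n_out, n_in), n_in))
        self.b = Param(np.zeros(n_out, dtype=np.float32))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.w.grad += g.T @ self._x
        self.b.grad += g.sum(axis=0)
        return g @ self.w.value


class DenseLayer:
    """One densely-connected layer: conv (optionally bottlenecked) + ReLU,
    output concatenated onto the input along channels."""

    def __init__(self, in_ch: int, growth: int, rng: np.random.Generator,
                 bottleneck: bool = False):
        self.in_ch, self.growth = in_ch, growth
        self.ops: list = []
        if bottleneck:
            self.ops = [
                Conv2d(in_ch, 4 * growth, k=1, pad=0, rng=rng),
                ReLU(),
                Conv2d(4 * growth, growth, k=3, pad=1, rng=rng),
                ReLU(),
            ]
        else:
            self.ops = [Conv2d(in_ch, growth, k=3, pad=1, rng=rng), ReLU()]
        self.out_ch = in_ch + growth

    def params(self):
        return [p for op in self.ops for p in op.params()]

    @property
    def n_convs(self) -> int:
        return sum(isinstance(op, Conv2d) for op in self.ops)

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for op in self.ops:
            h = op.forward(h)
        return np.concatenate([x, h], axis=1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        gx, gh = g[:, : self.in_ch], g[:, self.in_ch :]
        for op in reversed(self.ops):
            gh = op.backward(gh)
        return gx + gh


class Transition:
    """DenseNet transition: 1x1 conv channel reduction + ReLU + 2x2 avg pool."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv = Conv2d(in_ch, out_ch, k=1, pad=0, rng=rng)
        self.relu = ReLU()
        self.pool = AvgPool2d(2)
        self.out_ch = out_ch

    def params(self):
        return self.conv.params()

    def forward(self, x):
        return self.pool.forward(self.relu.forward(self.conv.forward(x)))

    def backward(self, g):
        return self.conv.backward(self.relu.backward(self.pool.backward(g)))


class Network:
    """A flat sequence of layers mapping (N,1,S,S) images to (N,3) logits."""

    def __init__(self, layers: list, name: str, input_size: int):
        self.layers = layers
        self.name = name
        self.input_size = input_size

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    @property
    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    @property
    def depth(self) -> int:
        """Number of weighted (conv/linear) layers."""
        d = 0
        for layer in self.layers:
            if isinstance(layer, Conv2d) or isinstance(layer, Linear):
                d += 1
            elif isinstance(layer, DenseLayer):
                d += layer.n_convs
            elif isinstance(layer, Transition):
                d += 1
        return d

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> None:
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.value[...] = w


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[Param], lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = params
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.value)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted categorical cross-entropy and its gradient w.r.t. logits.

    loss = mean_i  w[y_i] * (-log p_i[y_i]).  With balanced classes and unit
    weights this reduces to plain cross-entropy (ln 3 at uniform logits).
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    w = np.asarray(class_weights, dtype=np.float64)[y]
    nll = -np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    loss = float(np.mean(w * nll))
    grad = p
    grad[np.arange(n), y] -= 1.0
    grad *= (w / n)[:, None]
    return loss, grad.astype(np.float32)
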