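"""Minimal dense neural-network core: linear layers, SELU/sigmoid, Adam.

Everything the autoencoders need is a chain of affine maps with
element-wise activations, so forward passes and gradients are written
directly in numpy. Backward passes are exact (verified against finite
differences in the test suite), and all randomness flows through an
explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

SELU_ALPHA = 1.6732632423543772
SELU_LAMBDA = 1.0507009873554805


def selu(x: np.ndarray) -> np.ndarray:
    neg = np.minimum(x, 0.0)  # avoid exp overflow on the discarded branch
    return SELU_LAMBDA * np.where(x > 0, x, SELU_ALPHA * np.expm1(neg))


def selu_grad(x: np.ndarray) -> np.ndarray:
    neg = np.minimum(x, 0.0)
    return SELU_LAMBDA * np.where(x > 0, 1.0, SELU_ALPHA * np.exp(neg))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


_ACT = {
    "selu": (selu, selu_grad),
    "sigmoid": (sigmoid, None),  # gradient uses the stored output
    None: (lambda x: x, lambda x: np.ones_like(x)),
}


class Linear:
    """Affine map ``y = x W + b`` with LeCun-normal (fan-in) initialization.

    Fan-in scaled Gaussian initialization is the standard choice for
    self-normalizing (SELU) networks.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        self.W = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.gW[...] = self._x.T @ dy
        self.gb[...] = dy.sum(axis=0)
        return dy @ self.W.T

    @property
    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class MLP:
    """A stack of :class:`Linear` layers with per-layer activations."""

    def __init__(self, widths: list[int], activations: list[str | None],
                 rng: np.random.Generator, dtype=np.float32) -> None:
        if len(activations) != len(widths) - 1:
            raise ValueError("need one activation entry per layer")
        for name in activations:
            if name not in _ACT:
                raise ValueError(f"unknown activation {name!r}")
        self.widths = list(widths)
        self.activations = list(activations)
        self.layers = [
            Linear(widths[i], widths[i + 1], rng, dtype=dtype)
            for i in range(len(widths) - 1)
        ]
        self._pre: list[np.ndarray] = []
        self._post: list[np.ndarray] = []

    @property
    def n_in(self) -> int:
        return self.widths[0]

    @property
    def n_out(self) -> int:
        return self.widths[-1]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.n_in:
            raise ValueError(f"expected input of width {self.n_in}, got shape {x.shape}")
        self._pre, self._post = [], []
        h = x
        for layer, act in zip(self.layers, self.activations):
            z = layer.forward(h)
            self._pre.append(z)
            h = _ACT[act][0](z)
            self._post.append(h)
        return h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer, act, z, a in zip(self.layers[::-1], self.activations[::-1],
                                    self._pre[::-1], self._post[::-1]):
            if act == "sigmoid":
                dy = dy * a * (1.0 - a)
            else:
                dy = dy * _ACT[act][1](z)
            dy = layer.backward(dy)
        return dy

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def state(self) -> list[np.ndarray]:
        return [arr for layer in self.layers for arr in (layer.W, layer.b)]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        flat = [a for layer in self.layers for a in (layer.W, layer.b)]
        if len(arrays) != len(flat):
            raise ValueError("state size mismatch")
        for dst, src in zip(flat, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch {dst.shape} vs {src.shape}")
            dst[...] = src.astype(dst.dtype)


class Adam:
    """Adam optimizer over ``(param, grad)`` pairs (updates in place).

    Scratch buffers are preallocated and every update uses ``out=`` so a
    step allocates nothing — steps over many-million-parameter stacks are
    memory-bandwidth bound, not allocator bound.
    """

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self._buf = [np.empty_like(p) for p, _ in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for (p, g), m, v, buf in zip(self.params, self.m, self.v, self._buf):
            np.multiply(g, 1.0 - self.beta1, out=buf)
            m *= self.beta1
            m += buf
            np.multiply(g, g, out=buf)
            buf *= 1.0 - self.beta2
            v *= self.beta2
            v += buf
            np.divide(v, b2t, out=buf)
            np.sqrt(buf, out=buf)
            buf += self.eps
            np.divide(m, buf, out=buf)
            buf *= self.lr / b1t
            p -= buf
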