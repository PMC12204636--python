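"""Minimal CNN engine: the layers the sketch classifier needs, in numpy.

Forward and backward passes are written directly against numpy, with
convolutions expressed as k*k strided tensor contractions (cheap for the
3x3-and-smaller kernels used here).  Everything is deterministic given the
initialization seed; there is no threading or atomics-dependent reduction.

Only what the fire-module network requires is implemented: 2-D convolution,
ReLU, 2x2 max pooling, channel concatenation, global average pooling, softmax
cross-entropy, and Adam.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient and Adam state."""

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


class Conv2d:
    """Cross-correlation with bias; weight shape (out_c, in_c, k, k)."""

    def __init__(self, in_c: int, out_c: int, k: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_c * k * k
        scale = np.sqrt(2.0 / fan_in)  # He initialization (ReLU network)
        self.W = Param(rng.normal(0.0, scale, (out_c, in_c, k, k)))
        self.b = Param(np.zeros(out_c))
        self.k, self.stride, self.pad = k, stride, pad

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp = x
        n, c, h, w = x.shape
        ho = (h - k) // s + 1
        wo = (w - k) // s + 1
        out = np.broadcast_to(self.b.value[None, :, None, None],
                              (n, self.W.value.shape[0], ho, wo)).copy()
        for di in range(k):
            for dj in range(k):
                xs = x[:, :, di:di + s * ho:s, dj:dj + s * wo:s]
                out += np.einsum("ncij,oc->noij", xs, self.W.value[:, :, di, dj],
                                 optimize=True)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        x = self._xp
        n, c, h, w = x.shape
        ho, wo = grad.shape[2], grad.shape[3]
        self.b.grad += grad.sum(axis=(0, 2, 3))
        dx = np.zeros_like(x)
        for di in range(k):
            for dj in range(k):
                xs = x[:, :, di:di + s * ho:s, dj:dj + s * wo:s]
                self.W.grad[:, :, di, dj] += np.einsum("noij,ncij->oc", grad, xs,
                                                       optimize=True)
                dx[:, :, di:di + s * ho:s, dj:dj + s * wo:s] += np.einsum(
                    "noij,oc->ncij", grad, self.W.value[:, :, di, dj], optimize=True)
        if p:
            dx = dx[:, :, p:-p, p:-p]
        return dx


class ReLU:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2x2:
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        x = x[:, :, :2 * h2, :2 * w2]
        self._xshape = x.shape
        blocks = x.reshape(n, c, h2, 2, w2, 2)
        out = blocks.max(axis=(3, 5))
        self._mask = blocks == out[:, :, :, None, :, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self._mask * grad[:, :, :, None, :, None]
        # split ties evenly so gradient mass is conserved
        g = g / self._mask.sum(axis=(3, 5), keepdims=True)
        g = g.reshape(self._xshape)
        if self._xshape != self._in_shape:  # dropped odd row/col gets zero gradient
            full = np.zeros(self._in_shape)
            full[:, :, :self._xshape[2], :self._xshape[3]] = g
            return full
        return g


class GlobalAvgPool:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._spatial = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.broadcast_to(grad[:, :, None, None] / self._spatial, self._shape).copy()


class Fire:
    """Fire module: 1x1 squeeze, then parallel 1x1 and 3x3 expands, concatenated."""

    def __init__(self, in_c: int, squeeze: int, expand1: int, expand3: int,
                 rng: np.random.Generator):
        self.squeeze = Conv2d(in_c, squeeze, 1, rng=rng)
        self.sq_relu = ReLU()
        self.expand1 = Conv2d(squeeze, expand1, 1, rng=rng)
        self.expand3 = Conv2d(squeeze, expand3, 3, pad=1, rng=rng)
        self.ex_relu = ReLU()
        self.e1 = expand1

    def params(self) -> list[Param]:
        return self.squeeze.params() + self.expand1.params() + self.expand3.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.sq_relu.forward(self.squeeze.forward(x))
        out = np.concatenate([self.expand1.forward(s), self.expand3.forward(s)], axis=1)
        return self.ex_relu.forward(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.ex_relu.backward(grad)
        g1, g3 = grad[:, :self.e1], grad[:, self.e1:]
        gs = self.expand1.backward(g1) + self.expand3.backward(g3)
        return self.squeeze.backward(self.sq_relu.backward(gs))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(targets)
    loss = float(-np.log(np.clip(p[np.arange(n), targets], 1e-12, None)).mean())
    grad = p
    grad[np.arange(n), targets] -= 1.0
    return loss, grad / n


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for p in self.params:
            p.m = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1 - self.b2) * p.grad ** 2
            mhat = p.m / (1 - self.b1 ** self.t)
            vhat = p.v / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
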