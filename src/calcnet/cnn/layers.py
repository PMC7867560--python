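"""Minimal deterministic CPU layers for the 2.5D classifier.

Data layout is (N, C, H, W) float32.  Convolutions are 'valid', stride 1,
implemented as im2col + GEMM; their backward pass reuses the same machinery
(full correlation with flipped kernels for the input gradient).  Everything
is pure numpy, so a fixed seed gives bit-reproducible training on a given
BLAS build.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (C*k*k, N*OH*OW) patch matrix, channel-major.

    Built from k*k contiguous block copies, which is much faster than a
    strided gather for the small kernels used here.
    """
    n, c, h, w = x.shape
    oh, ow = h - k + 1, w - k + 1
    xc = x.transpose(1, 0, 2, 3)  # (C, N, H, W) view
    buf = np.empty((c, k, k, n, oh, ow), dtype=x.dtype)
    for di in range(k):
        for dj in range(k):
            buf[:, di, dj] = xc[:, :, di:di + oh, dj:dj + ow]
    return buf.reshape(c * k * k, n * oh * ow)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Valid convolution (cross-correlation), stride 1, He-initialised.

    `needs_input_grad=False` (set on the first layer of a network) skips
    the input-gradient pass, which is the single most expensive step of
    backprop and useless at the input.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, needs_input_grad: bool = True
                 ) -> None:
        super().__init__()
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        self.needs_input_grad = needs_input_grad
        fan_in = in_channels * kernel * kernel
        self.W = rng.normal(0, np.sqrt(2.0 / fan_in),
                            size=(fan_in, out_channels)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._in_shape = x.shape
        self._oh, self._ow = h - self.k + 1, w - self.k + 1
        cols = _im2col(x, self.k)  # (cin*k*k, n*oh*ow)
        self._cols = cols
        out = self.W.T @ cols  # (cout, n*oh*ow)
        out += self.b[:, None]
        return np.ascontiguousarray(
            out.reshape(self.cout, n, self._oh, self._ow).transpose(1, 0, 2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        n = dout.shape[0]
        dflat = np.ascontiguousarray(dout.transpose(1, 0, 2, 3)).reshape(
            self.cout, -1)  # (cout, n*oh*ow)
        self.grads[0][...] = self._cols @ dflat.T
        self.grads[1][...] = dflat.sum(axis=1)
        if not self.needs_input_grad:
            return None
        # input gradient: full correlation of dout with spatially flipped W
        pad = self.k - 1
        dpad = np.pad(dout, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        Wk = self.W.reshape(self.cin, self.k, self.k, self.cout)
        Wflip = Wk[:, ::-1, ::-1, :]  # flip spatial dims
        # kernel for the transposed op: (cin, cout*k*k)
        Wt = Wflip.transpose(0, 3, 1, 2).reshape(self.cin,
                                                 self.cout * self.k * self.k)
        cols = _im2col(dpad, self.k)  # (cout*k*k, n*h*w)
        dx = Wt @ cols
        h, w = self._in_shape[2], self._in_shape[3]
        return np.ascontiguousarray(
            dx.reshape(self.cin, n, h, w).transpose(1, 0, 2, 3))


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._m = x > 0
        return x * self._m

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._m


class AvgPool2D(Layer):
    """Non-overlapping average pooling; trailing rows/cols are dropped."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.s = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.s
        self._in_shape = x.shape
        oh, ow = h // s, w // s
        out = np.zeros((n, c, oh, ow), dtype=x.dtype)
        for di in range(s):
            for dj in range(s):
                out += x[:, :, di:oh * s:s, dj:ow * s:s]
        out *= 1.0 / (s * s)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        s = self.s
        oh, ow = dout.shape[2], dout.shape[3]
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        up = np.repeat(np.repeat(dout, s, axis=2), s, axis=3) / (s * s)
        dx[:, :, :oh * s, :ow * s] = up
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; active only when `train_mode` is set by the
    training loop.  Own seeded generator keeps runs reproducible."""

    def __init__(self, rate: float, seed: int = 0) -> None:
        super().__init__()
        self.rate = float(rate)
        self.seed = int(seed)
        self.rng = np.random.default_rng(seed)
        self.train_mode = False

    def reset(self) -> None:
        self.rng = np.random.default_rng(self.seed)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.train_mode or self.rate <= 0:
            self._m = None
            return x
        keep = 1.0 - self.rate
        self._m = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._m

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._m is None else dout * self._m


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = rng.normal(0, np.sqrt(2.0 / n_in),
                            size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray,
                          weights: np.ndarray | None = None
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(targets)
    eps = 1e-12
    ll = -np.log(p[np.arange(n), targets] + eps)
    if weights is None:
        loss = float(ll.mean())
        g = p.copy()
        g[np.arange(n), targets] -= 1.0
        g /= n
    else:
        wsum = float(weights.sum())
        loss = float((weights * ll).sum() / wsum)
        g = p * weights[:, None]
        g[np.arange(n), targets] -= weights
        g /= wsum
    return loss, g.astype(np.float32)


class Adam:
    """Adaptive-moment optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay > 0 and p.ndim > 1:  # decoupled, skip biases
                p -= self.lr * self.weight_decay * p
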