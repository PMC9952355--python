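"""A compact CPU layer stack for the cascade networks.

Layers store their parameters and caches, expose ``forward(x)`` and
``backward(grad_out)`` (which accumulates parameter gradients and returns the
gradient with respect to the input), and are composed explicitly by the
network classes.  Everything runs in float32; convolutions are lowered to
batched BLAS matmuls through im2col.  Tensor layout is (N, C, H, W).
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    training: bool = True

    def params(self) -> list[Param]:
        return []

    def set_training(self, flag: bool) -> None:
        self.training = flag


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C, k*k, H*W) patch matrix (stride 1)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, C, k*k, H*W)
    return np.ascontiguousarray(
        win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c, k * k, h * w)
    )


def _col2im(dcols: np.ndarray, k: int, pad: int, h: int, w: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add (N, C, k*k, H*W) back to (N, C, H, W)."""
    n, c = dcols.shape[:2]
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, c, k, k, h, w)
    for dy in range(k):
        for dx in range(k):
            dxp[:, :, dy : dy + h, dx : dx + w] += d[:, :, dy, dx]
    return dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp


class Conv2d(Layer):
    """3x3 (or kxk) stride-1 convolution with zero padding k//2."""

    def __init__(self, cin: int, cout: int, k: int = 3, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        scale = np.sqrt(2.0 / fan_in)  # He initialization
        self.w = Param(rng.normal(0.0, scale, (cout, cin, k, k)))
        self.b = Param(np.zeros(cout)) if bias else None
        self.k, self.pad = k, k // 2
        self.cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k, self.pad).reshape(n, c * self.k**2, h * w)
        w2 = self.w.data.reshape(self.w.data.shape[0], -1)
        y = np.matmul(w2, cols)  # (N, Cout, H*W)
        if self.b is not None:
            y += self.b.data[None, :, None]
        self.cache = (cols, (n, c, h, w))
        return y.reshape(n, -1, h, w)

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self.cache
        g2 = g.reshape(n, -1, h * w)
        w2 = self.w.data.reshape(self.w.data.shape[0], -1)
        self.w.grad += np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0).reshape(
            self.w.data.shape
        )
        if self.b is not None:
            self.b.grad += g2.sum(axis=(0, 2))
        dcols = np.matmul(w2.T, g2).reshape(n, c, self.k**2, h * w)
        return _col2im(dcols, self.k, self.pad, h, w)


class DepthwiseConv2d(Layer):
    """Per-channel spatial convolution: each input channel gets ``mult``
    kxk kernels, producing cin*mult output maps (channel-major order)."""

    def __init__(self, cin: int, mult: int, k: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (k * k))
        self.w = Param(rng.normal(0.0, scale, (cin, mult, k * k)))
        self.cin, self.mult, self.k, self.pad = cin, mult, k, k // 2
        self.cache = None

    def params(self):
        return [self.w]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)  # (N, C, kk, HW)
        # batched per-channel (mult, kk) @ (kk, HW) -> (N, C, mult, HW)
        y = np.matmul(self.w.data[None], cols)
        self.cache = (cols, (n, c, h, w))
        return y.reshape(n, c * self.mult, h, w)

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self.cache
        g4 = g.reshape(n, c, self.mult, h * w)
        self.w.grad += np.matmul(g4, cols.transpose(0, 1, 3, 2)).sum(axis=0)
        dcols = np.matmul(self.w.data.transpose(0, 2, 1)[None], g4)
        return _col2im(dcols, self.k, self.pad, h, w)


class ConvTranspose2d(Layer):
    """2x2 stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / cin)
        self.w = Param(rng.normal(0.0, scale, (cin, cout * 4)))
        self.b = Param(np.zeros(cout))
        self.cin, self.cout = cin, cout
        self.cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        x2 = x.reshape(n, c, h * w).transpose(0, 2, 1)  # (N, HW, Cin)
        y = np.matmul(x2, self.w.data)  # (N, HW, Cout*4)
        y = y.reshape(n, h, w, self.cout, 2, 2).transpose(0, 3, 1, 4, 2, 5)
        y = np.ascontiguousarray(y).reshape(n, self.cout, 2 * h, 2 * w)
        y += self.b.data[None, :, None, None]
        self.cache = (x2, (n, c, h, w))
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        x2, (n, c, h, w) = self.cache
        self.b.grad += g.sum(axis=(0, 2, 3))
        g6 = g.reshape(n, self.cout, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        g2 = np.ascontiguousarray(g6).reshape(n, h * w, self.cout * 4)
        self.w.grad += np.matmul(x2.transpose(0, 2, 1), g2).sum(axis=0)
        dx2 = np.matmul(g2, self.w.data.T)  # (N, HW, Cin)
        return dx2.transpose(0, 2, 1).reshape(n, c, h, w)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with affine terms and running stats."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self.cache = None
        self._accum: list[tuple[np.ndarray, np.ndarray]] | None = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self._accum is not None:
                self._accum.append((mean, var))
            else:
                self.running_mean += self.momentum * (mean - self.running_mean)
                self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self.cache = (xhat, invstd)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[
            None, :, None, None
        ]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, invstd = self.cache
        self.gamma.grad += (g * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += g.sum(axis=(0, 2, 3))
        if not self.training:
            return g * (self.gamma.data * invstd)[None, :, None, None]
        m = g.shape[0] * g.shape[2] * g.shape[3]
        gg = g * self.gamma.data[None, :, None, None]
        sum_gg = gg.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (gg * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return invstd[None, :, None, None] * (gg - (sum_gg + xhat * sum_gx) / m)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.mask = x > 0
        return np.where(self.mask, x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self.mask, g, 0.0)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        x6 = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x5 = np.ascontiguousarray(x6).reshape(n, c, h // 2, w // 2, 4)
        self.idx = x5.argmax(axis=-1)
        self.shape = (n, c, h, w)
        return np.take_along_axis(x5, self.idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self.shape
        dx5 = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(dx5, self.idx[..., None], g[..., None], axis=-1)
        dx6 = dx5.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx6).reshape(n, c, h, w)


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling (parameter-free)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = g.shape
        return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def set_training(self, flag: bool) -> None:
        for l in self.layers:
            l.set_training(flag)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad.fill(0.0)

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad**2 - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def iter_batchnorms(net: Layer):
    """All BatchNorm2d layers reachable through the standard containers."""
    out, stack, seen = [], [net], set()
    while stack:
        m = stack.pop()
        if id(m) in seen:
            continue
        seen.add(id(m))
        if isinstance(m, BatchNorm2d):
            out.append(m)
        for attr in ("layers", "_modules", "enc", "pools", "dec", "ups"):
            stack.extend(getattr(m, attr, []) or [])
        for attr in ("body", "bottleneck", "head", "op"):
            sub = getattr(m, attr, None)
            if isinstance(sub, Layer):
                stack.append(sub)
    return out


def recalibrate_batchnorm(net: Layer, x: np.ndarray, batch_size: int = 64) -> None:
    """Re-estimate batch-norm running statistics with the final weights.

    During a short training run the exponential running averages lag the
    (fast-moving) weights, so inference-mode normalization can drift far from
    what the layers saw in training.  One frozen-weight pass over the data
    replaces the running statistics with exact aggregates: mean of batch
    means and, by the law of total variance, mean of batch variances plus
    the variance of batch means.
    """
    bns = iter_batchnorms(net)
    for bn in bns:
        bn._accum = []
    net.set_training(True)
    try:
        for start in range(0, len(x), batch_size):
            net.forward(x[start : start + batch_size])
    finally:
        net.set_training(False)
        for bn in bns:
            if bn._accum:
                means = np.stack([m for m, _ in bn._accum])
                varis = np.stack([v for _, v in bn._accum])
                bn.running_mean[...] = means.mean(axis=0)
                bn.running_var[...] = varis.mean(axis=0) + means.var(axis=0)
            bn._accum = None


def count_parameters(net: Layer) -> int:
    """Number of trainable scalars, including batch-norm affine terms."""
    return int(sum(p.size for p in net.params()))
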