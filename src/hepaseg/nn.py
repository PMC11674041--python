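"""Minimal CNN engine: layers with explicit forward/backward passes.

Implements exactly the operations the segmentation U-nets need — 2D
convolution (odd kernels, "same" padding, stride 1), batch normalization,
leaky ReLU, 2x2 max pooling at stride 2 (between blocks) and stride 1 with
edge padding (inside blocks), 2x2 stride-2 transposed convolution, channel
concatenation, separable bilinear resampling, sigmoid, binary cross-entropy
and Adam — on float32 NCHW arrays.

Every layer caches what its backward pass needs only when ``train=True``,
so inference on large inputs stays memory-light.  All gradients are exact
(validated against central finite differences in the test suite).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Module", "Conv2d", "BatchNorm2d", "LeakyReLU", "MaxPool2x2",
    "MaxPoolSame2x2", "UpConv2x2", "Sequential", "Concat", "BilinearUpsample",
    "sigmoid", "bce_with_logits_grad", "Adam", "glorot_uniform",
]

_F32 = np.float32


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_F32)


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(_F32)
        self.grad = np.zeros_like(self.value)


class Module:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad.fill(0.0)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Module):
    """k x k convolution, stride 1, zero-padded "same" output, odd k.

    Weights (out_ch, in_ch, k, k) Glorot-uniform, bias zero.  The spatial
    loop runs over the k*k taps with one batched matmul each, which keeps
    peak memory at one activation copy instead of an im2col buffer.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1 or kernel < 1:
            raise ValueError(f"Conv2d kernel must be odd, got {kernel}")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in, fan_out = in_ch * kernel * kernel, out_ch * kernel * kernel
        self.W = Param(glorot_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in, fan_out))
        self.b = Param(np.zeros(out_ch))
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        if k == 1:
            xp = x
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp = xp if train else None
        y = np.empty((n, self.out_ch, h * w), dtype=_F32)
        y[:] = self.b.value[None, :, None]
        Wf = self.W.value
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i : i + h, j : j + w].reshape(n, c, h * w)
                y += np.matmul(Wf[:, :, i, j], xs)
        return y.reshape(n, self.out_ch, h, w)

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._xp is None:
            raise RuntimeError("backward called without a train-mode forward")
        n, o, h, w = g.shape
        k = self.k
        xp = self._xp
        gf = g.reshape(n, o, h * w)
        self.b.grad += gf.sum(axis=(0, 2))
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i : i + h, j : j + w]
                self.W.grad[:, :, i, j] += np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
                gxs = np.matmul(self.W.value[:, :, i, j].T, gf).reshape(n, self.in_ch, h, w)
                gxp[:, :, i : i + h, j : j + w] += gxs
        self._xp = None
        if k == 1:
            return gxp
        p = k // 2
        return gxp[:, :, p : p + h, p : p + w]


class BatchNorm2d(Module):
    """Per-channel batch normalization with learnable scale/shift.

    Training uses batch statistics and updates exponential moving averages
    (momentum 0.99, epsilon 1e-3 — the framework-conventional defaults);
    inference uses the moving averages.  The averages are stored
    zero-initialized together with an update counter and read back
    initialization-debiased (divided by 1 - momentum^t, the same correction
    Adam applies to its moments): without it, short trainings — a few
    hundred steps — would do inference with statistics still biased toward
    the arbitrary start values.  An untrained layer falls back to mean 0,
    variance 1.
    """

    def __init__(self, ch: int, momentum: float = 0.99, eps: float = 1e-3):
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.moving_mean = np.zeros(ch, dtype=_F32)
        self.moving_var = np.zeros(ch, dtype=_F32)
        self.updates = 0
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def inference_stats(self) -> tuple[np.ndarray, np.ndarray]:
        if self.updates == 0:
            return np.zeros(self.ch, dtype=_F32), np.ones(self.ch, dtype=_F32)
        debias = 1.0 - self.momentum**self.updates
        return self.moving_mean / debias, self.moving_var / debias

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.moving_mean = (self.momentum * self.moving_mean
                                + (1 - self.momentum) * mean).astype(_F32)
            self.moving_var = (self.momentum * self.moving_var
                               + (1 - self.momentum) * var).astype(_F32)
            self.updates += 1
        else:
            mean, var = self.inference_stats()
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None]).astype(_F32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a train-mode forward")
        xhat, inv_std = self._cache
        self._cache = None
        m = g.shape[0] * g.shape[2] * g.shape[3]
        self.beta.grad += g.sum(axis=(0, 2, 3))
        self.gamma.grad += (g * xhat).sum(axis=(0, 2, 3))
        gxhat = g * self.gamma.value[None, :, None, None]
        # standard batch-norm gradient through the batch statistics
        gx = (gxhat
              - gxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return (gx * inv_std[None, :, None, None]).astype(_F32)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.3):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x).astype(_F32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            raise RuntimeError("backward called without a train-mode forward")
        gx = np.where(self._mask, g, self.slope * g).astype(_F32)
        self._mask = None
        return gx


class MaxPool2x2(Module):
    """2x2 max pooling, stride 2 (the between-block downsampling). Requires
    even spatial dims; gradient routes to the first maximal element."""

    def __init__(self):
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2x2 needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        am = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, am[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (am, (n, c, h, w))
        return y.astype(_F32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a train-mode forward")
        am, (n, c, h, w) = self._cache
        self._cache = None
        gxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=_F32)
        np.put_along_axis(gxr, am[..., None], g[..., None].astype(_F32), axis=-1)
        gx = gxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return gx.reshape(n, c, h, w)


class MaxPoolSame2x2(Module):
    """2x2 max pooling, stride 1, edge-replicated on the bottom/right so the
    output keeps the input's spatial size (the in-block pool branch)."""

    def __init__(self):
        self._cache: tuple | None = None

    @staticmethod
    def _candidates(x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (0, 1), (0, 1)), mode="edge")
        return np.stack([xp[:, :, di : di + h, dj : dj + w]
                         for di in (0, 1) for dj in (0, 1)])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cand = self._candidates(x)
        am = cand.argmax(axis=0)
        y = np.take_along_axis(cand, am[None], axis=0)[0]
        if train:
            self._cache = (am, x.shape)
        return y.astype(_F32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a train-mode forward")
        am, (n, c, h, w) = self._cache
        self._cache = None
        gxp = np.zeros((n, c, h + 1, w + 1), dtype=_F32)
        for idx, (di, dj) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
            gxp[:, :, di : di + h, dj : dj + w] += np.where(am == idx, g, 0.0)
        gx = gxp[:, :, :h, :w].copy()
        gx[:, :, h - 1, :] += gxp[:, :, h, :w]
        gx[:, :, :, w - 1] += gxp[:, :, :h, w]
        gx[:, :, h - 1, w - 1] += gxp[:, :, h, w]
        return gx


class UpConv2x2(Module):
    """2x2 transposed convolution with stride 2: each input pixel expands to
    a 2x2 output patch, doubling the spatial dims."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in, fan_out = in_ch * 4, out_ch * 4
        self.W = Param(glorot_uniform(rng, (2, 2, out_ch, in_ch), fan_in, fan_out))
        self.b = Param(np.zeros(out_ch))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        self._x = x if train else None
        xf = x.reshape(n, c, h * w)
        y = np.empty((n, self.out_ch, 2 * h, 2 * w), dtype=_F32)
        for di in (0, 1):
            for dj in (0, 1):
                y[:, :, di::2, dj::2] = np.matmul(
                    self.W.value[di, dj], xf
                ).reshape(n, self.out_ch, h, w)
        y += self.b.value[None, :, None, None]
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("backward called without a train-mode forward")
        x = self._x
        self._x = None
        n, c, h, w = x.shape
        self.b.grad += g.sum(axis=(0, 2, 3))
        gx = np.zeros_like(x)
        for di in (0, 1):
            for dj in (0, 1):
                gs = g[:, :, di::2, dj::2]
                self.W.grad[di, dj] += np.tensordot(gs, x, axes=([0, 2, 3], [0, 2, 3]))
                gx += np.matmul(
                    self.W.value[di, dj].T, gs.reshape(n, self.out_ch, h * w)
                ).reshape(n, c, h, w)
        return gx


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class Concat(Module):
    """Channel concatenation of parallel branches applied to one input;
    the backward pass splits the gradient and sums the branch inputs."""

    def __init__(self, branches: list[Module]):
        self.branches = branches
        self._splits: list[int] | None = None

    def params(self) -> list[Param]:
        return [p for b in self.branches for p in b.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        outs = [b.forward(x, train=train) for b in self.branches]
        self._splits = [o.shape[1] for o in outs] if train else None
        return np.concatenate(outs, axis=1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._splits is None:
            raise RuntimeError("backward called without a train-mode forward")
        edges = np.cumsum(self._splits)[:-1]
        self._splits = None
        gs = np.split(g, edges, axis=1)
        gx = self.branches[0].backward(gs[0])
        for b, gb in zip(self.branches[1:], gs[1:]):
            gx = gx + b.backward(gb)
        return gx


def _interp_matrix(n_in: int, factor: int) -> np.ndarray:
    """1D bilinear interpolation matrix (n_in*factor, n_in), half-pixel
    centers, edges clamped. Resizing is separable: Y = A @ X @ B.T."""
    n_out = n_in * factor
    A = np.zeros((n_out, n_in), dtype=_F32)
    for i in range(n_out):
        src = (i + 0.5) / factor - 0.5
        lo = int(np.floor(src))
        t = src - lo
        lo_c, hi_c = min(max(lo, 0), n_in - 1), min(max(lo + 1, 0), n_in - 1)
        A[i, lo_c] += 1.0 - t
        A[i, hi_c] += t
    return A


class BilinearUpsample(Module):
    """Parameter-free bilinear upsampling by an integer factor, realized as
    two separable linear maps so the backward pass is the exact adjoint."""

    def __init__(self, factor: int):
        self.factor = factor
        self._mats: dict[int, np.ndarray] = {}
        self._shape: tuple | None = None

    def _mat(self, n_in: int) -> np.ndarray:
        if n_in not in self._mats:
            self._mats[n_in] = _interp_matrix(n_in, self.factor)
        return self._mats[n_in]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if train:
            self._shape = x.shape
        A, B = self._mat(h), self._mat(w)
        y = np.einsum("ph,nchw,qw->ncpq", A, x, B, optimize=True)
        return y.astype(_F32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._shape is None:
            raise RuntimeError("backward called without a train-mode forward")
        n, c, h, w = self._shape
        self._shape = None
        A, B = self._mat(h), self._mat(w)
        gx = np.einsum("ph,ncpq,qw->nchw", A, g, B, optimize=True)
        return gx.astype(_F32)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=_F32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits_grad(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy evaluated stably from logits, and its exact
    gradient with respect to the logits: (sigmoid(z) - y) / n."""
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    # log(1 + e^z) computed stably as max(z,0) + log1p(e^{-|z|})
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = ((sigmoid(logits) - targets.astype(_F32)) / logits.size).astype(_F32)
    return float(loss), grad


class Adam:
    """Adam optimizer over a parameter list (beta1 0.9, beta2 0.999)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad.fill(0.0)
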