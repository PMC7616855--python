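"""Minimal convolutional-network backend on numpy.

Implements exactly the pieces the residual classifiers here need: 2-d
convolution with "same" padding, batch normalization, ReLU, global average
pooling, a dense classifier head, softmax cross-entropy and SGD with
momentum.  Forward and backward passes are written by hand; convolutions
are evaluated as a sum over kernel offsets of strided-slice matmuls, which
is efficient for the small kernels (1/3/5) used throughout.

Tensors are float32 in NHWC (channels-last) layout inside the backend —
convolutions then reduce to contiguous matrix products — while the
package-level APIs speak NCHW and convert at the boundary.  Every module
caches what its backward pass needs during ``forward(..., training=True)``;
call order must be forward-then-backward per batch.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Identity",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "SGD",
]


class Parameter:
    """A trainable array with its gradient and momentum buffer."""

    def __init__(self, data: np.ndarray) -> None:
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.vel = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: tracks child modules and parameters by attribute name."""

    def __init__(self) -> None:
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out = {prefix + n: p for n, p in self._params.items()}
        for n, m in self._modules.items():
            out.update(m.named_parameters(prefix + n + "."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def extra_state(self) -> dict[str, np.ndarray]:
        """Non-trainable buffers (e.g. batch-norm running stats)."""
        return {}

    def _named_buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self.extra_state().items()}
        for n, m in self._modules.items():
            out.update(m._named_buffers(prefix + n + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {n: p.data.copy() for n, p in self.named_parameters().items()}
        d.update(self._named_buffers())
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters().items():
            p.data[...] = d[n]
        self._load_buffers(d, "")

    def _load_buffers(self, d, prefix) -> None:
        for k in self.extra_state():
            getattr(self, k)[...] = d[prefix + k]
        for n, m in self._modules.items():
            m._load_buffers(d, prefix + n + ".")

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x, training: bool = False):
        return self.forward(x, training=training)


def _he_uniform(shape, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2d(Module):
    """2-d convolution, "same" padding by default, optional stride, no bias.

    "same" means padding of (k-1)//2 per side so the output grid is
    ceil(H/stride) x ceil(W/stride); kernels are expected to be odd.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError(f"kernel must be odd and >= 1, got {kernel}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        self.pad = (kernel - 1) // 2
        self.weight = Parameter(
            _he_uniform((out_ch, in_ch, kernel, kernel), in_ch * kernel * kernel, rng))

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        k, s, p = self.kernel, self.stride, self.pad
        wgt = self.weight.data
        if k == 1:  # pointwise: a single matrix product, no padding
            xs = x[:, ::s, ::s, :]
            y = xs.reshape(-1, c) @ wgt[:, :, 0, 0].T
            if training:
                self._cache = (x, x.shape, xs.shape[1], xs.shape[2])
            return y.reshape(xs.shape[0], xs.shape[1], xs.shape[2],
                             self.out_ch)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        acc = np.zeros((n, ho, wo, self.out_ch), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                xs = xp[:, di:di + s * ho:s, dj:dj + s * wo:s, :]
                # (N,Ho,Wo,C) x (C,O) -> accumulate (N,Ho,Wo,O)
                acc += np.tensordot(xs, wgt[:, :, di, dj], axes=([3], [1]))
        if training:
            self._cache = (xp, x.shape, ho, wo)
        return acc

    def backward(self, dy):
        xp, xshape, ho, wo = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        wgt = self.weight.data
        if k == 1:
            xs = xp[:, ::s, ::s, :]
            dyf = dy.reshape(-1, self.out_ch)
            self.weight.grad[:, :, 0, 0] += dyf.T @ xs.reshape(-1, self.in_ch)
            dxs = (dyf @ wgt[:, :, 0, 0]).reshape(
                dy.shape[0], dy.shape[1], dy.shape[2], self.in_ch)
            if s == 1:
                return dxs
            dx = np.zeros(xshape, dtype=np.float32)
            dx[:, ::s, ::s, :] = dxs
            return dx
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                xs = xp[:, di:di + s * ho:s, dj:dj + s * wo:s, :]
                self.weight.grad[:, :, di, dj] += np.tensordot(
                    dy, xs, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, di:di + s * ho:s, dj:dj + s * wo:s, :] += np.tensordot(
                    dy, wgt[:, :, di, dj], axes=([3], [0]))
        if p:
            return dxp[:, p:-p, p:-p, :]
        return dxp


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.gamma = Parameter(np.ones(ch, dtype=np.float32))
        self.beta = Parameter(np.zeros(ch, dtype=np.float32))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def extra_state(self):
        return {"running_mean": self.running_mean.copy(),
                "running_var": self.running_var.copy()}

    def forward(self, x, training=False):
        if training:
            # single-pass channel statistics via BLAS reductions
            x2d = x.reshape(-1, self.ch)
            m_count = x2d.shape[0]
            ones = np.ones(m_count, dtype=np.float32)
            mean = (ones @ x2d) / m_count
            sq = np.einsum("nc,nc->c", x2d, x2d, dtype=np.float32) / m_count
            var = np.maximum(sq - mean * mean, 0.0)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        # fused affine: y = x * scale + shift
        scale = self.gamma.data * invstd
        shift = self.beta.data - mean * scale
        y = x * scale + shift
        if training:
            self._cache = (x, mean, invstd)
        return y

    def backward(self, dy):
        x, mean, invstd = self._cache
        n = dy.size // self.ch
        dy2d = dy.reshape(-1, self.ch)
        x2d = x.reshape(-1, self.ch)
        ones = np.ones(n, dtype=np.float32)
        dbeta = ones @ dy2d
        cross = np.einsum("nc,nc->c", dy2d, x2d, dtype=np.float32)
        dgamma = (cross - mean * dbeta) * invstd
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        coef = self.gamma.data * invstd
        g2 = coef * invstd * dgamma / n
        bias = g2 * mean - coef * dbeta / n
        return coef * dy - g2 * x + bias


class ReLU(Module):
    def forward(self, x, training=False):
        y = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask


class Identity(Module):
    def forward(self, x, training=False):
        return x

    def backward(self, dy):
        return dy


class GlobalAvgPool(Module):
    """(N,H,W,C) -> (N,C) spatial mean."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2), dtype=np.float32)

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :], self._shape) / (h * w)


class Dense(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Parameter(_he_uniform((in_dim, out_dim), in_dim, rng))
        self.bias = Parameter(np.zeros(out_dim, dtype=np.float32))

    def forward(self, x, training=False):
        if training:
            self._x = x
        return x @ self.weight.data + self.bias.data

    def backward(self, dy):
        self.weight.grad += self._x.T @ dy
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data.T


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, lyr in enumerate(layers):
            setattr(self, f"l{i}", lyr)

    def forward(self, x, training=False):
        for lyr in self.layers:
            x = lyr.forward(x, training=training)
        return x

    def backward(self, dy):
        for lyr in reversed(self.layers):
            dy = lyr.backward(dy)
        return dy


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Parameter], momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay

    def step(self, lr: float) -> None:
        for p in self.params:
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            p.vel[...] = self.momentum * p.vel + g
            p.data -= lr * p.vel
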