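"""Minimal CPU neural-network layers with explicit backpropagation.

All tensors are float32 numpy arrays in NCHW layout.  Each layer exposes
``forward(x, train)``, ``backward(grad_out) -> grad_in``, ``params()`` and
``buffers()``; gradients accumulate into ``Param.grad`` and are consumed by
the optimizer.  Convolution kernels carry ``decay=True`` so that L2
regularization can be restricted to them.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool = False, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.decay = decay
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        return {}


class Conv2d(Layer):
    """k x k same-padded convolution (k in {1, 3}) via im2col."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, k: int = 3, name: str = "conv"):
        if k not in (1, 3):
            raise ValueError("kernel size must be 1 or 3")
        self.cin, self.cout, self.k = cin, cout, k
        std = np.sqrt(2.0 / (cin * k * k))
        self.weight = Param(rng.normal(0.0, std, (cin * k * k, cout)), decay=True, name=f"{name}.weight")
        self.bias = Param(np.zeros(cout), decay=False, name=f"{name}.bias")
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        # (n, c, h, w, k, k) -> (n, h, w, c*k*k)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        cols = np.ascontiguousarray(cols, dtype=DTYPE)
        out = cols @ self.weight.value + self.bias.value
        if train:
            self._cols = cols
            self._shape = (n, c, h, w)
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        k, p = self.k, self.k // 2
        gf = np.ascontiguousarray(grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout), dtype=DTYPE)
        self.weight.grad += self._cols.T @ gf
        self.bias.grad += gf.sum(axis=0)
        dcols = (gf @ self.weight.value.T).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class MaxPool2d(Layer):
    """2x2 max pooling; input height/width must be even."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = (n, c, h, w)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(gr, self._idx[..., None], grad[..., None], axis=-1)
        return gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(channels), name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._xhat = xhat
            self._invstd = invstd
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        m = n * h * w
        self.gamma.grad += (grad * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        ghat = grad * g
        mean_g = ghat.mean(axis=(0, 2, 3), keepdims=True)
        mean_gx = (ghat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        dx = (ghat - mean_g - self._xhat * mean_gx) * self._invstd[None, :, None, None]
        self._xhat = None
        return dx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Linear(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator, name: str = "fc"):
        std = np.sqrt(2.0 / nin)
        self.weight = Param(rng.normal(0.0, std, (nin, nout)), decay=False, name=f"{name}.weight")
        self.bias = Param(np.zeros(nout), decay=False, name=f"{name}.bias")

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        dx = grad @ self.weight.value.T
        self._x = None
        return dx


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(DTYPE) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for i, l in enumerate(self.layers):
            for k, v in l.buffers().items():
                out[f"{i}.{k}"] = v
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad
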