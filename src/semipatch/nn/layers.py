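"""Neural-network layers with explicit forward/backward passes.

All layers operate on float64 numpy arrays. Convolutional layers use the
NCHW layout. Each layer caches what its backward pass needs during
``forward``; calling ``backward`` before ``forward`` is a programming error.

Weight initialisation draws from a caller-supplied ``numpy.random.Generator``
so that building the same network twice from the same seed yields
bit-identical parameters.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
    "Softmax",
    "MaxPool2d",
    "GlobalAvgPool",
    "Dropout",
    "Flatten",
    "Reshape",
]


class Layer:
    """Base layer: parameter container plus forward/backward contract."""

    def __init__(self, name: str | None = None):
        self.name = name or self.__class__.__name__
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.__class__.__name__}({self.name})"


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str | None = None):
        super().__init__(name)
        self.params = {
            "w": _he_init(rng, (n_in, n_out), n_in),
            "b": np.zeros(n_out),
        }

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dy):
        self.grads = {"w": self._x.T @ dy, "b": dy.sum(axis=0)}
        return dy @ self.params["w"].T


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*kh*kw, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * kh * kw, ho * wo)


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int) -> np.ndarray:
    n, c, h, w = x_shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    x = np.zeros(x_shape, dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    return x


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with integer zero padding."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int | str = "same",
        name: str | None = None,
    ):
        super().__init__(name)
        if padding == "same":
            if stride != 1:
                raise ValueError("'same' padding requires stride 1")
            padding = (kernel - 1) // 2
        self.kernel = kernel
        self.stride = stride
        self.padding = int(padding)
        fan_in = c_in * kernel * kernel
        self.params = {
            "w": _he_init(rng, (c_out, c_in, kernel, kernel), fan_in),
            "b": np.zeros(c_out),
        }

    def forward(self, x, training=False):
        k, s, p = self.kernel, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._x_padded_shape = x.shape
        cols = _im2col(x, k, k, s)
        self._cols = cols
        n = x.shape[0]
        f = self.params["w"].shape[0]
        wmat = self.params["w"].reshape(f, -1)
        ho = (x.shape[2] - k) // s + 1
        wo = (x.shape[3] - k) // s + 1
        y = np.einsum("fk,nkp->nfp", wmat, cols, optimize=True)
        y += self.params["b"][None, :, None]
        return y.reshape(n, f, ho, wo)

    def backward(self, dy):
        k, s, p = self.kernel, self.stride, self.padding
        n, f = dy.shape[:2]
        dyf = dy.reshape(n, f, -1)
        wmat = self.params["w"].reshape(f, -1)
        dw = np.einsum("nfp,nkp->fk", dyf, self._cols, optimize=True)
        self.grads = {
            "w": dw.reshape(self.params["w"].shape),
            "b": dyf.sum(axis=(0, 2)),
        }
        dcols = np.einsum("fk,nfp->nkp", wmat, dyf, optimize=True)
        dx = _col2im(dcols, self._x_padded_shape, k, k, s)
        if p:
            dx = dx[:, :, p:-p, p:-p]
        return dx


class ConvTranspose2d(Layer):
    """Stride-``s`` transposed convolution producing an exact ``s``-times upsample.

    Output spatial size is ``H * stride``; the full ``(H-1)*s + k`` response is
    cropped symmetrically (extra pixel removed at the bottom/right), matching
    the usual 'same'-style transposed convolution.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 2,
        name: str | None = None,
    ):
        super().__init__(name)
        if kernel < stride:
            raise ValueError("kernel must be >= stride for gap-free upsampling")
        self.kernel = kernel
        self.stride = stride
        fan_in = c_in * kernel * kernel
        self.params = {
            "w": _he_init(rng, (c_in, c_out, kernel, kernel), fan_in),
            "b": np.zeros(c_out),
        }

    def _geometry(self, h, w):
        k, s = self.kernel, self.stride
        hf, wf = (h - 1) * s + k, (w - 1) * s + k
        ho, wo = h * s, w * s
        top = (hf - ho) // 2
        left = (wf - wo) // 2
        return hf, wf, ho, wo, top, left

    def forward(self, x, training=False):
        self._x = x
        n, c, h, w = x.shape
        k, s = self.kernel, self.stride
        f = self.params["w"].shape[1]
        hf, wf, ho, wo, top, left = self._geometry(h, w)
        y = np.zeros((n, f, hf, wf), dtype=x.dtype)
        wgt = self.params["w"]
        for i in range(k):
            for j in range(k):
                y[:, :, i : i + s * h : s, j : j + s * w : s] += np.einsum(
                    "nchw,cf->nfhw", x, wgt[:, :, i, j], optimize=True
                )
        y = y[:, :, top : top + ho, left : left + wo]
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy):
        x = self._x
        n, c, h, w = x.shape
        k, s = self.kernel, self.stride
        f = self.params["w"].shape[1]
        hf, wf, ho, wo, top, left = self._geometry(h, w)
        dy_full = np.zeros((n, f, hf, wf), dtype=dy.dtype)
        dy_full[:, :, top : top + ho, left : left + wo] = dy
        dx = np.zeros_like(x)
        dw = np.zeros_like(self.params["w"])
        wgt = self.params["w"]
        for i in range(k):
            for j in range(k):
                dslice = dy_full[:, :, i : i + s * h : s, j : j + s * w : s]
                dx += np.einsum("nfhw,cf->nchw", dslice, wgt[:, :, i, j], optimize=True)
                dw[:, :, i, j] = np.einsum("nchw,nfhw->cf", x, dslice, optimize=True)
        self.grads = {"w": dw, "b": dy.sum(axis=(0, 2, 3))}
        return dx


class BatchNorm(Layer):
    """Batch normalisation over the batch (and spatial dims for NCHW input).

    Keeps exponential running statistics for evaluation mode.
    """

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5, name: str | None = None):
        super().__init__(name)
        self.eps = eps
        self.momentum = momentum
        self.params = {"gamma": np.ones(n_channels), "beta": np.zeros(n_channels)}
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)

    def _shape(self, x):
        if x.ndim == 4:
            return (0, 2, 3), (1, -1, 1, 1)
        if x.ndim == 2:
            return (0,), (1, -1)
        raise ValueError(f"BatchNorm expects 2-D or 4-D input, got {x.ndim}-D")

    def forward(self, x, training=False):
        axes, bshape = self._shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(bshape)) / std.reshape(bshape)
        self._cache = (xhat, std, axes, bshape, training)
        return self.params["gamma"].reshape(bshape) * xhat + self.params["beta"].reshape(bshape)

    def backward(self, dy):
        xhat, std, axes, bshape, training = self._cache
        self.grads = {
            "gamma": (dy * xhat).sum(axis=axes),
            "beta": dy.sum(axis=axes),
        }
        g = self.params["gamma"].reshape(bshape)
        if not training:
            return dy * g / std.reshape(bshape)
        m = np.prod([xhat.shape[a] for a in axes])
        dxhat = dy * g
        mean_dxhat = dxhat.mean(axis=axes).reshape(bshape)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes).reshape(bshape)
        return (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) / std.reshape(bshape)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2, name: str | None = None):
        super().__init__(name)
        self.alpha = alpha

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy)


class Tanh(Layer):
    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Softmax(Layer):
    """Row-wise softmax with the exact Jacobian in backward."""

    def forward(self, x, training=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._y = e / e.sum(axis=-1, keepdims=True)
        return self._y

    def backward(self, dy):
        y = self._y
        return y * (dy - (dy * y).sum(axis=-1, keepdims=True))


class MaxPool2d(Layer):
    def __init__(self, size: int = 2, name: str | None = None):
        super().__init__(name)
        self.size = size

    def forward(self, x, training=False):
        s = self.size
        n, c, h, w = x.shape
        if h % s or w % s:
            raise ValueError(f"spatial size {(h, w)} not divisible by pool size {s}")
        ho, wo = h // s, w // s
        xr = x.reshape(n, c, ho, s, wo, s).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, s * s)
        self._idx = xr.argmax(axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        s = self.size
        n, c, h, w = self._x_shape
        ho, wo = h // s, w // s
        dxr = np.zeros((n, c, ho, wo, s * s), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        return dxr.reshape(n, c, ho, wo, s, s).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    """Channel-wise spatial mean: (N,C,H,W) -> (N,C)."""

    def forward(self, x, training=False):
        self._x_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._x_shape
        return np.broadcast_to(dy[:, :, None, None], self._x_shape) / (h * w)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator, name: str | None = None):
        super().__init__(name)
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...], name: str | None = None):
        super().__init__(name)
        self.shape = shape

    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dy):
        return dy.reshape(self._in_shape)
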