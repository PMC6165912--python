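"""Minimal NumPy layers with explicit backward passes.

All tensors are ``float32`` and laid out ``(batch, channel, *spatial)``
with 2 or 3 spatial axes.  Each layer caches what its backward pass needs
during ``forward(..., train=True)``; caches are dropped afterwards, so a
layer instance supports one in-flight forward/backward pair (sufficient
for plain SGD-style training).
"""

from __future__ import annotations

import numpy as np

from parotidseg.netarch.arch import SizingError


class Layer:
    name: str = ""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def state(self) -> dict[str, np.ndarray]:
        """Non-trainable buffers (e.g. batch-norm running statistics)."""
        return {}

    def zero_grad(self) -> None:
        for g in self.grads().values():
            g[...] = 0.0


class ConvValid(Layer):
    """Valid (unpadded) convolution; output shrinks by kernel-1 per axis.

    Implemented as one GEMM per kernel offset on a channels-last copy of
    the input, which is substantially faster on CPU than materializing
    im2col windows.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, d: int, rng, name: str):
        fan_in = c_in * kernel**d
        scale = np.sqrt(2.0 / fan_in)
        self.w = (rng.standard_normal((c_out, c_in) + (kernel,) * d) * scale).astype(np.float32)
        self.b = np.zeros(c_out, np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.d = d
        self.kernel = kernel
        self.name = name
        self._xt = None  # channels-last input copy for the weight gradient

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.gw, "b": self.gb}

    def _out_extents(self, x: np.ndarray) -> tuple[int, ...]:
        d, k = self.d, self.kernel
        for i in range(d):
            if x.shape[2 + i] < k:
                raise SizingError(
                    f"{self.name}: spatial extent {x.shape[2 + i]} smaller than kernel {k}"
                )
        return tuple(x.shape[2 + i] - k + 1 for i in range(d))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        d, k = self.d, self.kernel
        so = self._out_extents(x)
        w = self.w.astype(x.dtype, copy=False)
        xt = np.ascontiguousarray(np.moveaxis(x, 1, -1))
        self._xt = xt if train else None
        out = np.zeros((x.shape[0],) + so + (w.shape[0],), dtype=x.dtype)
        out += self.b.astype(x.dtype, copy=False)
        for q in np.ndindex(*(k,) * d):
            sl = (slice(None),) + tuple(slice(q[i], q[i] + so[i]) for i in range(d))
            out += xt[sl] @ w[(slice(None), slice(None)) + q].T
        return np.ascontiguousarray(np.moveaxis(out, -1, 1))

    def backward(self, g: np.ndarray) -> np.ndarray:
        d, k = self.d, self.kernel
        xt = self._xt
        self._xt = None
        so = g.shape[2:]
        c_out, c_in = self.w.shape[:2]
        w = self.w.astype(g.dtype, copy=False)
        gt = np.ascontiguousarray(np.moveaxis(g, 1, -1))
        gtm = gt.reshape(-1, c_out)
        self.gb += gtm.sum(axis=0)
        gxt = np.zeros(xt.shape, dtype=g.dtype)
        for q in np.ndindex(*(k,) * d):
            sl = (slice(None),) + tuple(slice(q[i], q[i] + so[i]) for i in range(d))
            xs = np.ascontiguousarray(xt[sl]).reshape(-1, c_in)
            self.gw[(slice(None), slice(None)) + q] += gtm.T @ xs
            gxt[sl] += gt @ w[(slice(None), slice(None)) + q]
        return np.ascontiguousarray(np.moveaxis(gxt, -1, 1))


class BatchNorm(Layer):
    """Per-channel batch normalization over batch and spatial axes."""

    def __init__(self, channels: int, name: str, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, np.float32)
        self.beta = np.zeros(channels, np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self.momentum = momentum
        self.eps = eps
        self.name = name
        self._cache = None
        self._calib = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.ggamma, "beta": self.gbeta}

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def begin_calibration(self) -> None:
        c = self.gamma.shape[0]
        self._calib = [0, np.zeros(c, np.float64), np.zeros(c, np.float64)]

    def end_calibration(self) -> None:
        n, s1, s2 = self._calib
        self._calib = None
        if n == 0:
            return
        mean = s1 / n
        var = s2 / n - mean * mean
        self.running_mean[...] = mean
        self.running_var[...] = np.maximum(var, 0.0)

    def _bshape(self, ndim: int):
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            if self._calib is not None:
                # exact-moment accumulation for post-training recalibration
                m = x.size // x.shape[1]
                self._calib[0] += m
                self._calib[1] += m * mu
                self._calib[2] += m * (var + mu * mu)
            else:
                self.running_mean += self.momentum * (mu - self.running_mean)
                self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(x.dtype)
        xhat = (x - mu.reshape(self._bshape(x.ndim))) / std.reshape(self._bshape(x.ndim))
        if train:
            self._cache = (xhat, std)
        return (
            self.gamma.reshape(self._bshape(x.ndim)) * xhat
            + self.beta.reshape(self._bshape(x.ndim))
        ).astype(x.dtype, copy=False)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        self._cache = None
        axes = (0,) + tuple(range(2, g.ndim))
        m = g.size // g.shape[1]
        dbeta = g.sum(axis=axes)
        dgamma = (g * xhat).sum(axis=axes)
        self.gbeta += dbeta
        self.ggamma += dgamma
        bs = self._bshape(g.ndim)
        gx = (self.gamma / std).reshape(bs) * (
            g - dbeta.reshape(bs) / m - xhat * dgamma.reshape(bs) / m
        )
        return gx.astype(g.dtype, copy=False)


class ReLU(Layer):
    def __init__(self, name: str):
        self.name = name
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        gx = g * self._mask
        self._mask = None
        return gx


class MaxPool(Layer):
    """Non-overlapping max pooling by ``extent`` along each spatial axis."""

    def __init__(self, extent: int, d: int, name: str):
        self.p = extent
        self.d = d
        self.name = name
        self._cache = None

    def _blockify(self, x: np.ndarray) -> np.ndarray:
        """(N, C, *S) -> (N, C, *S/p, p**d) with pooled positions last."""
        p, d = self.p, self.d
        n, c = x.shape[:2]
        s = x.shape[2:]
        shape = (n, c) + sum(((s[i] // p, p) for i in range(d)), ())
        xr = x.reshape(shape)
        order = [0, 1] + [2 + 2 * i for i in range(d)] + [3 + 2 * i for i in range(d)]
        xt = xr.transpose(order)
        return xt.reshape(xt.shape[: 2 + d] + (p**d,))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        p, d = self.p, self.d
        for i in range(d):
            if x.shape[2 + i] % p:
                raise SizingError(
                    f"{self.name}: extent {x.shape[2 + i]} not divisible by pool extent {p}"
                )
        blocks = self._blockify(x)
        idx = blocks.argmax(axis=-1)
        out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, g: np.ndarray) -> np.ndarray:
        idx, in_shape = self._cache
        self._cache = None
        p, d = self.p, self.d
        blocks = np.zeros(g.shape + (p**d,), dtype=g.dtype)
        np.put_along_axis(blocks, idx[..., None], g[..., None], axis=-1)
        n, c = in_shape[:2]
        s_out = g.shape[2:]
        bt = blocks.reshape(g.shape + (p,) * d)
        # invert the transpose done in _blockify
        order = [0, 1] + sum(([2 + i, 2 + d + i] for i in range(d)), [])
        gx = bt.transpose(order).reshape(in_shape)
        return np.ascontiguousarray(gx)


class Upsample(Layer):
    """Nearest-neighbor upsampling by ``extent`` along each spatial axis."""

    def __init__(self, extent: int, d: int, name: str):
        self.p = extent
        self.d = d
        self.name = name

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for ax in range(2, 2 + self.d):
            x = np.repeat(x, self.p, axis=ax)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        p, d = self.p, self.d
        n, c = g.shape[:2]
        s = g.shape[2:]
        shape = (n, c) + sum(((s[i] // p, p) for i in range(d)), ())
        gr = g.reshape(shape)
        gx = gr.sum(axis=tuple(3 + 2 * i for i in range(d)))
        return np.ascontiguousarray(gx)
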