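"""Layer implementations for the numpy CNN core (channels-last layout)."""

from __future__ import annotations

import numpy as np

try:  # JIT-compiled im2col/col2im: the copies dominate CPU conv cost
    from numba import njit

    @njit(cache=True)
    def _im2col_kernel(xp, cols):
        n_b, hp, wp, c = xp.shape
        h, w = hp - 2, wp - 2
        for n in range(n_b):
            for i in range(h):
                for j in range(w):
                    k = 0
                    for di in range(3):
                        for dj in range(3):
                            for ch in range(c):
                                cols[n, i, j, k] = xp[n, i + di, j + dj, ch]
                                k += 1

    @njit(cache=True)
    def _col2im_kernel(dcols, dxp):
        n_b, hp, wp, c = dxp.shape
        h, w = hp - 2, wp - 2
        for n in range(n_b):
            for i in range(h):
                for j in range(w):
                    k = 0
                    for di in range(3):
                        for dj in range(3):
                            for ch in range(c):
                                dxp[n, i + di, j + dj, ch] += dcols[n, i, j, k]
                                k += 1

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def _im2col_numpy(xp, cols):
    h, w = xp.shape[1] - 2, xp.shape[2] - 2
    c = xp.shape[3]
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[..., k * c : (k + 1) * c] = xp[:, di : di + h, dj : dj + w, :]
            k += 1


def _col2im_numpy(dcols, dxp):
    h, w = dxp.shape[1] - 2, dxp.shape[2] - 2
    c = dxp.shape[3]
    k = 0
    for di in range(3):
        for dj in range(3):
            dxp[:, di : di + h, dj : dj + w, :] += dcols[..., k * c : (k + 1) * c]
            k += 1


class Layer:
    """Base class: stateless layers override only forward/backward."""

    def params_and_grads(self):
        return []

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


def he_init(rng, shape, fan_in, dtype):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 'same', via im2col + GEMM.

    The im2col / col2im copies run through JIT-compiled kernels when numba is
    available, and the large scratch buffers are kept on the instance and
    reused between batches of the same shape.
    """

    def __init__(self, c_in, c_out, rng, dtype=np.float32):
        self.c_in = c_in
        self.c_out = c_out
        self.W = he_init(rng, (9 * c_in, c_out), 9 * c_in, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._buffers = {}

    def params_and_grads(self):
        return [(self, "W"), (self, "b")]

    def _buffer(self, name, shape, dtype, zero=False):
        key = (name, shape, np.dtype(dtype).str)
        buf = self._buffers.get(key)
        if buf is None:
            buf = np.zeros(shape, dtype=dtype)
            self._buffers[key] = buf
        elif zero:
            buf[...] = 0
        return buf

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        xp = self._buffer("xp", (n, h + 2, w + 2, c), x.dtype)
        xp[:, 1:-1, 1:-1, :] = x  # border stays zero
        cols = self._buffer("cols", (n, h, w, 9 * c), x.dtype)
        if _HAVE_NUMBA and x.dtype == np.float32:
            _im2col_kernel(xp, cols)
        else:
            _im2col_numpy(xp, cols)
        cols2 = cols.reshape(n * h * w, 9 * c)
        out = self._buffer("out", (n * h * w, self.c_out), x.dtype)
        np.matmul(cols2, self.W, out=out)
        out += self.b
        self._shape = x.shape
        self._cols = cols
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout):
        n, h, w, c = self._shape
        cols2 = self._cols.reshape(n * h * w, 9 * c)
        d2 = dout.reshape(n * h * w, self.c_out)
        np.matmul(cols2.T, d2, out=self.dW)
        self.db[...] = d2.sum(axis=0)
        # cols are no longer needed once dW is computed: reuse the buffer
        dcols = self._cols
        np.matmul(d2, self.W.T, out=cols2)
        dxp = self._buffer("dxp", (n, h + 2, w + 2, c), dout.dtype, zero=True)
        if _HAVE_NUMBA and dout.dtype == np.float32:
            _col2im_kernel(dcols, dxp)
        else:
            _col2im_numpy(dcols, dxp)
        return dxp[:, 1:-1, 1:-1, :]


class Conv1x1(Layer):
    """Pixel-wise linear map; used as the output head of the U-Nets."""

    def __init__(self, c_in, c_out, rng, dtype=np.float32):
        self.c_in = c_in
        self.c_out = c_out
        self.W = he_init(rng, (c_in, c_out), c_in, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params_and_grads(self):
        return [(self, "W"), (self, "b")]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        n, h, w, _ = dout.shape
        x2 = self._x.reshape(-1, self.c_in)
        d2 = dout.reshape(-1, self.c_out)
        self.dW[...] = x2.T @ d2
        self.db[...] = d2.sum(axis=0)
        return (d2 @ self.W.T).reshape(self._x.shape)


class ConvTranspose2x2(Layer):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, c_in, c_out, rng, dtype=np.float32):
        self.c_in = c_in
        self.c_out = c_out
        self.W = he_init(rng, (c_in, 4 * c_out), c_in, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params_and_grads(self):
        return [(self, "W"), (self, "b")]

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        self._x = x
        y = x.reshape(n * h * w, c) @ self.W  # (n*h*w, 4*c_out)
        y = y.reshape(n, h, w, 2, 2, self.c_out)
        y = y.transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * w, self.c_out)
        return y + self.b

    def backward(self, dout):
        n, h2, w2, f = dout.shape
        h, w = h2 // 2, w2 // 2
        d = dout.reshape(n, h, 2, w, 2, f).transpose(0, 1, 3, 2, 4, 5)
        d = d.reshape(n * h * w, 4 * f)
        x2 = self._x.reshape(n * h * w, self.c_in)
        self.dW[...] = x2.T @ d
        self.db[...] = dout.sum(axis=(0, 1, 2))
        return (d @ self.W.T).reshape(self._x.shape)


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W) with running stats."""

    def __init__(self, c, momentum=0.9, eps=1e-5, dtype=np.float32):
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params_and_grads(self):
        return [(self, "gamma"), (self, "beta")]

    def _axes(self, x):
        return tuple(range(x.ndim - 1))

    def forward(self, x, train=False):
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std.astype(x.dtype))
        return self.gamma * xhat + self.beta

    def backward(self, dout):
        xhat, inv_std = self._cache
        axes = self._axes(dout)
        m = float(np.prod([dout.shape[a] for a in axes]))
        self.dgamma[...] = (dout * xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        # dx = gamma*inv_std * (dout - mean(dout) - xhat*mean(dout*xhat))
        # where the two means are dbeta/m and dgamma/m, already reduced above
        dx = dout - (self.dbeta / m + xhat * (self.dgamma / m))
        dx *= self.gamma * inv_std
        return dx


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.maximum(x, 0, out=x)  # inter-layer tensors are transient

    def backward(self, dout):
        return np.multiply(dout, self._mask, out=dout)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._p = 1.0 / (1.0 + np.exp(-x))
        return self._p

    def backward(self, dout):
        return dout * self._p * (1.0 - self._p)


class Softmax(Layer):
    """Softmax over the last axis with the full Jacobian in backward."""

    def forward(self, x, train=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=-1, keepdims=True)
        return self._p

    def backward(self, dout):
        p = self._p
        return p * (dout - (dout * p).sum(axis=-1, keepdims=True))


class MaxPool2x2(Layer):
    def forward(self, x, train=False):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        r = x.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        r = r.reshape(n, h2, w2, c, 4)
        self._arg = r.argmax(axis=4)
        self._shape = x.shape
        return np.take_along_axis(r, self._arg[..., None], axis=4)[..., 0]

    def backward(self, dout):
        n, h, w, c = self._shape
        h2, w2 = h // 2, w // 2
        dr = np.zeros((n, h2, w2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dr, self._arg[..., None], dout[..., None], axis=4)
        dr = dr.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dr.reshape(n, h, w, c)


class SpatialDropout(Layer):
    """Drops whole feature channels; identity when rate == 0 or at eval."""

    def __init__(self, rate, rng):
        self.rate = float(rate)
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random((x.shape[0], 1, 1, x.shape[-1])) < keep)
        self._mask = mask.astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class GlobalAvgPool(Layer):
    """Mean over the spatial axes: (N, H, W, C) -> (N, C)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, d_in, d_out, rng, dtype=np.float32):
        self.W = he_init(rng, (d_in, d_out), d_in, dtype)
        self.b = np.zeros(d_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params_and_grads(self):
        return [(self, "W"), (self, "b")]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params_and_grads(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params_and_grads())
        return out

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout
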