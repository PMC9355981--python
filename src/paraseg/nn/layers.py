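"""Trainable layers: convolutions, transpose convolution, instance norm,
leaky ReLU, and the residual unit used at every U-Net stage.

Each layer owns its parameters and gradient buffers and implements
``forward(x, train)`` / ``backward(gy)``; composition bookkeeping lives in
:mod:`paraseg.nn.unet`. Weights use the fan-in uniform initialisation that
convolutional reference implementations default to.
"""

from __future__ import annotations

import numpy as np

from .functional import conv_forward, conv_input_grad, conv_weight_grad, im2col

DTYPE = np.float32


class Layer:
    def parameters(self) -> list[tuple[str, np.ndarray]]:
        return []

    def gradients(self) -> list[tuple[str, np.ndarray]]:
        return []


def _init_conv(rng: np.random.Generator, shape, fan_in: int):
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Conv(Layer):
    """k^d convolution with 'same' padding and optional stride."""

    def __init__(self, cin, cout, k, stride, dims, rng, bias=True):
        self.stride = stride
        fan_in = cin * k**dims
        self.W = _init_conv(rng, (cout, cin) + (k,) * dims, fan_in)
        self.b = _init_conv(rng, (cout,), fan_in) if bias else None
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b) if bias else None
        self._cols = None
        self._in_sp = None

    def forward(self, x, train=True):
        y, cols = conv_forward(x, self.W, self.b, self.stride)
        if train:
            self._cols, self._in_sp = cols, x.shape[2:]
        return y

    def backward(self, gy):
        self.gW += conv_weight_grad(self._cols, gy, self.W.shape)
        if self.b is not None:
            self.gb += gy.sum(axis=(0,) + tuple(range(2, gy.ndim)))
        gx = conv_input_grad(gy, self.W, self.stride, self._in_sp)
        self._cols = None
        return gx

    def parameters(self):
        out = [("W", self.W)]
        if self.b is not None:
            out.append(("b", self.b))
        return out

    def gradients(self):
        out = [("W", self.gW)]
        if self.b is not None:
            out.append(("b", self.gb))
        return out


class ConvTranspose(Layer):
    """Stride-s transpose convolution; output spatial size = s * input."""

    def __init__(self, cin, cout, k, stride, dims, rng, bias=True):
        self.stride = stride
        self.k = k
        fan_in = cin * k**dims
        self.W = _init_conv(rng, (cin, cout) + (k,) * dims, fan_in)
        self.b = _init_conv(rng, (cout,), fan_in) if bias else None
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b) if bias else None
        self._x = None

    def forward(self, x, train=True):
        out_sp = tuple(self.stride * s for s in x.shape[2:])
        y = conv_input_grad(x, self.W, self.stride, out_sp)
        if self.b is not None:
            y += self.b.reshape((1, -1) + (1,) * (x.ndim - 2))
        if train:
            self._x = x
        return y

    def backward(self, gy):
        x = self._x
        cols, out_sp = im2col(gy, self.k, self.stride, (self.k - 1) // 2)
        assert tuple(out_sp) == tuple(x.shape[2:])
        self.gW += conv_weight_grad(cols, x, self.W.shape)
        if self.b is not None:
            self.gb += gy.sum(axis=(0,) + tuple(range(2, gy.ndim)))
        gx, _ = conv_forward(gy, self.W, None, self.stride)
        self._x = None
        return gx

    parameters = Conv.parameters
    gradients = Conv.gradients


class InstanceNorm(Layer):
    """Per-sample, per-channel standardisation over the spatial axes."""

    def __init__(self, c, eps=1e-5, affine=True):
        self.eps = eps
        self.affine = affine
        self.gamma = np.ones(c, dtype=DTYPE) if affine else None
        self.beta = np.zeros(c, dtype=DTYPE) if affine else None
        self.ggamma = np.zeros_like(self.gamma) if affine else None
        self.gbeta = np.zeros_like(self.beta) if affine else None
        self._cache = None

    def forward(self, x, train=True):
        axes = tuple(range(2, x.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * invstd
        if train:
            self._cache = (xhat, invstd, axes)
        if self.affine:
            shp = (1, -1) + (1,) * (x.ndim - 2)
            return self.gamma.reshape(shp) * xhat + self.beta.reshape(shp)
        return xhat

    def backward(self, gy):
        xhat, invstd, axes = self._cache
        if self.affine:
            shp = (1, -1) + (1,) * (gy.ndim - 2)
            self.ggamma += (gy * xhat).sum(axis=(0,) + axes)
            self.gbeta += gy.sum(axis=(0,) + axes)
            dxhat = gy * self.gamma.reshape(shp)
        else:
            dxhat = gy
        m1 = dxhat.mean(axis=axes, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
        gx = invstd * (dxhat - m1 - xhat * m2)
        self._cache = None
        return gx.astype(gy.dtype, copy=False)

    def parameters(self):
        return [("gamma", self.gamma), ("beta", self.beta)] if self.affine else []

    def gradients(self):
        return [("gamma", self.ggamma), ("beta", self.gbeta)] if self.affine else []


class LeakyReLU(Layer):
    def __init__(self, negative_slope=0.01):
        self.slope = negative_slope
        self._mask = None

    def forward(self, x, train=True):
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, gy):
        gx = np.where(self._mask, gy, self.slope * gy)
        self._mask = None
        return gx


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for lyr in self.layers:
            x = lyr.forward(x, train)
        return x

    def backward(self, gy):
        for lyr in reversed(self.layers):
            gy = lyr.backward(gy)
        return gy

    def parameters(self):
        return [(f"{i}.{n}", p) for i, lyr in enumerate(self.layers) for n, p in lyr.parameters()]

    def gradients(self):
        return [(f"{i}.{n}", g) for i, lyr in enumerate(self.layers) for n, g in lyr.gradients()]


class ResidualUnit(Layer):
    """conv -> IN -> act -> conv -> IN -> act, plus an additive shortcut.

    The shortcut is the identity when geometry permits, else a 1x1 strided
    projection convolution. No activation follows the addition, so a stage
    with all path weights at zero passes the (projected) input through
    unchanged.
    """

    def __init__(self, cin, cout, stride, dims, rng, negative_slope=0.01,
                 eps=1e-5, affine=True):
        self.path = Sequential(
            Conv(cin, cout, 3, stride, dims, rng),
            InstanceNorm(cout, eps, affine),
            LeakyReLU(negative_slope),
            Conv(cout, cout, 3, 1, dims, rng),
            InstanceNorm(cout, eps, affine),
            LeakyReLU(negative_slope),
        )
        self.shortcut = None
        if cin != cout or stride != 1:
            self.shortcut = Conv(cin, cout, 1, stride, dims, rng)

    def forward(self, x, train=True):
        h = self.path.forward(x, train)
        r = self.shortcut.forward(x, train) if self.shortcut is not None else x
        return h + r

    def backward(self, gy):
        gx = self.path.backward(gy)
        if self.shortcut is not None:
            gx = gx + self.shortcut.backward(gy)
        else:
            gx = gx + gy
        return gx

    def parameters(self):
        out = [(f"path.{n}", p) for n, p in self.path.parameters()]
        if self.shortcut is not None:
            out += [(f"shortcut.{n}", p) for n, p in self.shortcut.parameters()]
        return out

    def gradients(self):
        out = [(f"path.{n}", g) for n, g in self.path.gradients()]
        if self.shortcut is not None:
            out += [(f"shortcut.{n}", g) for n, g in self.shortcut.gradients()]
        return out
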