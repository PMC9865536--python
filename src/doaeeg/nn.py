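"""Minimal NumPy layers with explicit backward passes, for the 1-D
residual-shrinkage regressor.

Feature maps are ``(batch, channels, width)`` arrays; fully connected
activations are ``(batch, features)``.  Every layer exposes
``forward(x, train)`` and ``backward(grad_out)``, accumulating parameter
gradients in ``Param.grad``; correctness is pinned by numerical gradient
checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = np.asarray(value)
        if not np.issubdtype(self.value.dtype, np.floating):
            self.value = self.value.astype(float)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # include in L2 regularization


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _same_pad(w: int, k: int, stride: int) -> tuple[int, int, int]:
    out = -(-w // stride)  # ceil
    total = max((out - 1) * stride + k - w, 0)
    return out, total // 2, total - total // 2


class Conv1d(Layer):
    """'Same'-padded 1-D convolution (cross-correlation), stride >= 1."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, rng=None,
                 dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k))
        self.w = Param(rng.normal(0.0, scale, size=(cout, cin, k)).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype), decay=False)
        self.k, self.stride = k, stride

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        b, c, w = x.shape
        self._wout, pl, pr = _same_pad(w, self.k, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        cols = sliding_window_view(xp, self.k, axis=2)[:, :, :: self.stride, :]
        self._cache = (cols, xp.shape[2], pl, w)
        return (
            np.einsum("bcwk,ock->bow", cols, self.w.value, optimize=True)
            + self.b.value[None, :, None]
        )

    def backward(self, g):
        cols, wp, pl, w_in = self._cache
        self.w.grad += np.einsum("bow,bcwk->ock", g, cols, optimize=True)
        self.b.grad += g.sum(axis=(0, 2))
        gxp = np.zeros((g.shape[0], self.w.value.shape[1], wp), dtype=g.dtype)
        wout = g.shape[2]
        for j in range(self.k):
            # positions j, j+stride, ... are unique for fixed j
            gxp[:, :, j : j + (wout - 1) * self.stride + 1 : self.stride] += np.einsum(
                "bow,oc->bcw", g, self.w.value[:, :, j], optimize=True
            )
        return gxp[:, :, pl : pl + w_in]


class BatchNorm(Layer):
    """Batch normalization per channel (axis 1), over batch and width."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float64):
        self.gamma = Param(np.ones(c, dtype=dtype), decay=False)
        self.beta = Param(np.zeros(c, dtype=dtype), decay=False)
        self.run_mean = np.zeros(c, dtype=dtype)
        self.run_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2)

    def _shape(self, x):
        return (1, -1) if x.ndim == 2 else (1, -1, 1)

    def forward(self, x, train=True):
        axes, shp = self._axes(x), self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size / mean.size
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var * (
                n / max(n - 1, 1)
            )
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) * inv.reshape(shp)
        self._cache = (xhat, inv, axes, shp, train)
        return self.gamma.value.reshape(shp) * xhat + self.beta.value.reshape(shp)

    def backward(self, g):
        xhat, inv, axes, shp, train = self._cache
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        gxhat = g * self.gamma.value.reshape(shp)
        if not train:
            return gxhat * inv.reshape(shp)
        n = xhat.size / inv.size
        return (
            inv.reshape(shp)
            / n
            * (
                n * gxhat
                - gxhat.sum(axis=axes).reshape(shp)
                - xhat * (gxhat * xhat).sum(axis=axes).reshape(shp)
            )
        )


class ELU(Layer):
    def forward(self, x, train=True):
        self._pos = x > 0
        self._y = np.where(self._pos, x, np.expm1(x))
        return self._y

    def backward(self, g):
        return g * np.where(self._pos, 1.0, self._y + 1.0)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._pos = x > 0
        return x * self._pos

    def backward(self, g):
        return g * self._pos


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng=None, dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / nin), size=(nin, nout)).astype(dtype))
        self.b = Param(np.zeros(nout, dtype=dtype), decay=False)

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, g):
        self.w.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.w.value.T


class GlobalAvgPool(Layer):
    """(B, C, W) -> (B, C) mean over width."""

    def forward(self, x, train=True):
        self._w = x.shape[2]
        return x.mean(axis=2)

    def backward(self, g):
        return np.repeat(g[:, :, None], self._w, axis=2) / self._w


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


def soft_threshold(x: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Channel-wise shrinkage: zero inside [-tau, tau], shrink by tau outside.

    ``tau`` broadcasts against ``x`` (e.g. shape (B, C, 1) against (B, C, W));
    all thresholds must be non-negative.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("soft thresholds must be non-negative")
    return np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)


class ShrinkageModule(Layer):
    """Channel-wise threshold estimator + soft thresholding.

    Per sample: ``x_avg = mean |x|`` over width (GAP of the magnitude map);
    a two-layer fully connected net with BN and ReLU maps x_avg to logits z;
    ``alpha = sigmoid(z)`` and ``tau_c = alpha_c * x_avg_c``, guaranteeing
    0 <= tau_c <= x_avg_c.  Output is x soft-thresholded at tau.
    """

    def __init__(self, c: int, rng=None, dtype=np.float64):
        self.fc1 = Dense(c, c, rng, dtype)
        self.bn = BatchNorm(c, dtype=dtype)
        self.relu = ReLU()
        self.fc2 = Dense(c, c, rng, dtype)
        self.sig = Sigmoid()

    def params(self):
        return self.fc1.params() + self.bn.params() + self.fc2.params()

    def thresholds(self, x: np.ndarray, train: bool = True):
        a = np.abs(x).mean(axis=2)
        z = self.fc2.forward(
            self.relu.forward(self.bn.forward(self.fc1.forward(a, train), train), train),
            train,
        )
        alpha = self.sig.forward(z, train)
        return a, alpha, alpha * a

    def forward(self, x, train=True):
        a, alpha, tau = self.thresholds(x, train)
        self._cache = (x, a, alpha, tau)
        return soft_threshold(x, tau[:, :, None])

    def backward(self, g):
        x, a, alpha, tau = self._cache
        active = np.abs(x) > tau[:, :, None]
        sgn = np.sign(x)
        gx = g * active
        gtau = -(g * sgn * active).sum(axis=2)
        galpha = gtau * a
        ga = gtau * alpha
        gz = self.sig.backward(galpha)
        ga_fc = self.fc1.backward(self.bn.backward(self.relu.backward(self.fc2.backward(gz))))
        ga += ga_fc
        gx += (ga / x.shape[2])[:, :, None] * sgn
        return gx


class RSBU(Layer):
    """Residual shrinkage building unit with channel-wise thresholds.

    Pre-activation layout: BN - ELU - Conv(stride) - BN - ELU - Conv, then
    soft thresholding of the branch via a ShrinkageModule, added to the
    shortcut.  The ``convolutional`` variant reshapes the shortcut with a
    strided 1x1 convolution + BN.  ``ablate`` skips the shrinkage (plain
    residual building unit with ELU activations).
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 ablate: bool = False, rng=None, dtype=np.float64):
        self.branch_pre = Sequential(
            BatchNorm(cin, dtype=dtype), ELU(), Conv1d(cin, cout, k, stride, rng, dtype),
            BatchNorm(cout, dtype=dtype), ELU(), Conv1d(cout, cout, k, 1, rng, dtype),
        )
        self.shrink = None if ablate else ShrinkageModule(cout, rng, dtype)
        self.convolutional = cin != cout or stride != 1
        if self.convolutional:
            self.sc_conv = Conv1d(cin, cout, 1, stride, rng, dtype)
            self.sc_bn = BatchNorm(cout, dtype=dtype)

    def params(self):
        p = self.branch_pre.params()
        if self.shrink is not None:
            p += self.shrink.params()
        if self.convolutional:
            p += self.sc_conv.params() + self.sc_bn.params()
        return p

    def forward(self, x, train=True):
        h = self.branch_pre.forward(x, train)
        if self.shrink is not None:
            h = self.shrink.forward(h, train)
        if self.convolutional:
            sc = self.sc_bn.forward(self.sc_conv.forward(x, train), train)
        else:
            sc = x
        if sc.shape != h.shape:
            raise ValueError(
                f"RSBU shape mismatch: shortcut {sc.shape} vs branch {h.shape}"
            )
        return sc + h

    def backward(self, g):
        gh = g
        if self.shrink is not None:
            gh = self.shrink.backward(gh)
        gx = self.branch_pre.backward(gh)
        if self.convolutional:
            gx = gx + self.sc_conv.backward(self.sc_bn.backward(g))
        else:
            gx = gx + g
        return gx


class Adam:
    """Adam with decoupled-from-nothing classic L2 (added to gradients)."""

    def __init__(self, params: list[Param], lr: float = 0.005,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
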