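"""Numpy neural-network layers with explicit backward passes.

All arrays are float32 in NHWC layout (batch, height, width, channels):
with channels innermost, im2col patch matrices are assembled from k*k
contiguous block copies and the convolution GEMM produces NHWC output
directly, which keeps the stack memory-bandwidth-friendly on a single CPU.
Every layer exposes ``params``/``grads`` (aligned lists of arrays),
``forward(x, train)`` and ``backward(grad_out)``.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

F32 = np.float32


class Layer:
    params: List[np.ndarray]
    grads: List[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


try:  # JIT im2col writes the patch matrix sequentially (the numpy fallback
    # is correct but considerably slower on strided writes)
    from numba import njit

    @njit(cache=False, fastmath=True)
    def _im2col_pad_jit(xf, n, h, w, c, k, pt, pb, cols):  # pragma: no cover
        # xf: flattened contiguous (n*h*w*c); interior rows copy k*c
        # contiguous elements at once so the loop vectorizes
        ho = h + pt + pb - k + 1
        wo = w + pt + pb - k + 1
        row = w * c
        img = h * w * c
        kc = k * c
        idx = 0
        for b in range(n):
            for i in range(ho):
                for j in range(wo):
                    jj0 = j - pt
                    t = 0
                    for u in range(k):
                        ii = i + u - pt
                        if 0 <= ii < h:
                            base = b * img + ii * row + jj0 * c
                            if jj0 >= 0 and jj0 + k <= w:
                                for m in range(kc):
                                    cols[idx, t + m] = xf[base + m]
                            else:
                                for v in range(k):
                                    jj = jj0 + v
                                    if 0 <= jj < w:
                                        for ch in range(c):
                                            cols[idx, t + v * c + ch] = \
                                                xf[base + v * c + ch]
                                    else:
                                        for ch in range(c):
                                            cols[idx, t + v * c + ch] = 0.0
                        else:
                            for m in range(kc):
                                cols[idx, t + m] = 0.0
                        t += kc
                    idx += 1

    @njit(cache=False, fastmath=True)
    def _col2im_jit(cols, n, h, w, c, k, pt, pb, xf):  # pragma: no cover
        # scatter-add inverse of _im2col_pad_jit (transposed convolution)
        ho = h + pt + pb - k + 1
        wo = w + pt + pb - k + 1
        row = w * c
        img = h * w * c
        kc = k * c
        idx = 0
        for b in range(n):
            for i in range(ho):
                for j in range(wo):
                    jj0 = j - pt
                    t = 0
                    for u in range(k):
                        ii = i + u - pt
                        if 0 <= ii < h:
                            base = b * img + ii * row + jj0 * c
                            if jj0 >= 0 and jj0 + k <= w:
                                for m in range(kc):
                                    xf[base + m] += cols[idx, t + m]
                            else:
                                for v in range(k):
                                    jj = jj0 + v
                                    if 0 <= jj < w:
                                        for ch in range(c):
                                            xf[base + v * c + ch] += \
                                                cols[idx, t + v * c + ch]
                        t += kc
                    idx += 1

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _im2col_pad(x: np.ndarray, k: int, pt: int, pb: int):
    """(N, H, W, C) input -> patch matrix with symmetric-in-xy padding
    (pt top/left, pb bottom/right): ((N*Ho*Wo, k*k*C), (n, ho, wo))."""
    n, h, w, c = x.shape
    ho = h + pt + pb - k + 1
    wo = w + pt + pb - k + 1
    cols = np.empty((n * ho * wo, k * k * c), x.dtype)
    if _HAVE_NUMBA:
        xc = np.ascontiguousarray(x)
        _im2col_pad_jit(xc.reshape(-1), n, h, w, c, k, pt, pb, cols)
        return cols, (n, ho, wo)
    xp = np.pad(x, ((0, 0), (pt, pb), (pt, pb), (0, 0)))
    cols6 = cols.reshape(n, ho, wo, k, k, c)
    for u in range(k):
        for v in range(k):
            cols6[:, :, :, u, v, :] = xp[:, u:u + ho, v:v + wo, :]
    return cols, (n, ho, wo)


class Conv2d(Layer):
    """Same-padding 2D convolution (asymmetric padding for even widths)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 needs_input_grad: bool = True):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = (rng.standard_normal((k * k * cin, cout)) * scale).astype(F32)
        self.b = np.zeros(cout, F32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.pt = (k - 1) // 2
        self.pb = k // 2
        self.needs_input_grad = needs_input_grad  # False for the first layer

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        cols, (n, ho, wo) = _im2col_pad(x, self.k, self.pt, self.pb)
        y = cols @ self.W
        y += self.b
        self._cols = cols if train else None
        self._shape = (n, h, w, c)
        return y.reshape(n, ho, wo, self.cout)

    def backward(self, g: np.ndarray) -> Optional[np.ndarray]:
        n, h, w, c = self._shape
        k = self.k
        gm = g.reshape(-1, self.cout)
        self.grads[0] += self._cols.T @ gm
        self.grads[1] += gm.sum(axis=0)
        self._cols = None
        if not self.needs_input_grad:
            return None
        # dX: per-window gradient contributions scattered back (transposed
        # convolution); far cheaper than correlating with flipped kernels
        dcols = gm @ self.W.T  # (N*Ho*Wo, k*k*cin)
        dx = np.zeros(n * h * w * c, F32)
        if _HAVE_NUMBA:
            _col2im_jit(dcols, n, h, w, c, k, self.pt, self.pb, dx)
            return dx.reshape(n, h, w, c)
        dx4 = dx.reshape(n, h, w, c)
        dcols6 = dcols.reshape(n, h, w, k, k, c)
        xp = np.zeros((n, h + k - 1, w + k - 1, c), F32)
        for u in range(k):
            for v in range(k):
                xp[:, u:u + h, v:v + w, :] += dcols6[:, :, :, u, v, :]
        dx4[...] = xp[:, self.pt:self.pt + h, self.pt:self.pt + w, :]
        return dx4


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(c, F32)
        self.beta = np.zeros(c, F32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.run_mean = np.zeros(c, F32)
        self.run_var = np.ones(c, F32)
        self.momentum, self.eps = momentum, eps
        self.collecting = False  # exact-statistics recalibration mode
        self._acc = None

    def begin_collect(self) -> None:
        self.collecting = True
        self._acc = [np.zeros(self.gamma.shape, np.float64),
                     np.zeros(self.gamma.shape, np.float64), 0]

    def end_collect(self) -> None:
        s, ss, n = self._acc
        if n:
            mean = s / n
            self.run_mean = mean.astype(F32)
            self.run_var = (ss / n - mean ** 2).astype(F32)
        self.collecting = False
        self._acc = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if self.collecting:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = x.shape[0] * x.shape[1] * x.shape[2]
            self._acc[0] += m * mu
            self._acc[1] += m * (var + mu ** 2)
            self._acc[2] += m
        elif train:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.run_mean = (self.momentum * self.run_mean
                             + (1 - self.momentum) * mu).astype(F32)
            self.run_var = (self.momentum * self.run_var
                            + (1 - self.momentum) * var).astype(F32)
        else:
            mu, var = self.run_mean, self.run_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x - mu) * inv
        if train:
            self._xhat, self._inv = xhat, inv
        return self.gamma * xhat + self.beta

    def backward(self, g: np.ndarray) -> np.ndarray:
        m = g.shape[0] * g.shape[1] * g.shape[2]
        xhat, inv = self._xhat, self._inv
        self.grads[0] += (g * xhat).sum(axis=(0, 1, 2))
        self.grads[1] += g.sum(axis=(0, 1, 2))
        gsum = g.mean(axis=(0, 1, 2))
        gx = (g * xhat).mean(axis=(0, 1, 2))
        dx = (self.gamma * inv) * (g - gsum - xhat * gx)
        self._xhat = None
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, F32(0))

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, F32(0))


class MaxPool2x2(Layer):
    """2x2 max pooling; at exact ties the gradient is split among maxima."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        s = (x[:, 0::2, 0::2, :], x[:, 0::2, 1::2, :],
             x[:, 1::2, 0::2, :], x[:, 1::2, 1::2, :])
        m = np.maximum(np.maximum(s[0], s[1]), np.maximum(s[2], s[3]))
        if train:
            self._x = x
            self._m = m
        return m

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, m = self._x, self._m
        masks = [(x[:, i::2, j::2, :] == m) for i in (0, 1) for j in (0, 1)]
        cnt = masks[0].astype(F32)
        for mk in masks[1:]:
            cnt += mk
        share = g / cnt
        dx = np.zeros_like(x)
        for (i, j), mk in zip(((0, 0), (0, 1), (1, 0), (1, 1)), masks):
            dx[:, i::2, j::2, :] = np.where(mk, share, F32(0))
        self._x = self._m = None
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / nin)
        self.W = (rng.standard_normal((nin, nout)) * scale).astype(F32)
        self.b = np.zeros(nout, F32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads[0] += self._x.T @ g
        self.grads[1] += g.sum(axis=0)
        self._x = None
        return g @ self.W.T


class Dropout(Layer):
    """Inverted dropout between the hidden dense layer and the output."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(F32) / F32(1 - self.p)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    def __init__(self, params: List[np.ndarray], grads: List[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * (g * g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0
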