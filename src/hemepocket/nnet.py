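"""Minimal 3-D convolutional network engine on numpy.

Implements exactly the building blocks the pocket-to-distortion regressor
needs -- kernel-2 3-D convolution, batch normalization, ReLU, kernel-2/stride-2
max pooling, dropout, dense layers -- with reverse-mode gradients and an Adam
optimizer.  Convolutions are evaluated as eight shifted GEMMs, which maps the
whole forward/backward pass onto BLAS matrix products; activations are kept
in float32, channels-last (batch, depth, height, width, channel).

All randomness (initialization, batch shuffling, dropout) flows through
numpy Generators seeded by the caller, so training runs are exactly
reproducible on a given machine.
"""

from __future__ import annotations

import copy
from typing import Sequence

import numpy as np

_SHIFTS = [(di, dj, dk) for di in (0, 1) for dj in (0, 1) for dk in (0, 1)]


class Layer:
    """Base class: stateless unless it owns parameters."""

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class _BufferPool:
    """Reusable scratch arrays keyed by (tag, shape); avoids re-allocation,
    which otherwise dominates the runtime of large convolutions."""

    def __init__(self):
        self._store: dict[tuple, np.ndarray] = {}

    def get(self, tag: str, shape: tuple[int, ...], dtype=np.float32) -> np.ndarray:
        key = (tag, shape, np.dtype(dtype))
        buf = self._store.get(key)
        if buf is None:
            buf = np.empty(shape, dtype)
            self._store[key] = buf
        return buf


class Conv3d(Layer):
    """Kernel-2, stride-1 3-D convolution, optional 1-voxel zero padding.

    With kernel 2 the output side is ``L + 2*pad - 1``: a padded convolution
    therefore *grows* the grid by one cell per axis, an unpadded one shrinks
    it by one.  The kernel offset convention aligns offset (0,0,0) with the
    output cell.

    Evaluated as an im2col GEMM: the eight shifted views of the padded input
    are gathered into a ``(rows, 8 * c_in)`` matrix and hit with a single
    ``(8 * c_in, c_out)`` weight product.  The gather runs over micro-batches
    bounded to ``_COL_BUDGET`` floats so peak scratch memory stays flat.
    """

    _COL_BUDGET = 24_000_000  # floats (~96 MB float32) for the im2col buffer

    def __init__(self, c_in: int, c_out: int, pad: int, rng: np.random.Generator,
                 input_grad: bool = True):
        self.c_in, self.c_out, self.pad = c_in, c_out, pad
        self.input_grad = input_grad
        fan_in = c_in * 8
        bound = 1.0 / np.sqrt(fan_in)
        # weight layout: (8 * c_in, c_out), shift-major
        self.w = rng.uniform(-bound, bound, size=(8 * c_in, c_out)).astype(np.float32)
        self.b = rng.uniform(-bound, bound, size=(c_out,)).astype(np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._pool = _BufferPool()
        self._xp: np.ndarray | None = None

    def _micro_batch(self, voxels: int) -> int:
        return max(1, self._COL_BUDGET // (voxels * 8 * self.c_in))

    def _gather(self, xp: np.ndarray, b0: int, b1: int, do: int, ho: int, wo: int) -> np.ndarray:
        """im2col for samples [b0, b1): returns (rows, 8 * c_in)."""
        nb = b1 - b0
        col = self._pool.get("col", (nb * do * ho * wo, 8 * self.c_in))
        c = self.c_in
        for s, (di, dj, dk) in enumerate(_SHIFTS):
            dst = col[:, s * c:(s + 1) * c].reshape(nb, do, ho, wo, c)
            np.copyto(dst, xp[b0:b1, di:di + do, dj:dj + ho, dk:dk + wo, :])
        return col

    def forward(self, x, training, rng):
        p = self.pad
        if p:
            b, d0, h0, w0, c = x.shape
            xp = self._pool.get("xp", (b, d0 + 2 * p, h0 + 2 * p, w0 + 2 * p, c))
            xp.fill(0.0)
            xp[:, p:-p, p:-p, p:-p, :] = x
        else:
            xp = x
        b, d, h, w, _ = xp.shape
        do, ho, wo = d - 1, h - 1, w - 1
        if b * do * ho * wo * self.c_out > 1_000_000:
            y = self._pool.get("y", (b, do, ho, wo, self.c_out))
        else:
            y = np.empty((b, do, ho, wo, self.c_out), np.float32)
        y2 = y.reshape(-1, self.c_out)
        v = do * ho * wo
        mb = self._micro_batch(v)
        for b0 in range(0, b, mb):
            b1 = min(b0 + mb, b)
            col = self._gather(xp, b0, b1, do, ho, wo)
            np.matmul(col, self.w, out=y2[b0 * v:b1 * v])
        y2 += self.b
        if training:
            # keep the padded input (pooled; valid until the next forward of
            # this layer, and backward always runs first); im2col is
            # re-gathered from it in backward
            self._xp = xp
        self._out_dims = (do, ho, wo)
        return y

    def backward(self, dy):
        xp = self._xp
        assert xp is not None, "backward before forward(training=True)"
        b = xp.shape[0]
        do, ho, wo = self._out_dims
        v = do * ho * wo
        dy2 = dy.reshape(-1, self.c_out)
        self.db[...] = dy2.sum(axis=0)
        self.dw.fill(0.0)
        c = self.c_in
        dxp = None
        if self.input_grad:
            dxp = self._pool.get("dxp", xp.shape)
            dxp.fill(0.0)
        mb = self._micro_batch(v)
        for b0 in range(0, b, mb):
            b1 = min(b0 + mb, b)
            col = self._gather(xp, b0, b1, do, ho, wo)
            dyc = dy2[b0 * v:b1 * v]
            self.dw += col.T @ dyc
            if dxp is None:
                continue
            dcol = self._pool.get("dcol", ((b1 - b0) * v, 8 * c))
            np.matmul(dyc, self.w.T, out=dcol)
            for s, (di, dj, dk) in enumerate(_SHIFTS):
                block = dcol[:, s * c:(s + 1) * c].reshape(b1 - b0, do, ho, wo, c)
                dxp[b0:b1, di:di + do, dj:dj + ho, dk:dk + wo, :] += block
        p = self.pad
        self._xp = None
        if dxp is None:
            return None
        if p:
            inner = dxp[:, p:-p, p:-p, p:-p, :]
            out = self._pool.get("dx_out", inner.shape)
            np.copyto(out, inner)
            return out
        return dxp

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channel) axis.

    Serves both the volumetric (BatchNorm3d) and dense (BatchNorm1d) uses;
    running statistics (momentum 0.1) are used at evaluation time.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 inplace: bool = False):
        self.inplace = inplace
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._pool = _BufferPool()

    def forward(self, x, training, rng):
        c = x.shape[-1]
        x2 = x.reshape(-1, c)
        n = x2.shape[0]
        if training:
            mean = x2.mean(axis=0)
            # var via sum of squares; avoids a second full pass with temporaries
            sq = np.einsum("ij,ij->j", x2, x2) / n
            var = np.maximum(sq - mean * mean, 0.0)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mean
            self.running_var[...] = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = self._pool.get("xhat", x2.shape)
        np.subtract(x2, mean.astype(np.float32), out=xhat)
        xhat *= invstd
        # in-place mode overwrites the caller's buffer (conv outputs are
        # pooled, so inside the assembled network this is safe and halves
        # the activation footprint)
        y = x2 if self.inplace else self._pool.get("y", x2.shape)
        np.multiply(xhat, self.gamma, out=y)
        y += self.beta
        if training:
            self._xhat, self._invstd = xhat, invstd
        return y.reshape(x.shape)

    def backward(self, dy):
        xhat, invstd = self._xhat, self._invstd
        c = dy.shape[-1]
        dy2 = dy.reshape(-1, c)
        n = dy2.shape[0]
        self.dgamma[...] = np.einsum("ij,ij->j", dy2, xhat)
        self.dbeta[...] = dy2.sum(axis=0)
        # dx = (dxhat - mean(dxhat) - xhat * mean(dxhat * xhat)) * invstd,
        # computed in place on dy (the upstream buffer is spent here) with
        # row-chunked temporaries to avoid a full-size scratch array
        coef = (self.gamma * self.dgamma / n).astype(np.float32)
        shift = (self.gamma * self.dbeta / n).astype(np.float32)
        dy2 *= self.gamma
        dy2 -= shift
        step = max(1, 8_000_000 // max(c, 1))
        for r0 in range(0, n, step):
            dy2[r0:r0 + step] -= xhat[r0:r0 + step] * coef
        dy2 *= invstd
        self._xhat = None
        return dy2.reshape(dy.shape)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU(Layer):
    def __init__(self, inplace: bool = False):
        self.inplace = inplace
        self._pool = _BufferPool()

    def forward(self, x, training, rng):
        y = x if self.inplace else self._pool.get("y", x.shape)
        np.maximum(x, 0, out=y)
        if training:
            mask = self._pool.get("mask", x.shape, dtype=bool)
            np.greater(y, 0, out=mask)
            self._mask = mask
        return y

    def backward(self, dy):
        # overwrite dy in place: the upstream buffer is spent at this point
        dy *= self._mask
        self._mask = None
        return dy


class MaxPool3d(Layer):
    """Kernel-2, stride-2 max pooling; a trailing odd cell is dropped."""

    def __init__(self):
        self._pool = _BufferPool()

    def forward(self, x, training, rng):
        b, d, h, w, c = x.shape
        do, ho, wo = d // 2, h // 2, w // 2
        if min(do, ho, wo) < 1:
            raise ValueError(f"max-pool underflow: input side {min(d, h, w)} < 2")
        xc = x[:, :2 * do, :2 * ho, :2 * wo, :]
        win = xc.reshape(b, do, 2, ho, 2, wo, 2, c)
        y = self._pool.get("y", (b, do, ho, wo, c))
        win.max(axis=(2, 4, 6), out=y)
        if training:
            self._crop = (2 * do, 2 * ho, 2 * wo)
            self._in_shape = x.shape
            # route gradient to every element attaining the window maximum
            mask = self._pool.get("mask", win.shape, dtype=bool)
            np.equal(win, y[:, :, None, :, None, :, None, :], out=mask)
            self._mask = mask
        return y

    def backward(self, dy):
        dx = self._pool.get("dx", self._in_shape)
        dx.fill(0.0)
        cd, chh, cw = self._crop
        # one strided assignment per window offset instead of a full-size
        # expanded-gradient scratch array
        for oi in (0, 1):
            for oj in (0, 1):
                for ok in (0, 1):
                    dst = dx[:, oi:cd:2, oj:chh:2, ok:cw:2, :]
                    np.multiply(self._mask[:, :, oi, :, oj, :, ok, :], dy, out=dst)
        self._mask = None
        return dx


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(f_in)
        self.w = rng.uniform(-bound, bound, size=(f_in, f_out)).astype(np.float32)
        self.b = rng.uniform(-bound, bound, size=(f_out,)).astype(np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training, rng):
        if training:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        dx = dy @ self.w.T
        self._x = None
        return dx

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p

    def forward(self, x, training, rng):
        if not training or self.p == 0:
            self._mask = None
            return x
        assert rng is not None, "dropout in training mode needs an rng"
        self._mask = (rng.random(x.shape) >= self.p).astype(np.float32) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class Sequential:
    """A plain layer stack with shared forward/backward plumbing."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def state(self) -> list[np.ndarray]:
        """Deep copy of parameters and batch-norm running statistics."""
        out = [p.copy() for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                out.extend([layer.running_mean.copy(), layer.running_var.copy()])
        return out

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        state = list(state)
        n = len(self.params())
        for p, s in zip(self.params(), state[:n]):
            p[...] = s
        it = iter(state[n:])
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)

    def clone(self) -> "Sequential":
        return copy.deepcopy(self)


class Adam:
    """Adam optimizer over a parameter list (in-place updates)."""

    def __init__(self, params: Sequence[np.ndarray], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        scratch = np.empty(max(p.size for p in self.params), np.float32)
        self._tmp = [scratch[:p.size].reshape(p.shape) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v, tmp in zip(self.params, grads, self.m, self.v, self._tmp):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            np.multiply(g, g, out=tmp)
            tmp *= 1 - self.b2
            v += tmp
            np.divide(v, b2t, out=tmp)
            np.sqrt(tmp, out=tmp)
            tmp += self.eps
            np.divide(m, tmp, out=tmp)
            tmp *= self.lr / b1t
            p -= tmp


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean-square error and its gradient with respect to ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, (2.0 / diff.size) * diff.astype(np.float32)
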