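"""Minimal NHWC neural-network layer library (numpy, CPU).

Implements exactly the operations the fusion architecture needs: 2-D
convolution and fractional-stride (transposed) convolution via im2col + BLAS
matmul, batch normalization, ReLU, max/average pooling, dropout, linear
layers, softmax cross-entropy and SGD with momentum + weight decay.  Tensors
are float32 in (N, H, W, C) layout, which keeps the im2col copies contiguous
and the matmuls large.

Every module implements ``forward(x, training=False)`` and ``backward(dy)``;
forward caches are only retained while gradients are enabled (see
:func:`no_grad`), so inference over large batches stays memory-lean.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = [True]


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[0]


@contextlib.contextmanager
def no_grad():
    """Disable forward caching (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = None

    @property
    def shape(self):
        return self.value.shape


class Module:
    def forward(self, x, training: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x, training: bool = False):
        return self.forward(x, training)

    def _children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
            elif isinstance(v, dict):
                for item in v.values():
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list:
        params = [v for v in self.__dict__.values() if isinstance(v, Param)]
        for child in self._children():
            params.extend(child.parameters())
        return params

    def modules(self) -> list:
        out = [self]
        for child in self._children():
            out.extend(child.modules())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def state_dict(self) -> dict:
        state = {"params": [p.value.copy() for p in self.parameters()],
                 "buffers": []}
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                state["buffers"].append((m.running_mean.copy(), m.running_var.copy()))
        return state

    def load_state_dict(self, state: dict) -> None:
        for p, v in zip(self.parameters(), state["params"], strict=True):
            p.value = v.copy()
        bns = [m for m in self.modules() if isinstance(m, BatchNorm2d)]
        for m, (mean, var) in zip(bns, state["buffers"], strict=True):
            m.running_mean, m.running_var = mean.copy(), var.copy()


def _rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


# ---------------------------------------------------------------- conv plumbing

def _im2col(xp: np.ndarray, k: int, stride: int):
    """xp: padded (N, Hp, Wp, C).  Returns (cols, Ho, Wo) with rows ordered
    (n, ho, wo) and columns ordered (ki, kj, c)."""
    n, hp, wp, c = xp.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    cols = np.empty((n * ho * wo, k * k * c), dtype=np.float32)
    idx = 0
    for i in range(k):
        for j in range(k):
            patch = xp[:, i:i + stride * ho:stride, j:j + stride * wo:stride, :]
            cols[:, idx * c:(idx + 1) * c] = patch.reshape(-1, c)
            idx += 1
    return cols, ho, wo


def _col2im(dcols: np.ndarray, xp_shape, k: int, stride: int, ho: int, wo: int):
    n, hp, wp, c = xp_shape
    dxp = np.zeros(xp_shape, dtype=np.float32)
    idx = 0
    for i in range(k):
        for j in range(k):
            dxp[:, i:i + stride * ho:stride, j:j + stride * wo:stride, :] += (
                dcols[:, idx * c:(idx + 1) * c].reshape(n, ho, wo, c))
            idx += 1
    return dxp


class Conv2d(Module):
    """2-D convolution.

    Stride-1 convolutions accumulate one broadcast matmul per kernel tap over
    contiguous input views (fast, no im2col buffer); strided convolutions fall
    back to explicit im2col + one large matmul.
    """

    def __init__(self, cin, cout, k, stride=1, pad=0, bias=True, rng=0):
        rng = _rng(rng)
        std = np.sqrt(2.0 / (k * k * cin))
        self.W = Param(rng.normal(0, std, (k * k * cin, cout)))
        self.b = Param(np.zeros(cout)) if bias else None
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        self._cache = None

    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        n, hp, wp, c = xp.shape
        ho = (hp - self.k) // self.stride + 1
        wo = (wp - self.k) // self.stride + 1
        if self.stride == 1:
            out = None
            for idx, (i, j) in enumerate(self._taps()):
                Wt = self.W.value[idx * c:(idx + 1) * c]
                term = xp[:, i:i + ho, j:j + wo, :] @ Wt
                out = term if out is None else out + term
            if is_grad_enabled():
                self._cache = ("taps", xp, ho, wo)
        else:
            cols, ho, wo = _im2col(xp, self.k, self.stride)
            out = (cols @ self.W.value).reshape(n, ho, wo, self.cout)
            if is_grad_enabled():
                self._cache = ("cols", cols, xp.shape, ho, wo)
        if self.b is not None:
            out += self.b.value
        return out

    def _taps(self):
        return [(i, j) for i in range(self.k) for j in range(self.k)]

    def backward(self, dy):
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        if self.b is not None:
            self.b.grad = dy.reshape(-1, self.cout).sum(axis=0)
        p = self.pad
        if self._cache[0] == "taps":
            _, xp, ho, wo = self._cache
            c = xp.shape[3]
            self.W.grad = np.empty_like(self.W.value)
            dxp = np.zeros(xp.shape, dtype=np.float32)
            for idx, (i, j) in enumerate(self._taps()):
                sl = xp[:, i:i + ho, j:j + wo, :]
                self.W.grad[idx * c:(idx + 1) * c] = np.tensordot(
                    sl, dy, axes=([0, 1, 2], [0, 1, 2]))
                Wt = self.W.value[idx * c:(idx + 1) * c]
                dxp[:, i:i + ho, j:j + wo, :] += dy @ Wt.T
            xp_shape = xp.shape
        else:
            _, cols, xp_shape, ho, wo = self._cache
            dyf = dy.reshape(-1, self.cout)
            self.W.grad = cols.T @ dyf
            dcols = dyf @ self.W.value.T
            dxp = _col2im(dcols, xp_shape, self.k, self.stride, ho, wo)
        self._cache = None
        return dxp[:, p:xp_shape[1] - p, p:xp_shape[2] - p, :] if p else dxp


class ConvTranspose2d(Module):
    """Fractional-stride convolution (output side = (H-1)*stride + k - 2*pad).

    Equivalent to convolving the zero-stuffed input, but implemented by
    stride-parity decomposition: each output parity class (oy % s, ox % s)
    touches a fixed subset of kernel taps, so no zero-stuffed buffer is ever
    materialized and no multiply is wasted on stuffed zeros.
    """

    def __init__(self, cin, cout, k, stride=1, pad=0, bias=True, rng=0):
        rng = _rng(rng)
        std = np.sqrt(2.0 / (k * k * cin))
        # rows ordered (u, v, cin) like Conv2d's im2col layout
        self.W = Param(rng.normal(0, std, (k * k * cin, cout)))
        self.b = Param(np.zeros(cout)) if bias else None
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        self._cache = None
        pe = k - 1 - pad  # effective padding of the stuffed input
        if pe < 0:
            raise ValueError("pad must be <= k - 1")
        # per parity class: list of (tap index u, input offset delta)
        self._taps = []
        for a in range(stride):
            taps = [(u, (u + a - pe) // stride) for u in range(k)
                    if (u + a - pe) % stride == 0]
            self._taps.append(taps)
        self._delta_max = max(abs(d) for taps in self._taps for _, d in taps)

    def _out_side(self, h):
        return (h - 1) * self.stride + self.k - 2 * self.pad

    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        n, h, w, c = x.shape
        ho, wo = self._out_side(h), self._out_side(w)
        D = self._delta_max
        xp = np.pad(x, ((0, 0), (D, D), (D, D), (0, 0)))
        out = np.empty((n, ho, wo, self.cout), dtype=np.float32)
        for a in range(self.stride):
            n_q = len(range(a, ho, self.stride))
            for bpar in range(self.stride):
                n_r = len(range(bpar, wo, self.stride))
                par = None
                for u, du in self._taps[a]:
                    for v, dv in self._taps[bpar]:
                        row = (u * self.k + v) * c
                        Wt = self.W.value[row:row + c]
                        sl = xp[:, du + D:du + D + n_q, dv + D:dv + D + n_r, :]
                        term = sl @ Wt
                        par = term if par is None else par + term
                out[:, a::self.stride, bpar::self.stride, :] = par
        if self.b is not None:
            out += self.b.value
        if is_grad_enabled():
            self._cache = (xp, x.shape, (ho, wo))
        return out

    def backward(self, dy):
        xp, x_shape, (ho, wo) = self._cache
        n, h, w, c = x_shape
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        if self.b is not None:
            self.b.grad = dy.reshape(-1, self.cout).sum(axis=0)
        self.W.grad = np.zeros_like(self.W.value)
        dxp = np.zeros(xp.shape, dtype=np.float32)
        D = self._delta_max
        for a in range(self.stride):
            n_q = len(range(a, ho, self.stride))
            for bpar in range(self.stride):
                n_r = len(range(bpar, wo, self.stride))
                dy_par = np.ascontiguousarray(
                    dy[:, a::self.stride, bpar::self.stride, :])
                for u, du in self._taps[a]:
                    for v, dv in self._taps[bpar]:
                        row = (u * self.k + v) * c
                        sl = xp[:, du + D:du + D + n_q, dv + D:dv + D + n_r, :]
                        self.W.grad[row:row + c] += np.tensordot(
                            sl, dy_par, axes=([0, 1, 2], [0, 1, 2]))
                        Wt = self.W.value[row:row + c]
                        dxp[:, du + D:du + D + n_q, dv + D:dv + D + n_r, :] += (
                            dy_par @ Wt.T)
        self._cache = None
        return dxp[:, D:D + h, D:D + w, :] if D else dxp


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.calibrating = False  # cumulative-mean running-stat estimation
        self._calib_n = 0
        self._cache = None

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=np.float32)
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if self.calibrating:
                self._calib_n += 1
                w = 1.0 / self._calib_n
                self.running_mean = (1 - w) * self.running_mean + w * mean
                self.running_var = (1 - w) * self.running_var + w * var
            else:
                m = self.momentum
                self.running_mean = (1 - m) * self.running_mean + m * mean
                self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        if not is_grad_enabled():  # fused inference path: one multiply-add
            scale = self.gamma.value * inv
            return x * scale + (self.beta.value - mean * scale)
        xhat = (x - mean) * inv
        out = self.gamma.value * xhat + self.beta.value
        self._cache = (xhat, inv, x.shape, axes, training)
        return out

    def backward(self, dy):
        xhat, inv, shape, axes, training = self._cache
        dy = dy.astype(np.float32)
        self.gamma.grad = (dy * xhat).sum(axis=axes)
        self.beta.grad = dy.sum(axis=axes)
        if not training:
            self._cache = None
            return dy * self.gamma.value * inv
        m = np.prod([shape[a] for a in axes])
        dxhat = dy * self.gamma.value
        dx = (dxhat - dxhat.mean(axis=axes)
              - xhat * (dxhat * xhat).mean(axis=axes)) * inv
        self._cache = None
        return dx


class ReLU(Module):
    def forward(self, x, training=False):
        out = np.maximum(x, 0.0)
        if is_grad_enabled():
            self._mask = x > 0
        return out

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class Dropout(Module):
    def __init__(self, p=0.5, rng=0):
        self.p = p
        self.rng = _rng(rng)

    def forward(self, x, training=False):
        if not training or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.uniform(size=x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Linear(Module):
    def __init__(self, cin, cout, rng=0):
        rng = _rng(rng)
        std = np.sqrt(2.0 / cin)
        self.W = Param(rng.normal(0, std, (cin, cout)))
        self.b = Param(np.zeros(cout))
        self._cache = None

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=np.float32)
        if is_grad_enabled():
            self._cache = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        x = self._cache
        dy = dy.astype(np.float32)
        self.W.grad = x.T @ dy
        self.b.grad = dy.sum(axis=0)
        self._cache = None
        return dy @ self.W.value.T


class MaxPool2d(Module):
    def __init__(self, k, stride, pad=0):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=np.float32)
        p = self.pad
        xp = (np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)),
                     constant_values=-np.inf) if p else x)
        n, hp, wp, c = xp.shape
        ho = (hp - self.k) // self.stride + 1
        wo = (wp - self.k) // self.stride + 1
        if not is_grad_enabled():  # fast inference path: separable max
            rows = None
            for i in range(self.k):
                sl = xp[:, i:i + self.stride * ho:self.stride, :, :]
                rows = sl.copy() if rows is None else np.maximum(rows, sl)
            out = None
            for j in range(self.k):
                sl = rows[:, :, j:j + self.stride * wo:self.stride, :]
                out = sl.copy() if out is None else np.maximum(out, sl)
            return out
        stack = np.stack([
            xp[:, i:i + self.stride * ho:self.stride,
               j:j + self.stride * wo:self.stride, :]
            for i in range(self.k) for j in range(self.k)])
        arg = stack.argmax(axis=0)
        out = np.take_along_axis(stack, arg[None], axis=0)[0]
        self._cache = (arg, xp.shape, ho, wo)
        return out

    def backward(self, dy):
        arg, xp_shape, ho, wo = self._cache
        dxp = np.zeros(xp_shape, dtype=np.float32)
        idx = 0
        for i in range(self.k):
            for j in range(self.k):
                sel = arg == idx
                view = dxp[:, i:i + self.stride * ho:self.stride,
                           j:j + self.stride * wo:self.stride, :]
                view += dy * sel
                idx += 1
        p = self.pad
        self._cache = None
        return dxp[:, p:xp_shape[1] - p, p:xp_shape[2] - p, :] if p else dxp


class AvgPool2d(Module):
    def __init__(self, k, stride):
        self.k, self.stride = k, stride

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=np.float32)
        n, h, w, c = x.shape
        ho = (h - self.k) // self.stride + 1
        wo = (w - self.k) // self.stride + 1
        out = np.zeros((n, ho, wo, c), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                out += x[:, i:i + self.stride * ho:self.stride,
                         j:j + self.stride * wo:self.stride, :]
        if is_grad_enabled():
            self._cache = (x.shape, ho, wo)
        return out / (self.k * self.k)

    def backward(self, dy):
        x_shape, ho, wo = self._cache
        dx = np.zeros(x_shape, dtype=np.float32)
        dy = dy / (self.k * self.k)
        for i in range(self.k):
            for j in range(self.k):
                dx[:, i:i + self.stride * ho:self.stride,
                   j:j + self.stride * wo:self.stride, :] += dy
        self._cache = None
        return dx


class GlobalAvgPool(Module):
    def forward(self, x, training=False):
        if is_grad_enabled():
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w),
                               self._shape).astype(np.float32)


class Normalize(Module):
    """Fixed (x - mean) / std input standardization; no trainable state."""

    def __init__(self, mean=0.45, std=0.25):
        self.mean, self.std = mean, std

    def forward(self, x, training=False):
        return (np.asarray(x, dtype=np.float32) - self.mean) / self.std

    def backward(self, dy):
        return dy / self.std


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


# ----------------------------------------------------------------- loss / opt

def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(dprobs: np.ndarray, probs: np.ndarray) -> np.ndarray:
    dot = (dprobs * probs).sum(axis=-1, keepdims=True)
    return probs * (dprobs - dot)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = len(labels)
    loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class SGD:
    """SGD with momentum and decoupled-from-nothing classic weight decay."""

    def __init__(self, params, lr=0.01, momentum=0.9, weight_decay=0.001):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value = p.value - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def set_bn_calibration(module: Module, on: bool) -> None:
    """Toggle cumulative-mean running-stat calibration on every BatchNorm."""
    for m in module.modules():
        if isinstance(m, BatchNorm2d):
            m.calibrating = on
            if on:
                m._calib_n = 0
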