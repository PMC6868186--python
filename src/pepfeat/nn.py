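"""Minimal neural-network primitives (NumPy, manual gradients).

The two models in this package use bespoke recurrences — a fully-connected
recurrence injected between two dense layers, and an attention-gated state
update — that are simple enough to express directly with NumPy. This module
provides the forward/backward building blocks: valid/same 2-D convolution,
2x2 max pooling, dense layers, inverted dropout, a masked sparse softmax
cross-entropy, and the Adam/Adagrad optimisers used to train them.

All image tensors are NHWC ``float32``. Layers accumulate gradients in-place
(``gW``/``gb``); an optimiser zeroes them after each step.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

Array = np.ndarray

# ---------------------------------------------------------------------------
# activations


def tanh(x: Array) -> Array:
    return np.tanh(x)


def dtanh_from_out(y: Array) -> Array:
    """Derivative of tanh expressed through its output ``y = tanh(x)``."""
    return 1.0 - y * y


def sigmoid(x) -> Array:
    x = np.asarray(x)
    z = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + z), z / (1.0 + z))


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int,
                   dtype=np.float32) -> Array:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


# ---------------------------------------------------------------------------
# layers


class Conv2D:
    """2-D cross-correlation over NHWC input, optional tanh, valid/same padding.

    ``stride`` applies to (rows, cols). 'same' padding is only supported with
    unit stride (sufficient for the grouping model's small frames).
    """

    def __init__(self, rng, in_ch: int, out_ch: int, kernel=(3, 5),
                 stride=(1, 1), padding: str = "valid", activation: str | None = "tanh"):
        kh, kw = kernel
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        if padding == "same" and stride != (1, 1):
            raise ValueError("'same' padding requires unit stride")
        self.kernel = (kh, kw)
        self.stride = tuple(stride)
        self.padding = padding
        self.activation = activation
        self.W = glorot_uniform(rng, (kh, kw, in_ch, out_ch),
                                kh * kw * in_ch, kh * kw * out_ch)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def variables(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def _pad(self, x: Array) -> Array:
        if self.padding == "valid":
            return x
        kh, kw = self.kernel
        ph, pw = (kh - 1) // 2, (kw - 1) // 2
        return np.pad(x, ((0, 0), (ph, kh - 1 - ph), (pw, kw - 1 - pw), (0, 0)))

    def _out_shape(self, xp):
        kh, kw = self.kernel
        sh, sw = self.stride
        return (xp.shape[1] - kh) // sh + 1, (xp.shape[2] - kw) // sw + 1

    def _row_windows(self, xp: Array, i: int, ho: int, wo: int) -> Array:
        """Contiguous (B*Ho*Wo, kw*C) patch rows for kernel-row offset i.

        Along the width axis each window is a *contiguous* run of kw*C
        floats in memory, so the copy is cheap — this is the reason the
        patch matrix is assembled row-of-kernel-wise instead of as one
        6-D im2col gather.
        """
        kh, kw = self.kernel
        sh, sw = self.stride
        c = xp.shape[3]
        flat = xp.reshape(xp.shape[0], xp.shape[1], -1)
        win = sliding_window_view(flat, kw * c, axis=2)[:, :, ::sw * c]
        rows = win[:, i:i + sh * ho:sh, :wo]
        return np.ascontiguousarray(rows).reshape(-1, kw * c)

    def forward(self, x: Array, cache: bool = True):
        xp = self._pad(x.astype(np.float32, copy=False))
        kh, kw = self.kernel
        b, _, _, c = xp.shape
        ho, wo = self._out_shape(xp)
        out_ch = self.W.shape[-1]
        wrows = self.W.reshape(kh, kw * c, out_ch)
        z = None
        for i in range(kh):
            zi = self._row_windows(xp, i, ho, wo) @ wrows[i]
            z = zi if z is None else z + zi
        z += self.b
        z = z.reshape(b, ho, wo, out_ch)
        y = np.tanh(z) if self.activation == "tanh" else z
        return y, (x, y) if cache else None

    def backward(self, dy: Array, cache) -> Array:
        x, y = cache
        dz = dy * dtanh_from_out(y) if self.activation == "tanh" else dy
        kh, kw = self.kernel
        sh, sw = self.stride
        xp = self._pad(x.astype(np.float32, copy=False))
        b, _, _, c = xp.shape
        ho, wo = self._out_shape(xp)
        out_ch = self.W.shape[-1]
        dz2 = dz.reshape(-1, out_ch)
        self.gb += dz2.sum(axis=0)
        gw = self.gW.reshape(kh, kw * c, out_ch)
        for i in range(kh):
            gw[i] += self._row_windows(xp, i, ho, wo).T @ dz2
        dcols = (dz2 @ self.W.reshape(-1, out_ch).T).reshape(b, ho, wo, kh, kw, c)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i:i + sh * ho:sh, j:j + sw * wo:sw, :] += dcols[:, :, :, i, j, :]
        if self.padding == "same":
            ph, pw = (kh - 1) // 2, (kw - 1) // 2
            dxp = dxp[:, ph:ph + x.shape[1], pw:pw + x.shape[2], :]
        return dxp


class MaxPool2D:
    """2x2/stride-2 max pooling; odd trailing rows/cols are cropped."""

    def __init__(self, size: int = 2):
        self.size = size

    def variables(self):
        return []

    def forward(self, x: Array, cache: bool = True):
        s = self.size
        b, h, w, c = x.shape
        hc, wc = (h // s) * s, (w // s) * s
        win = x[:, :hc, :wc, :].reshape(b, hc // s, s, wc // s, s, c)
        flat = win.transpose(0, 1, 3, 5, 2, 4).reshape(b, hc // s, wc // s, c,
                                                       s * s)
        arg = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        return y, (x.shape, arg) if cache else None

    def backward(self, dy: Array, cache) -> Array:
        # gradient goes to exactly one (the first) maximal cell per window
        s = self.size
        shape, arg = cache
        b, ho, wo, c = dy.shape
        dflat = np.zeros((b, ho, wo, c, s * s), dtype=dy.dtype)
        np.put_along_axis(dflat, arg[..., None], dy[..., None], axis=-1)
        dwin = dflat.reshape(b, ho, wo, c, s, s).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(shape, dtype=dy.dtype)
        dx[:, :ho * s, :wo * s, :] = dwin.reshape(b, ho * s, wo * s, c)
        return dx


class Dense:
    def __init__(self, rng, n_in: int, n_out: int, activation: str | None = "tanh"):
        self.activation = activation
        self.W = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def variables(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x: Array, cache: bool = True):
        z = x @ self.W + self.b
        y = np.tanh(z) if self.activation == "tanh" else z
        return y, (x, y) if cache else None

    def backward(self, dy: Array, cache) -> Array:
        x, y = cache
        dz = dy * dtanh_from_out(y) if self.activation == "tanh" else dy
        self.gW += x.T @ dz
        self.gb += dz.sum(axis=0)
        return dz @ self.W.T


def dropout_forward(x: Array, rate: float, rng: np.random.Generator,
                    training: bool):
    """Inverted dropout; identity at inference. Returns (y, mask)."""
    if not training or rate <= 0.0:
        return x, None
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
    return x * mask, mask


def dropout_backward(dy: Array, mask) -> Array:
    return dy if mask is None else dy * mask


# ---------------------------------------------------------------------------
# loss


def softmax(logits: Array) -> Array:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: Array, labels: Array, mask: Array | None = None):
    """Mean sparse softmax cross-entropy.

    ``logits``: (B, K); ``labels``: (B,) integer classes; ``mask``: optional
    (B,) weights — frames with zero weight contribute no loss or gradient.
    Returns (loss, dlogits).
    """
    p = softmax(logits)
    b = logits.shape[0]
    idx = np.arange(b)
    nll = -np.log(np.clip(p[idx, labels], 1e-12, None))
    if mask is None:
        w = np.ones(b, dtype=logits.dtype)
    else:
        w = mask.astype(logits.dtype)
    denom = max(float(w.sum()), 1.0)
    loss = float((nll * w).sum() / denom)
    dlogits = p
    dlogits[idx, labels] -= 1.0
    dlogits *= (w / denom)[:, None]
    return loss, dlogits


# ---------------------------------------------------------------------------
# optimisers


def _clip_global(grads, clip: float | None):
    if clip is None:
        return
    total = np.sqrt(sum(float((g * g).sum()) for g in grads))
    if total > clip and total > 0:
        scale = clip / total
        for g in grads:
            g *= scale


class Adam:
    def __init__(self, variables, lr: float = 0.01, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, clip: float | None = 5.0):
        self.vars = list(variables)
        self.lr, self.b1, self.b2, self.eps, self.clip = lr, beta1, beta2, eps, clip
        self.m = [np.zeros_like(p) for p, _ in self.vars]
        self.v = [np.zeros_like(p) for p, _ in self.vars]
        self.t = 0

    def step(self):
        self.t += 1
        _clip_global([g for _, g in self.vars], self.clip)
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.vars, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            g[...] = 0.0


class Adagrad:
    def __init__(self, variables, lr: float = 0.07, eps: float = 1e-8,
                 clip: float | None = 5.0):
        self.vars = list(variables)
        self.lr, self.eps, self.clip = lr, eps, clip
        self.acc = [np.zeros_like(p) for p, _ in self.vars]

    def step(self):
        _clip_global([g for _, g in self.vars], self.clip)
        for (p, g), a in zip(self.vars, self.acc):
            a += g * g
            p -= self.lr * g / (np.sqrt(a) + self.eps)
            g[...] = 0.0


# ---------------------------------------------------------------------------
# recurrence primitives (pure functions; shared by the models and the tests)


def fc_rnn_state(x_i, f_prev, w_io, w_hh, b_o):
    """Fully-connected recurrence: ``f_t = tanh(W_io·X_it + W_hh·f_{t-1} + b_o)``.

    The recurrent state *is* the second dense layer's activation; the frame
    embedding enters through ``W_io`` and the previous state through ``W_hh``.
    """
    return np.tanh(np.dot(x_i, w_io) + np.dot(f_prev, w_hh) + b_o)


def attention_gate_state(x_o, f_prev, w_hh, w_oh, b_h, w_a, b_a):
    """Attention-gated recurrence.

    ``f'_t = tanh(W_hh·f_{t-1} + W_oh·X_ot + b_h)``;
    ``a_t = sigmoid(W_a·f'_t + b_a)`` (scalar per sample);
    ``f_t = (1 - a_t)·f_{t-1} + a_t·f'_t``.

    Returns ``(f_t, a_t, f_prime)``.
    """
    f_prime = np.tanh(np.dot(f_prev, w_hh) + np.dot(x_o, w_oh) + b_h)
    a = sigmoid(np.dot(f_prime, w_a) + b_a)
    f_t = (1.0 - a) * f_prev + a * f_prime
    return f_t, a, f_prime
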