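"""Minimal neural-network kernels (numpy, manual backprop, Adam).

Shared by the address-orientation CNN (:mod:`swingtrack.orient`) and the
bidirectional recurrent phase labeller (:mod:`swingtrack.segment`).  Only the
small pieces those two models need are implemented; everything is seeded
through the caller's Generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# ---------------------------------------------------------------------------
# optimizer


class AdamState:
    """Adam with bias correction; updates parameter arrays in place."""

    def __init__(self, shapes, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    @classmethod
    def for_params(cls, params, lr=1e-3, **kw):
        return cls([p.shape for p in params], lr=lr, **kw)

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# feed-forward pieces (batched: x is (B, C, L) or (B, D))


def conv1d_forward(x, w, b):
    """x (B, Ci, L), w (Co, Ci, K) -> out (B, Co, L-K+1)."""
    win = sliding_window_view(x, w.shape[2], axis=2)  # (B, Ci, Lo, K)
    out = np.einsum("oik,bilk->bol", w, win, optimize=True)
    out += b[None, :, None]
    return out, (x, win)


def conv1d_backward(dout, w, cache):
    x, win = cache
    dw = np.einsum("bol,bilk->oik", dout, win, optimize=True)
    db = dout.sum(axis=(0, 2))
    k = w.shape[2]
    dpad = np.pad(dout, ((0, 0), (0, 0), (k - 1, k - 1)))
    dwin = sliding_window_view(dpad, k, axis=2)  # (B, Co, L, K)
    dx = np.einsum("oik,bolk->bil", w[:, :, ::-1], dwin, optimize=True)
    return dx, dw, db


def maxpool1d_forward(x, pool):
    b, c, l = x.shape
    lo = l // pool
    xr = x[:, :, : lo * pool].reshape(b, c, lo, pool)
    idx = xr.argmax(axis=3)
    out = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]
    return out, (x.shape, pool, idx)


def maxpool1d_backward(dout, cache):
    shape, pool, idx = cache
    b, c, l = shape
    lo = l // pool
    dxr = np.zeros((b, c, lo, pool))
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=3)
    dx = np.zeros(shape)
    dx[:, :, : lo * pool] = dxr.reshape(b, c, lo * pool)
    return dx


def dense_forward(x, w, b):
    return x @ w + b, x


def dense_backward(dout, w, cache):
    x = cache
    return dout @ w.T, x.T @ dout, dout.sum(axis=0)


def tanh_forward(x):
    y = np.tanh(x)
    return y, y


def tanh_backward(dout, y):
    return dout * (1 - y * y)


# ---------------------------------------------------------------------------
# bidirectional Elman recurrence (single sequence, sequence labelling)


@dataclass
class BiRnnParams:
    wx_f: np.ndarray
    wh_f: np.ndarray
    b_f: np.ndarray
    wx_b: np.ndarray
    wh_b: np.ndarray
    b_b: np.ndarray
    wo: np.ndarray
    bo: np.ndarray

    @classmethod
    def init(cls, n_in: int, hidden: int, n_out: int, rng: np.random.Generator):
        def glorot(*shape):
            lim = np.sqrt(6.0 / sum(shape))
            return rng.uniform(-lim, lim, size=shape)

        return cls(
            wx_f=glorot(n_in, hidden),
            wh_f=glorot(hidden, hidden) * 0.5,
            b_f=np.zeros(hidden),
            wx_b=glorot(n_in, hidden),
            wh_b=glorot(hidden, hidden) * 0.5,
            b_b=np.zeros(hidden),
            wo=glorot(2 * hidden, n_out),
            bo=np.zeros(n_out),
        )

    def flat(self):
        return [self.wx_f, self.wh_f, self.b_f,
                self.wx_b, self.wh_b, self.b_b, self.wo, self.bo]


def _rnn_pass(x, wx, wh, b):
    t, h = x.shape[0], wh.shape[0]
    hs = np.zeros((t + 1, h))
    xs_wx = x @ wx + b
    for i in range(t):
        hs[i + 1] = np.tanh(xs_wx[i] + hs[i] @ wh)
    return hs


def birnn_forward(params: BiRnnParams, x: np.ndarray):
    """x (T, n_in) -> logits (T, n_out)."""
    hf = _rnn_pass(x, params.wx_f, params.wh_f, params.b_f)
    hb_rev = _rnn_pass(x[::-1], params.wx_b, params.wh_b, params.b_b)
    h_cat = np.hstack([hf[1:], hb_rev[1:][::-1]])
    logits = h_cat @ params.wo + params.bo
    return logits, (x, hf, hb_rev, h_cat)


def _rnn_bptt(x, hs, wx, wh, dh_seq):
    t = x.shape[0]
    dwx = np.zeros_like(wx)
    dwh = np.zeros_like(wh)
    db = np.zeros(wh.shape[0])
    dh_next = np.zeros(wh.shape[0])
    for i in range(t - 1, -1, -1):
        dh = dh_seq[i] + dh_next
        dz = dh * (1 - hs[i + 1] ** 2)
        dwx += np.outer(x[i], dz)
        dwh += np.outer(hs[i], dz)
        db += dz
        dh_next = dz @ wh.T
    return dwx, dwh, db


def birnn_backward(params: BiRnnParams, cache, dlogits):
    x, hf, hb_rev, h_cat = cache
    h = params.wh_f.shape[0]
    dwo = h_cat.T @ dlogits
    dbo = dlogits.sum(axis=0)
    dh_cat = dlogits @ params.wo.T
    dhf_seq = dh_cat[:, :h]
    dhb_seq = dh_cat[:, h:][::-1]
    dwx_f, dwh_f, db_f = _rnn_bptt(x, hf, params.wx_f, params.wh_f, dhf_seq)
    dwx_b, dwh_b, db_b = _rnn_bptt(x[::-1], hb_rev, params.wx_b, params.wh_b, dhb_seq)
    return [dwx_f, dwh_f, db_f, dwx_b, dwh_b, db_b, dwo, dbo]
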