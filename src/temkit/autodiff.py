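"""Reverse-mode automatic differentiation over numpy arrays.

The TEM training objective backpropagates through every forward computation of
the network -- including the Hebbian memory writes and the attractor iterations,
which are part of the forward pass rather than of the optimizer.  This module
provides the small tape-based engine that makes that possible: a :class:`Tensor`
wrapping an ndarray, the primitive operations the model needs, and an
:class:`Adam` optimizer.

Only the primitives actually used by the network are implemented; gradients are
verified against central finite differences in the test-suite.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True
DTYPE = np.float64


@contextlib.contextmanager
def no_grad():
    """Context manager that disables taping (fast inference-only forward)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextlib.contextmanager
def default_dtype(dt):
    """Context manager selecting the float precision of new tensors.

    Training runs in float32 (the model is memory-bandwidth-bound on the
    Hebbian matrices); float64 is the default for analysis and for the
    finite-difference gradient checks."""
    global DTYPE
    prev = DTYPE
    DTYPE = np.dtype(dt)
    try:
        yield
    finally:
        DTYPE = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents",
                 "_backward", "name", "tracked")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None,
                 name=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward
        self.name = name
        self.tracked = requires_grad or bool(_parents)

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if pg is None:
                    continue
                pid = id(parent)
                if pid in grads:
                    grads[pid] = grads[pid] + pg
                else:
                    grads[pid] = pg

    # -- operators --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return slice_(self, idx)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward):
    if _GRAD_ENABLED:
        for p in parents:
            if p.tracked:
                return Tensor(data, _parents=parents, _backward=backward)
    return Tensor(data)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data
    return _make(out, (a, b), lambda g: (
        _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)))


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data
    return _make(out, (a, b), lambda g: (
        _unbroadcast(g * b.data, a.data.shape),
        _unbroadcast(g * a.data, b.data.shape)))


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data / b.data
    return _make(out, (a, b), lambda g: (
        _unbroadcast(g / b.data, a.data.shape),
        _unbroadcast(-g * a.data / b.data ** 2, b.data.shape)))


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = np.matmul(a.data, b.data)

    def backward(g):
        ad, bd = a.data, b.data
        if ad.ndim == 1:
            ad2 = ad[None, :]
            ga = np.matmul(g[..., None, :], np.swapaxes(bd, -1, -2))[..., 0, :]
        else:
            ad2 = ad
            ga = np.matmul(g if bd.ndim > 1 else g[..., :, None],
                           np.swapaxes(bd, -1, -2) if bd.ndim > 1 else bd[None, :])
        if bd.ndim == 1:
            gb = np.matmul(np.swapaxes(ad2, -1, -2), g[..., :, None])[..., 0]
        else:
            gb = np.matmul(np.swapaxes(ad2, -1, -2) if ad.ndim > 1 else ad[:, None],
                           g if ad.ndim > 1 else g[..., None, :])
        return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

    return _make(out, (a, b), backward)


def reshape(a, shape):
    a = as_tensor(a)
    out = a.data.reshape(shape)
    return _make(out, (a,), lambda g: (g.reshape(a.data.shape),))


def transpose(a, axes):
    a = as_tensor(a)
    out = np.transpose(a.data, axes)
    inv = np.argsort(axes)
    return _make(out, (a,), lambda g: (np.transpose(g, inv),))


def _is_basic_index(idx):
    items = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(i, (int, np.integer, slice)) or i is Ellipsis
               for i in items)


def slice_(a, idx):
    a = as_tensor(a)
    out = a.data[idx]
    basic = _is_basic_index(idx)

    def backward(g):
        ga = np.zeros_like(a.data)
        if basic:
            ga[idx] += g
        else:
            np.add.at(ga, idx, g)
        return (ga,)

    return _make(out, (a,), backward)


def concat(tensors, axis=-1):
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(out, tuple(tensors), backward)


def sum_(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        g2 = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(g2, a.data.shape).copy(),)

    return _make(out, (a,), backward)


def mean_(a, axis=None, keepdims=False):
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(sum_(a, axis, keepdims), 1.0 / n)


def square(a):
    a = as_tensor(a)
    return _make(a.data ** 2, (a,), lambda g: (2.0 * a.data * g,))


def exp(a):
    a = as_tensor(a)
    out = np.exp(a.data)
    return _make(out, (a,), lambda g: (g * out,))


def log(a):
    a = as_tensor(a)
    return _make(np.log(a.data), (a,), lambda g: (g / a.data,))


def sqrt(a):
    a = as_tensor(a)
    out = np.sqrt(a.data)
    return _make(out, (a,), lambda g: (0.5 * g / out,))


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0
    return _make(a.data * mask, (a,), lambda g: (g * mask,))


def elu(a, alpha=1.0):
    a = as_tensor(a)
    neg = a.data < 0
    ex = np.exp(np.minimum(a.data, 0.0))
    out = np.where(neg, alpha * (ex - 1.0), a.data)
    return _make(out, (a,), lambda g: (np.where(neg, g * alpha * ex, g),))


def softplus(a):
    a = as_tensor(a)
    out = np.logaddexp(0.0, a.data)
    sig = 1.0 / (1.0 + np.exp(-a.data))
    return _make(out, (a,), lambda g: (g * sig,))


def sigmoid(a):
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-a.data))
    return _make(out, (a,), lambda g: (g * out * (1.0 - out),))


def leaky_clamp(a, leak=0.01, lo=-1.0, hi=1.0):
    """Bounded activation for g and p: clip values to [lo, hi].

    The forward pass clips hard (components stay exactly within bounds, which
    the memory dynamics rely on); the backward pass uses a straight-through
    leak of slope `leak` outside the bounds so saturated units keep learning."""
    a = as_tensor(a)
    x = a.data
    inside = (x >= lo) & (x <= hi)
    out = np.clip(x, lo, hi)
    slope = np.where(inside, 1.0, leak)
    return _make(out, (a,), lambda g: (g * slope,))


def leaky_relu_clamp(a, leak=0.01, hi=1.0):
    """Leaky-rectified linear unit additionally thresholded at `hi`.

    Negative inputs are attenuated by `leak` (true leaky ReLU, so near-zero
    products stay near zero); values above `hi` are clipped with a
    straight-through leak gradient."""
    a = as_tensor(a)
    x = a.data
    out = np.clip(np.where(x < 0, leak * x, x), -hi, hi)
    slope = np.where((x < 0) | (x > hi), leak, 1.0)
    slope = np.where(leak * x < -hi, leak * leak, slope)
    return _make(out, (a,), lambda g: (g * slope,))


def take0(w, idx):
    """Index the leading axis of a parameter with an integer array.

    Used to select per-action transition matrices: ``w`` has shape
    (n_actions, n, n) and ``idx`` shape (B,); output (B, n, n)."""
    w = as_tensor(w)
    idx = np.asarray(idx)
    out = w.data[idx]

    def backward(g):
        gw = np.zeros_like(w.data)
        np.add.at(gw, idx, g)
        return (gw,)

    return _make(out, (w,), backward)


def tile_last(a, k):
    """Concatenate k copies of `a` along the last axis (np.tile semantics)."""
    a = as_tensor(a)
    out = np.tile(a.data, (1,) * (a.data.ndim - 1) + (k,))

    def backward(g):
        return (g.reshape(g.shape[:-1] + (k, a.data.shape[-1])).sum(-2),)

    return _make(out, (a,), backward)


def repeat_last(a, k):
    """Repeat each element of the last axis k times (np.repeat semantics)."""
    a = as_tensor(a)
    out = np.repeat(a.data, k, axis=-1)

    def backward(g):
        return (g.reshape(g.shape[:-1] + (a.data.shape[-1], k)).sum(-1),)

    return _make(out, (a,), backward)


def hebbian_update(M, p, p_hat, lam, eta, mask=None):
    """Fused rank-1 memory write: lam * M + eta * ((p - p_hat)(p + p_hat)^T),
    optionally projected onto a fixed 0/1 block mask.

    M: (B, P, P); p, p_hat: (B, P).  A single tape node keeps the BPTT graph
    small on the largest tensors in the model."""
    M, p, p_hat = as_tensor(M), as_tensor(p), as_tensor(p_hat)
    a = p.data - p_hat.data
    b = p.data + p_hat.data
    upd = np.multiply(a[:, :, None], b[:, None, :])
    if mask is not None:
        upd *= mask
    upd *= eta
    upd += lam * M.data
    out = upd

    def backward(g):
        gm = g if mask is None else g * mask
        ga = eta * np.matmul(gm, b[:, :, None])[:, :, 0]
        gb = eta * np.matmul(a[:, None, :], gm)[:, 0, :]
        return (lam * g, ga + gb, gb - ga)

    return _make(out, (M, p, p_hat), backward)


def attractor_step(h, M, kappa):
    """Fused pre-activation of one attractor iteration: kappa*h + M h.

    h: (B, P); M: (B, P, P)."""
    h, M = as_tensor(h), as_tensor(M)
    out = kappa * h.data + np.matmul(M.data, h.data[:, :, None])[:, :, 0]

    def backward(g):
        gh = kappa * g + np.matmul(g[:, None, :], M.data)[:, 0, :]
        gM = g[:, :, None] * h.data[:, None, :]
        return (gh, gM)

    return _make(out, (h, M), backward)


def attractor_sequence(cue, M, iters_per_stream, kappa, leak, slices):
    """Fused attractor retrieval: iterate h <- f_p(kappa*h + M h), freezing
    each stream's segment after its own iteration count (the frozen value
    keeps feeding the still-active streams).

    cue: (B, P); M: (B, P, P); slices: per-stream slice objects over P.
    f_p is the leaky-rectified unit thresholded at +-1 (leak both for the
    negative side and through saturation).  A single tape node covering the
    whole loop; the backward pass replays the iterations in reverse."""
    cue, M = as_tensor(cue), as_tensor(M)
    n_iters = max(iters_per_stream)
    P = cue.data.shape[-1]
    active = np.zeros((n_iters, P), dtype=bool)
    for f, (it, sl) in enumerate(zip(iters_per_stream, slices)):
        for tau in range(it):
            active[tau, sl[0]:sl[1]] = True
    hs = [cue.data]     # h_0 .. h_T (post-selection)
    pres = []
    h = cue.data
    Md = M.data
    for tau in range(n_iters):
        pre = kappa * h + np.matmul(Md, h[:, :, None])[:, :, 0]
        pres.append(pre)
        upd = np.clip(np.where(pre < 0, leak * pre, pre), -1.0, 1.0)
        h = np.where(active[tau], upd, h)
        hs.append(h)

    def backward(g):
        gh = g
        g_upds = []
        for tau in range(n_iters - 1, -1, -1):
            pre = pres[tau]
            slope = np.where((pre < 0) | (pre > 1.0), leak, 1.0)
            slope = np.where(leak * pre < -1.0, leak * leak, slope)
            g_upd = gh * (active[tau] * slope)
            g_upds.append(g_upd)
            gh = gh * ~active[tau] + kappa * g_upd + \
                np.matmul(g_upd[:, None, :], Md)[:, 0, :]
        # gM = sum_tau g_upd_tau (x) h_{tau}  as one batched GEMM
        G = np.stack(g_upds[::-1], axis=1)          # (B, T, P)
        Hst = np.stack(hs[:-1], axis=1)             # (B, T, P)
        gM = np.matmul(G.transpose(0, 2, 1), Hst)
        return (gh, gM)

    return _make(h, (cue, M), backward)


def cross_entropy_logits(logits, target_idx, weight=None):
    """Per-row categorical cross-entropy from logits.

    logits: (B, C); target_idx: (B,) ints; weight: optional (B,) floats.
    Returns a (B,) tensor of (weighted) negative log-likelihoods."""
    logits = as_tensor(logits)
    target_idx = np.asarray(target_idx)
    x = logits.data
    m = x.max(axis=-1, keepdims=True)
    lse = m[..., 0] + np.log(np.exp(x - m).sum(axis=-1))
    nll = lse - x[np.arange(x.shape[0]), target_idx]
    w = np.ones_like(nll) if weight is None else np.asarray(weight, dtype=float)
    out = nll * w

    def backward(g):
        p = np.exp(x - m)
        p /= p.sum(axis=-1, keepdims=True)
        p[np.arange(x.shape[0]), target_idx] -= 1.0
        return (p * (g * w)[..., None],)

    return _make(out, (logits,), backward)


# ---------------------------------------------------------------------------
# parameters and optimizer
# ---------------------------------------------------------------------------

def parameter(data, name=None) -> Tensor:
    return Tensor(np.asarray(data, dtype=DTYPE), requires_grad=True,
                  name=name)


def linear(x, w, b):
    return add(matmul(x, w), b)


class Adam:
    """Adaptive-moment first-order optimizer with optional global-norm clip."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 clip_norm=None):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
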