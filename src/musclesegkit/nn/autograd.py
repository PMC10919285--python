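"""Minimal reverse-mode autodiff on numpy arrays.

Define-by-run: every operation returns a :class:`Tensor` holding the
result and a closure that accumulates gradients into its parents.
``Tensor.backward()`` runs the tape in reverse topological order.  Only
the operations the segmentation networks need are provided; everything is
float32.

A global no-grad mode (:func:`no_grad`) disables tape construction for
inference.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, data, requires_grad=False, parents=(), backward_fn=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self.parents = parents if _GRAD_ENABLED else ()
        self.backward_fn = backward_fn if _GRAD_ENABLED else None

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node.backward_fn is not None and node.grad is not None:
                node.backward_fn(node.grad)

    # --- convenience operators -------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __repr__(self):
        return f"Tensor{self.data.shape}"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum grad over broadcast dimensions down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def _make(data, parents, backward_fn):
    req = any(p.requires_grad for p in parents)
    if not (_GRAD_ENABLED and req):
        return Tensor(data)
    return Tensor(data, requires_grad=True, parents=parents, backward_fn=backward_fn)


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), bw)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def bw(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), bw)


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def bw(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

    return _make(out_data, (a, b), bw)


def relu(x):
    x = _as_tensor(x)
    mask = x.data > 0
    out_data = np.maximum(x.data, 0.0)  # NaN-propagating, unlike where()

    def bw(g):
        if x.requires_grad:
            x.accumulate(g * mask)

    return _make(out_data, (x,), bw)


def sigmoid(x):
    x = _as_tensor(x)
    out_data = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def bw(g):
        if x.requires_grad:
            x.accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (x,), bw)


def concat(tensors, axis=1):
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.accumulate(g[tuple(sl)])

    return _make(out_data, tuple(tensors), bw)


def reshape(x, shape):
    x = _as_tensor(x)
    out_data = x.data.reshape(shape)

    def bw(g):
        if x.requires_grad:
            x.accumulate(g.reshape(x.shape))

    return _make(out_data, (x,), bw)


def mean(x, axis=None, keepdims=False):
    x = _as_tensor(x)
    out_data = x.data.mean(axis=axis, keepdims=keepdims)
    n = x.data.size / out_data.size

    def bw(g):
        if x.requires_grad:
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            x.accumulate(np.broadcast_to(gg, x.shape) / n)

    return _make(out_data, (x,), bw)


def amax(x, axis, keepdims=True):
    """Max along one axis; gradient flows to the first argmax."""
    x = _as_tensor(x)
    out_data = x.data.max(axis=axis, keepdims=keepdims)
    mask = x.data == (out_data if keepdims else np.expand_dims(out_data, axis))
    # break ties: keep first maximum only
    cum = np.cumsum(mask, axis=axis)
    mask = mask & (cum == 1)

    def bw(g):
        if x.requires_grad:
            gg = np.asarray(g)
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            x.accumulate(mask * gg)

    return _make(out_data, (x,), bw)


def pad2d(x, pad):
    """Zero-pad spatial dims of (B, C, H, W): pad = (top, bottom, left, right)."""
    x = _as_tensor(x)
    t, b, l, r = pad
    out_data = np.pad(x.data, ((0, 0), (0, 0), (t, b), (l, r)))

    def bw(g):
        if x.requires_grad:
            H, W = x.shape[2], x.shape[3]
            x.accumulate(g[:, :, t : t + H, l : l + W])

    return _make(out_data, (x,), bw)


def crop2d(x, box):
    """Crop spatial dims: box = (top, bottom, left, right) amounts removed."""
    x = _as_tensor(x)
    t, b, l, r = box
    H, W = x.shape[2], x.shape[3]
    out_data = x.data[:, :, t : H - b, l : W - r]

    def bw(g):
        if x.requires_grad:
            gg = np.zeros(x.shape, dtype=np.float32)
            gg[:, :, t : H - b, l : W - r] = g
            x.accumulate(gg)

    return _make(out_data, (x,), bw)


def conv2d(x, w, b=None, dilation=1):
    """'Same' 2D convolution, stride 1, square kernel, optional dilation.

    x: (B, Cin, H, W); w: (Cout, Cin, k, k); b: (Cout,).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    if b is not None:
        b = _as_tensor(b)
    B, Cin, H, W = x.shape
    Cout, _, k, _ = w.shape
    d = int(dilation)
    p = d * (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = np.empty((B, k * k * Cin, H * W), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            patch = xp[:, :, i * d : i * d + H, j * d : j * d + W]
            cols[:, (i * k + j) * Cin : (i * k + j + 1) * Cin, :] = patch.reshape(
                B, Cin, H * W
            )
    w_mat = w.data.transpose(2, 3, 1, 0).reshape(k * k * Cin, Cout)
    out = np.matmul(w_mat.T[None], cols).reshape(B, Cout, H, W)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def bw(g):
        g_mat = g.reshape(B, Cout, H * W)
        if w.requires_grad:
            dW_mat = np.einsum("bkn,bcn->kc", cols, g_mat)
            dW = dW_mat.reshape(k, k, Cin, Cout).transpose(3, 2, 0, 1)
            w.accumulate(dW)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(w_mat[None], g_mat)  # (B, kkCin, HW)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    sl = dcols[:, (i * k + j) * Cin : (i * k + j + 1) * Cin, :]
                    dxp[:, :, i * d : i * d + H, j * d : j * d + W] += sl.reshape(
                        B, Cin, H, W
                    )
            x.accumulate(dxp[:, :, p : p + H, p : p + W] if p else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, bw)


def maxpool2(x):
    """2x2 max pooling, stride 2; H and W must be even."""
    x = _as_tensor(x)
    B, C, H, W = x.shape
    r = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(B, C, H // 2, W // 2, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        if x.requires_grad:
            dr = np.zeros((B, C, H // 2, W // 2, 4), dtype=np.float32)
            np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
            dx = dr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x.accumulate(dx.reshape(B, C, H, W))

    return _make(out, (x,), bw)


def upsample_nearest(x, factor):
    x = _as_tensor(x)
    f = int(factor)
    out = x.data.repeat(f, axis=2).repeat(f, axis=3)

    def bw(g):
        if x.requires_grad:
            B, C, H, W = x.shape
            gg = g.reshape(B, C, H, f, W, f).sum(axis=(3, 5))
            x.accumulate(gg)

    return _make(out, (x,), bw)


def global_avg_pool(x):
    """(B, C, H, W) -> (B, C, 1, 1)."""
    return mean(x, axis=(2, 3), keepdims=True)


def batchnorm2d(x, gamma, beta, eps=1e-5):
    """Batch normalisation over (B, H, W) per channel with the full
    backward pass (gradients flow through the batch statistics).

    Returns (out, batch_mean, batch_var) so callers can update running
    statistics.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    axes = (0, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    g4 = gamma.data[None, :, None, None]
    out_data = g4 * xhat + beta.data[None, :, None, None]
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def bw(g):
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=axes))
        if x.requires_grad:
            gh = g * g4  # dL/dxhat
            mean_gh = gh.mean(axis=axes, keepdims=True)
            mean_ghx = (gh * xhat).mean(axis=axes, keepdims=True)
            dx = inv * (gh - mean_gh - xhat * mean_ghx)
            x.accumulate(dx.astype(np.float32))

    out = _make(out_data, (x, gamma, beta), bw)
    return out, mu.squeeze(), var.squeeze()
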