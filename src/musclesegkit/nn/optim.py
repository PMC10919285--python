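"""Optimisers and segmentation losses."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, _make

__all__ = ["SGD", "softmax", "segmentation_loss"]


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr=0.01, momentum=0.9):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def softmax(logits: np.ndarray, axis=1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def segmentation_loss(
    logits: Tensor,
    target: np.ndarray,
    kind: str = "ce+dice",
    eps: float = 1.0,
) -> tuple[Tensor, float]:
    """Voxelwise cross-entropy and/or soft multi-class Dice loss.

    ``logits``: (B, C, H, W); ``target``: (B, H, W) integer labels.
    Returns a scalar loss tensor (with analytic gradient wired into the
    tape) and its float value.  ``kind`` is one of ``"ce"``, ``"dice"``,
    ``"ce+dice"`` (the average of the two).
    """
    if kind not in ("ce", "dice", "ce+dice"):
        raise ValueError(f"unknown loss kind {kind!r}")
    B, C, H, W = logits.shape
    t = np.asarray(target)
    if t.shape != (B, H, W):
        raise ValueError(f"target shape {t.shape} != {(B, H, W)}")
    p = softmax(logits.data, axis=1)
    onehot = np.zeros_like(p)
    bidx = np.arange(B)[:, None, None]
    hidx = np.arange(H)[None, :, None]
    widx = np.arange(W)[None, None, :]
    onehot[bidx, t, hidx, widx] = 1.0

    n_vox = B * H * W
    losses = []
    dlogit = np.zeros_like(p)

    if kind in ("ce", "ce+dice"):
        ce = float(-np.sum(onehot * np.log(p + 1e-12)) / n_vox)
        losses.append(ce)
        dlogit += (p - onehot) / n_vox

    if kind in ("dice", "ce+dice"):
        inter = (p * onehot).sum(axis=(0, 2, 3))
        sums = p.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3))
        dice_c = (2.0 * inter + eps) / (sums + eps)
        dice_loss = float(1.0 - dice_c.mean())
        losses.append(dice_loss)
        # d dice_c / d p = (2*onehot*(sums+eps) - (2*inter+eps)) / (sums+eps)^2
        dd_dp = (
            2.0 * onehot * (sums + eps)[None, :, None, None]
            - (2.0 * inter + eps)[None, :, None, None]
        ) / ((sums + eps) ** 2)[None, :, None, None]
        g_p = -dd_dp / C  # d(1 - mean dice)/dp
        # chain through softmax: dL/dz_c = p_c*(g_c - sum_k g_k p_k)
        inner = (g_p * p).sum(axis=1, keepdims=True)
        dlogit += p * (g_p - inner)

    if kind == "ce+dice":
        value = 0.5 * (losses[0] + losses[1])
        dlogit *= 0.5
    else:
        value = losses[0]

    def bw(g):
        if logits.requires_grad:
            logits.accumulate(float(g) * dlogit)

    out = _make(np.float32(value), (logits,), bw)
    return out, value
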