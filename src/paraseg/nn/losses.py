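"""Dice + cross-entropy loss on multi-class voxel scores.

The loss is the sum of (i) voxel-mean cross-entropy of the softmax class
probabilities and (ii) one minus the soft Dice coefficient averaged over
samples and channels (background included), with a small smoothing term in
numerator and denominator so empty channels stay differentiable.
"""

from __future__ import annotations

import numpy as np

SMOOTH = 1e-5


def _softmax(scores: np.ndarray) -> np.ndarray:
    s = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(s, dtype=np.float64)
    return e / e.sum(axis=1, keepdims=True)


def _onehot(labels: np.ndarray, c: int) -> np.ndarray:
    return np.moveaxis(np.eye(c, dtype=np.float64)[labels], -1, 1)


def dice_ce_parts(scores: np.ndarray, labels: np.ndarray, smooth: float = SMOOTH):
    """Return (total, dice_loss, ce_loss, grad_wrt_scores).

    ``scores``: (N, C, *spatial) unnormalized class scores;
    ``labels``: (N, *spatial) integer labels in [0, C).
    """
    if scores.shape[0] != labels.shape[0] or scores.shape[2:] != labels.shape[1:]:
        raise ValueError(f"scores {scores.shape} and labels {labels.shape} do not match")
    n, c = scores.shape[:2]
    sp_axes = tuple(range(2, scores.ndim))
    nvox = int(n * np.prod(scores.shape[2:]))
    p = _softmax(np.asarray(scores, dtype=np.float64))
    y = _onehot(np.asarray(labels), c)

    ce = -np.log(np.clip((p * y).sum(axis=1), 1e-30, None)).sum() / nvox
    dce_dp_term = (p - y) / nvox  # CE grad already chained through softmax

    inter = (p * y).sum(axis=sp_axes)  # (N, C)
    psum = p.sum(axis=sp_axes)
    ysum = y.sum(axis=sp_axes)
    num = 2.0 * inter + smooth
    den = psum + ysum + smooth
    dice = num / den
    dice_loss = 1.0 - dice.mean()

    shp = (n, c) + (1,) * len(sp_axes)
    dl_dp = -(2.0 * y * den.reshape(shp) - num.reshape(shp)) / (den.reshape(shp) ** 2) / (n * c)
    # chain dice term through softmax: ds = p * (g - sum_c g*p)
    inner = (dl_dp * p).sum(axis=1, keepdims=True)
    grad = p * (dl_dp - inner) + dce_dp_term

    total = float(ce + dice_loss)
    return total, float(dice_loss), float(ce), grad.astype(scores.dtype, copy=False)


def dice_ce_loss(scores: np.ndarray, labels: np.ndarray, smooth: float = SMOOTH) -> float:
    """Scalar DiceCE loss (see :func:`dice_ce_parts`)."""
    return dice_ce_parts(scores, labels, smooth)[0]
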