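"""N-dimensional convolution primitives with explicit gradients.

Convolutions are evaluated as im2col + matmul so a BLAS does the heavy
lifting; the input gradient of a strided convolution is computed as a
zero-stuffed valid correlation with the spatially flipped, channel-swapped
kernel, which is also exactly the forward pass of the stride-2 transpose
convolution. All kernels are odd-sized with 'same' zero padding.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold ``x`` (N, C, *spatial) into (N, L, C*k^d) patch columns."""
    d = x.ndim - 2
    if pad:
        x = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * d)
    v = sliding_window_view(x, (k,) * d, axis=tuple(range(2, 2 + d)))
    v = v[(slice(None), slice(None)) + (slice(None, None, stride),) * d]
    out_sp = v.shape[2:2 + d]
    v = np.moveaxis(v, 1, 1 + d)  # (N, *out, C, *k)
    cols = v.reshape(x.shape[0], int(np.prod(out_sp)), -1)
    return cols, out_sp


def conv_forward(x: np.ndarray, W: np.ndarray, b, stride: int):
    """y = conv(x, W) + b with 'same' padding; returns (y, cols) for backward."""
    cout = W.shape[0]
    k = W.shape[2]
    cols, out_sp = im2col(x, k, stride, (k - 1) // 2)
    y = cols @ W.reshape(cout, -1).T
    if b is not None:
        y += b
    y = np.moveaxis(y, -1, 1).reshape(x.shape[0], cout, *out_sp)
    return np.ascontiguousarray(y), cols


def conv_weight_grad(cols: np.ndarray, gy: np.ndarray, w_shape):
    """Gradient w.r.t. W from cached columns and the output gradient."""
    n, cout = gy.shape[:2]
    gym = gy.reshape(n, cout, -1)
    gw = np.einsum("ncl,nlk->ck", gym, cols, optimize=True)
    return gw.reshape(w_shape)


def conv_input_grad(gy: np.ndarray, W: np.ndarray, stride: int, in_sp):
    """Gradient w.r.t. the input of conv_forward (also transpose-conv forward).

    ``gy`` has W.shape[0] channels; the result has W.shape[1] channels and
    spatial shape ``in_sp``.
    """
    n = gy.shape[0]
    cout, cin = W.shape[:2]
    k = W.shape[2]
    pad = (k - 1) // 2
    d = len(in_sp)
    buf = np.zeros((n, cout) + tuple(s + 2 * pad for s in in_sp), dtype=gy.dtype)
    sl = tuple(slice(pad, pad + (o - 1) * stride + 1, stride) for o in gy.shape[2:])
    buf[(slice(None), slice(None)) + sl] = gy
    Wt = np.flip(W, axis=tuple(range(2, 2 + d))).swapaxes(0, 1)  # (Cin, Cout, *k)
    cols, out_sp = im2col(buf, k, 1, 0)
    assert tuple(out_sp) == tuple(in_sp)
    gx = cols @ np.ascontiguousarray(Wt).reshape(cin, -1).T
    return np.ascontiguousarray(np.moveaxis(gx, -1, 1).reshape(n, cin, *in_sp))
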