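"""AdamW: Adam with decoupled weight decay.

The decay step is applied directly to the weights, outside the adaptive
gradient update, so large adaptive steps are not re-regularized.
Normalization affine parameters and biases are exempt from decay, following
common practice.
"""

from __future__ import annotations

import numpy as np


class AdamW:
    def __init__(self, named_params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=1e-4):
        self.named_params = list(named_params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.weight_decay = float(weight_decay)
        self.t = 0
        self.m = [np.zeros_like(p) for _, p in self.named_params]
        self.v = [np.zeros_like(p) for _, p in self.named_params]

    @staticmethod
    def _decays(name: str) -> bool:
        leaf = name.rsplit(".", 1)[-1]
        return leaf == "W"

    def step(self, named_grads) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for (name, p), m, v, (gname, g) in zip(self.named_params, self.m, self.v, named_grads):
            assert name == gname
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and self._decays(name):
                p -= self.lr * self.weight_decay * p
            p -= (self.lr * update).astype(p.dtype, copy=False)
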