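"""The modified U-Net.

Encoder–decoder with residual stages: pooling is replaced by stride-2
convolutions (stride 1 at the first stage), the decoder upsamples with
stride-2 transpose convolutions and concatenates the encoder feature maps at
matching resolution, and every stage carries an additive residual shortcut.
A final 1x1 convolution maps to unnormalized per-class scores, so the
network is fully convolutional and output spatial shape equals input shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .layers import DTYPE, Conv, ConvTranspose, InstanceNorm, LeakyReLU, ResidualUnit, Sequential


class ShapeError(ValueError):
    pass


@dataclass
class UNetConfig:
    """Architecture description.

    ``channels`` lists the encoder feature counts from the full-resolution
    stage down; ``deeper`` appends one extra encoder/decoder level pair with
    twice the top channel count (512 filters for the default ladder).
    """

    dims: int = 2
    in_channels: int = 1
    out_channels: int = 7
    channels: tuple = (16, 32, 64, 128, 256)
    deeper: bool = False
    negative_slope: float = 0.01
    norm_eps: float = 1e-5
    norm_affine: bool = True
    seed: int = 0

    def __post_init__(self):
        self.channels = tuple(int(c) for c in self.channels)
        if self.dims not in (2, 3):
            raise ValueError(f"dims must be 2 or 3, got {self.dims}")
        if len(self.channels) < 2 or any(b <= a for a, b in zip(self.channels, self.channels[1:])):
            raise ValueError(f"channels must be >= 2 strictly increasing values, got {self.channels}")
        if self.out_channels < 2:
            raise ValueError("out_channels must be >= 2")

    @property
    def effective_channels(self) -> tuple:
        return self.channels + ((2 * self.channels[-1],) if self.deeper else ())

    def to_dict(self) -> dict:
        return asdict(self)


class UNet:
    """Forward/backward evaluation of the modified U-Net."""

    def __init__(self, cfg: UNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.effective_channels
        d, slope, eps, aff = cfg.dims, cfg.negative_slope, cfg.norm_eps, cfg.norm_affine
        self.encoders = []
        cin = cfg.in_channels
        for i, c in enumerate(ch):
            self.encoders.append(ResidualUnit(cin, c, 1 if i == 0 else 2, d, rng, slope, eps, aff))
            cin = c
        self.ups = []
        self.decoders = []
        for i in range(len(ch) - 2, -1, -1):  # bottom-up
            self.ups.append(Sequential(
                ConvTranspose(ch[i + 1], ch[i], 3, 2, d, rng),
                InstanceNorm(ch[i], eps, aff),
                LeakyReLU(slope),
            ))
            self.decoders.append(ResidualUnit(2 * ch[i], ch[i], 1, d, rng, slope, eps, aff))
        self.final = Conv(ch[0], cfg.out_channels, 1, 1, d, rng)
        self._skip_grads = None

    @property
    def levels(self) -> int:
        return len(self.cfg.effective_channels)

    def check_input(self, x: np.ndarray) -> None:
        if x.ndim != self.cfg.dims + 2:
            raise ShapeError(f"expected (N, C, {'x, y' if self.cfg.dims == 2 else 'x, y, z'}) input, got shape {x.shape}")
        m = 2 ** (self.levels - 1)
        for ax, s in enumerate(x.shape[2:]):
            if s % m:
                raise ShapeError(f"spatial axis {ax} has size {s}, not divisible by {m} "
                                 f"(network with {self.levels} levels)")
            if s < m:
                raise ShapeError(f"spatial axis {ax} has size {s} < minimum window {m}")

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Return per-voxel class scores with the input's spatial shape."""
        x = np.ascontiguousarray(x, dtype=self.final.W.dtype)
        self.check_input(x)
        skips = []
        for i, enc in enumerate(self.encoders):
            x = enc.forward(x, train)
            if i < len(self.encoders) - 1:
                skips.append(x)
        for j, (up, dec) in enumerate(zip(self.ups, self.decoders)):
            x = up.forward(x, train)
            x = np.concatenate([x, skips[-1 - j]], axis=1)
            x = dec.forward(x, train)
        self._n_skips = len(skips)
        return self.final.forward(x, train)

    def backward(self, gscores: np.ndarray) -> np.ndarray:
        """Backpropagate; accumulates parameter gradients, returns input grad."""
        g = self.final.backward(gscores)
        skip_grads = [None] * self._n_skips
        ch = self.cfg.effective_channels
        for j in range(len(self.decoders) - 1, -1, -1):
            g = self.decoders[j].backward(g)
            c = ch[len(ch) - 2 - j]
            g, gskip = g[:, :c], g[:, c:]
            skip_grads[self._n_skips - 1 - j] = gskip
            g = self.ups[j].backward(g)
        for i in range(len(self.encoders) - 1, -1, -1):
            g = self.encoders[i].backward(g)
            if i - 1 >= 0:
                g = g + skip_grads[i - 1]
        return g

    # -- parameter plumbing ------------------------------------------------
    def _modules(self):
        mods = [(f"enc{i}", m) for i, m in enumerate(self.encoders)]
        mods += [(f"up{j}", m) for j, m in enumerate(self.ups)]
        mods += [(f"dec{j}", m) for j, m in enumerate(self.decoders)]
        mods.append(("final", self.final))
        return mods

    def parameters(self) -> list[tuple[str, np.ndarray]]:
        return [(f"{mn}.{n}", p) for mn, m in self._modules() for n, p in m.parameters()]

    def gradients(self) -> list[tuple[str, np.ndarray]]:
        return [(f"{mn}.{n}", g) for mn, m in self._modules() for n, g in m.gradients()]

    def zero_grad(self) -> None:
        for _, g in self.gradients():
            g[...] = 0.0

    def state_dict(self) -> dict:
        return {n: p.copy() for n, p in self.parameters()}

    def load_state_dict(self, state: dict) -> None:
        for n, p in self.parameters():
            p[...] = state[n]


def build_unet(cfg: UNetConfig) -> UNet:
    return UNet(cfg)


def forward(model: UNet, window: np.ndarray) -> np.ndarray:
    """Deterministic inference-mode forward pass (no caching)."""
    return model.forward(window, train=False)


def count_parameters(model: UNet) -> int:
    return int(sum(p.size for _, p in model.parameters()))


def save_checkpoint(model: UNet, path: str, extra: dict | None = None) -> None:
    """Self-describing checkpoint: weights plus the embedded UNetConfig."""
    meta = {"unet_config": model.cfg.to_dict(), "extra": extra or {}}
    arrays = {f"param/{n}": p for n, p in model.parameters()}
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                        **arrays)


def load_checkpoint(path: str) -> tuple[UNet, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg_d = dict(meta["unet_config"])
        cfg_d["channels"] = tuple(cfg_d["channels"])
        model = UNet(UNetConfig(**cfg_d))
        state = {n[len("param/"):]: z[n] for n in z.files if n.startswith("param/")}
    model.load_state_dict(state)
    return model, meta["extra"]
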