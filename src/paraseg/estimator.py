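"""Scikit-learn style segmentation estimator.

:class:`UNetSegmenter` wraps the modified U-Net, DiceCE loss, AdamW and the
class-balanced window sampler behind ``fit``/``predict``. ``X`` is a
sequence of 3D volumes (arrays or :class:`~paraseg.volume.ImageVolume`),
``y`` a matching sequence of label masks; volumes may differ in shape.
Inference is fully convolutional: 2D models run slice-by-slice on whole
padded slices, 3D models run sliding windows with 50% overlap along z and
mean score blending.
"""

from __future__ import annotations

import numpy as np

from sklearn.base import BaseEstimator

from .nn import AdamW, UNet, UNetConfig, dice_ce_parts, load_checkpoint, save_checkpoint
from .train import TrainConfig, _SubjectVolumes, _sample_from_subject
from .volume import ImageVolume, LabelMask


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, ImageVolume) else np.asarray(x)


class UNetSegmenter(BaseEstimator):
    """Multi-class volumetric segmenter (modified U-Net, DiceCE + AdamW).

    Parameters mirror the architecture/optimisation configuration; see
    :class:`~paraseg.nn.UNetConfig` and :class:`~paraseg.train.TrainConfig`.
    Fitted attributes: ``model_``, ``loss_history_`` (list of
    ``(iteration, loss)``), ``n_iter_``.
    """

    def __init__(self, dims=2, channels=(16, 32, 64, 128, 256), deeper=False,
                 out_channels=7, negative_slope=0.01, iterations=30000,
                 learning_rate=1e-3, weight_decay=1e-4, batch_size=None,
                 num_samples=None, window=None, pos_neg_ratio=1.0, seed=0,
                 log_every=100):
        self.dims = dims
        self.channels = channels
        self.deeper = deeper
        self.out_channels = out_channels
        self.negative_slope = negative_slope
        self.iterations = iterations
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.num_samples = num_samples
        self.window = window
        self.pos_neg_ratio = pos_neg_ratio
        self.seed = seed
        self.log_every = log_every

    # -- config plumbing ---------------------------------------------------
    def _unet_config(self) -> UNetConfig:
        return UNetConfig(dims=self.dims, out_channels=self.out_channels,
                          channels=tuple(self.channels), deeper=self.deeper,
                          negative_slope=self.negative_slope, seed=self.seed)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(iterations=self.iterations,
                           learning_rate=self.learning_rate,
                           weight_decay=self.weight_decay,
                           batch_size=self.batch_size,
                           num_samples=self.num_samples,
                           window=self.window,
                           pos_neg_ratio=self.pos_neg_ratio,
                           seed=self.seed, log_every=self.log_every).resolved(self.dims)

    @classmethod
    def from_configs(cls, unet_cfg: UNetConfig, train_cfg: TrainConfig) -> "UNetSegmenter":
        return cls(dims=unet_cfg.dims, channels=unet_cfg.channels,
                   deeper=unet_cfg.deeper, out_channels=unet_cfg.out_channels,
                   negative_slope=unet_cfg.negative_slope,
                   iterations=train_cfg.iterations,
                   learning_rate=train_cfg.learning_rate,
                   weight_decay=train_cfg.weight_decay,
                   batch_size=train_cfg.batch_size,
                   num_samples=train_cfg.num_samples, window=train_cfg.window,
                   pos_neg_ratio=train_cfg.pos_neg_ratio, seed=train_cfg.seed,
                   log_every=train_cfg.log_every)

    # -- training ----------------------------------------------------------
    def fit(self, X, y) -> "UNetSegmenter":
        if len(X) == 0 or len(X) != len(y):
            raise ValueError("X and y must be non-empty sequences of equal length")
        tcfg = self._train_config()
        if tcfg.batch_size % tcfg.num_samples:
            raise ValueError("batch_size must be a multiple of num_samples")
        subjects = [_SubjectVolumes(np.asarray(_as_array(xi), dtype=np.float32),
                                    _as_array(yi).astype(np.int64))
                    for xi, yi in zip(X, y)]
        model = UNet(self._unet_config())
        opt = AdamW(model.parameters(), lr=tcfg.learning_rate,
                    weight_decay=tcfg.weight_decay)
        rng = np.random.default_rng(tcfg.seed)
        vols_per_batch = tcfg.batch_size // tcfg.num_samples
        history = []
        for it in range(tcfg.iterations):
            imgs, labs = [], []
            for vi in rng.integers(0, len(subjects), size=vols_per_batch):
                for iw, mw in _sample_from_subject(subjects[vi], tcfg, rng):
                    imgs.append(iw)
                    labs.append(mw)
            xb = np.stack(imgs)[:, None]  # (N, 1, *window)
            yb = np.stack(labs)
            model.zero_grad()
            scores = model.forward(xb, train=True)
            loss, _, _, gscores = dice_ce_parts(scores, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at iteration {it}")
            model.backward(gscores)
            opt.step(model.gradients())
            if it % tcfg.log_every == 0 or it == tcfg.iterations - 1:
                history.append((it, float(loss)))
        self.model_ = model
        self.loss_history_ = history
        self.n_iter_ = tcfg.iterations
        return self

    # -- inference ---------------------------------------------------------
    def _pad_to_multiple(self, arr: np.ndarray, axes, m: int):
        pads = [(0, 0)] * arr.ndim
        for ax in axes:
            rem = (-arr.shape[ax]) % m
            pads[ax] = (0, rem)
        return (np.pad(arr, pads, mode="edge") if any(p != (0, 0) for p in pads)
                else arr), pads

    def predict_scores(self, x) -> np.ndarray:
        """Class-score volume (C, nx, ny, nz) for one input volume."""
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        vol = np.asarray(_as_array(x), dtype=np.float32)
        model = self.model_
        m = 2 ** (model.levels - 1)
        nx, ny, nz = vol.shape
        if self.dims == 2:
            padded, _ = self._pad_to_multiple(vol, (0, 1), m)
            scores = np.empty((self.out_channels, nx, ny, nz), dtype=np.float32)
            chunk = 8
            for z0 in range(0, nz, chunk):
                sl = padded[:, :, z0:z0 + chunk]
                xb = np.moveaxis(sl, -1, 0)[:, None]  # (B, 1, X, Y)
                s = model.forward(xb, train=False)
                scores[:, :, :, z0:z0 + sl.shape[2]] = np.moveaxis(
                    s[:, :, :nx, :ny], 0, -1)
            return scores
        tcfg = self._train_config()
        wz = min(tcfg.window[2], max(m, nz))
        wz += (-wz) % m
        padded, _ = self._pad_to_multiple(vol, (0, 1), m)
        if padded.shape[2] < wz:
            padded = np.pad(padded, ((0, 0), (0, 0), (0, wz - padded.shape[2])),
                            mode="edge")
        pz = padded.shape[2]
        acc = np.zeros((self.out_channels,) + padded.shape, dtype=np.float32)
        cnt = np.zeros(padded.shape[2], dtype=np.float32)
        step = max(wz // 2, 1)  # 50% overlap along z
        starts = sorted({min(z, pz - wz) for z in range(0, pz - wz + step, step)})
        for z0 in starts:
            xb = padded[None, None, :, :, z0:z0 + wz]
            s = model.forward(xb, train=False)[0]
            acc[:, :, :, z0:z0 + wz] += s
            cnt[z0:z0 + wz] += 1.0
        acc /= cnt[None, None, None, :]
        return acc[:, :nx, :ny, :nz]

    def predict(self, X) -> list[LabelMask]:
        """Arg-max label volumes; ties resolve to the lowest label ID."""
        out = []
        for x in X:
            scores = self.predict_scores(x)
            labels = np.argmax(scores, axis=0).astype(np.uint8)
            spacing = x.spacing if isinstance(x, ImageVolume) else (1.0, 1.0, 1.0)
            out.append(LabelMask(labels, spacing))
        return out

    # -- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        save_checkpoint(self.model_, path, extra={"params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.get_params().items()}})

    @classmethod
    def load(cls, path: str) -> "UNetSegmenter":
        model, extra = load_checkpoint(path)
        params = dict(extra.get("params", {}))
        for key in ("channels", "window"):
            if params.get(key) is not None:
                params[key] = tuple(params[key])
        est = cls(**params)
        est.model_ = model
        est.loss_history_ = []
        est.n_iter_ = 0
        return est
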