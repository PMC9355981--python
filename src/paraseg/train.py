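"""Training utilities: subject-level k-fold splits, class-balanced window
sampling, the DiceCE loss, and manifest-level train/predict wrappers around
:class:`paraseg.estimator.UNetSegmenter`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .nn.losses import dice_ce_loss, dice_ce_parts  # noqa: F401  (re-export)
from .volume import ImageVolume, LabelMask, read_manifest, read_pair


@dataclass
class TrainConfig:
    """Optimisation protocol.

    ``batch_size``, ``num_samples`` and ``window`` default by dimensionality
    to the 2D regime (batch 50 of four 256x256x1 windows per loaded volume)
    or the 3D regime (batch 10 of one 256x256x32 window); training windows
    are centred on a foreground or background voxel at ``pos_neg_ratio`` : 1.
    """

    iterations: int = 30000
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int | None = None
    num_samples: int | None = None
    window: tuple | None = None
    pos_neg_ratio: float = 1.0
    seed: int = 0
    log_every: int = 100

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.pos_neg_ratio < 0:
            raise ValueError("pos_neg_ratio must be >= 0")
        for name in ("batch_size", "num_samples"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{name} must be >= 1")

    def resolved(self, dims: int) -> "TrainConfig":
        out = TrainConfig(**asdict(self))
        if out.batch_size is None:
            out.batch_size = 50 if dims == 2 else 10
        if out.num_samples is None:
            out.num_samples = 4 if dims == 2 else 1
        if out.window is None:
            out.window = (256, 256, 1) if dims == 2 else (256, 256, 32)
        out.window = tuple(int(w) for w in out.window)
        return out


@dataclass
class FoldSplit:
    fold_index: int
    train_ids: list
    test_ids: list

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test subjects overlap")


def kfold_split(subject_ids, k: int, seed: int = 0) -> list[FoldSplit]:
    """Deterministic subject-level k-fold split; fold sizes differ by <= 1."""
    ids = list(subject_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of subjects ({len(ids)})")
    rng = np.random.default_rng(seed)
    order = np.array(ids, dtype=object)[rng.permutation(len(ids))]
    folds = np.array_split(order, k)
    out = []
    for i, test in enumerate(folds):
        test = list(test)
        train = [s for s in order if s not in set(test)]
        out.append(FoldSplit(i, train, test))
    return out


def _crop_window(arr: np.ndarray, center, size, pad_mode: str):
    """Crop ``size`` around ``center``, clamped into bounds; pad (edge) only
    when the volume is smaller than the window."""
    slices, pads = [], []
    for c, w, s in zip(center, size, arr.shape):
        lo = int(c) - w // 2
        lo = min(max(lo, 0), max(s - w, 0))  # clamp window inside the volume
        hi = lo + w
        pads.append((0, max(hi - s, 0)))
        slices.append(slice(lo, min(hi, s)))
    out = arr[tuple(slices)]
    if any(p != (0, 0) for p in pads):
        out = np.pad(out, pads, mode=pad_mode)
    return out


class _SubjectVolumes:
    """A loaded, normalized subject with cached foreground coordinates."""

    def __init__(self, image: np.ndarray, mask: np.ndarray):
        self.image = image
        self.mask = mask
        self.fg = np.argwhere(mask > 0)
        self.bg = np.argwhere(mask == 0)


def sample_windows(img, msk, cfg: TrainConfig, rng: np.random.Generator,
                   dims: int = 2) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw ``num_samples`` (image, label) windows with class-balanced centres.

    Each window's centre voxel is foreground with probability
    ratio / (ratio + 1); windows are clamped into the volume and edge-padded
    only when the volume is smaller than the window.
    """
    image = img.data if isinstance(img, ImageVolume) else np.asarray(img)
    mask = msk.data if isinstance(msk, LabelMask) else np.asarray(msk)
    cfg = cfg.resolved(dims)
    sub = _SubjectVolumes(image, mask)
    return _sample_from_subject(sub, cfg, rng)


def _sample_from_subject(sub: _SubjectVolumes, cfg: TrainConfig,
                         rng: np.random.Generator):
    p_fg = cfg.pos_neg_ratio / (cfg.pos_neg_ratio + 1.0)
    if len(sub.fg) == 0 and p_fg > 0:
        warnings.warn("mask has no foreground voxels; sampling background centres",
                      stacklevel=2)
    out = []
    for _ in range(cfg.num_samples):
        pool = sub.fg if (len(sub.fg) and rng.random() < p_fg) else sub.bg
        if len(pool) == 0:
            pool = sub.fg
        center = pool[rng.integers(len(pool))]
        iw = _crop_window(sub.image, center, cfg.window, "edge")
        mw = _crop_window(sub.mask, center, cfg.window, "edge")
        if cfg.window[2] == 1:  # squeeze the unitary axis to a true 2D patch
            iw, mw = iw[..., 0], mw[..., 0]
        out.append((iw, mw))
    return out


def train_model(train_manifest, unet_cfg, train_cfg: TrainConfig,
                checkpoint_path: str | None = None,
                log_path: str | None = None):
    """Train on a cohort manifest (CSV path or DataFrame); returns the fitted
    :class:`~paraseg.estimator.UNetSegmenter`.

    Volumes are min-max normalized per subject on load. The loss trace is
    written as CSV (iteration, loss) when ``log_path`` is given.
    """
    from .estimator import UNetSegmenter
    from .preprocess import normalize_intensity

    df = read_manifest(train_manifest) if not isinstance(train_manifest, pd.DataFrame) else train_manifest
    if len(df) == 0:
        raise ValueError("training manifest is empty")
    images, masks = [], []
    for _, row in df.iterrows():
        img, msk = read_pair(row["image"], row["mask"])
        images.append(normalize_intensity(img))
        masks.append(msk)
    est = UNetSegmenter.from_configs(unet_cfg, train_cfg)
    est.fit(images, masks)
    if log_path is not None:
        pd.DataFrame(est.loss_history_, columns=["iteration", "loss"]).to_csv(log_path, index=False)
    if checkpoint_path is not None:
        est.save(checkpoint_path)
    return est


def predict_volume(model, img: ImageVolume) -> LabelMask:
    """Full-volume prediction with a fitted estimator or a checkpoint path."""
    from .estimator import UNetSegmenter

    if isinstance(model, (str, bytes)):
        model = UNetSegmenter.load(model)
    return model.predict([img])[0]
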