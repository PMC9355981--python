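"""Random affine and elastic augmentation for paired image/label volumes.

One augmented sample applies, in order: left-right mirroring (with the
anatomically forced label swap 1<->2, 3<->4, 5<->6), per-axis rotation,
per-axis scaling, translation — composed into a single affine resampling —
followed by an elastic warp (white noise smoothed by a Gaussian of width
sigma, scaled by a magnitude factor). Images interpolate trilinearly, masks
nearest-neighbour; both use border (edge-replicate) padding and share every
sampled transform so mask boundaries move with image edges.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import (ImageVolume, LabelMask, MIRROR_LABEL_MAP, read_manifest,
                     read_pair, write_manifest, write_volume)


@dataclass
class AugmentConfig:
    """Sampling intervals for one augmentation draw.

    ``scale_range`` is a fractional interval (±2.5% default); rotation is in
    degrees per axis; translation in voxels per axis; ``elastic_magnitude``
    is the raw scale applied to the Gaussian-smoothed displacement noise —
    the convention of reference augmentation frameworks, where the effective
    displacement is magnitude times the (small) smoothed-noise amplitude.
    """

    scale_range: tuple = (-0.025, 0.025)
    mirror_prob: float = 0.5
    rot_deg: tuple = ((-2.5, 2.5), (-2.5, 2.5), (-2.5, 2.5))
    trans_vox: tuple = ((-25, 25), (-25, 25), (-2, 2))
    elastic_sigma: tuple = (6.0, 8.0)
    elastic_magnitude: tuple = (50.0, 100.0)
    apply_elastic: bool = True
    padding: str = "border"
    n_out: int = 1000
    seed: int = 0

    def __post_init__(self):
        def _check(iv, name):
            if len(iv) != 2 or iv[0] > iv[1]:
                raise ValueError(f"{name} must be an ordered (lo, hi) interval, got {iv}")
        _check(self.scale_range, "scale_range")
        _check(self.elastic_sigma, "elastic_sigma")
        _check(self.elastic_magnitude, "elastic_magnitude")
        for name in ("rot_deg", "trans_vox"):
            for iv in getattr(self, name):
                _check(iv, name)
        if not 0.0 <= self.mirror_prob <= 1.0:
            raise ValueError("mirror_prob must be in [0, 1]")
        if self.n_out < 1:
            raise ValueError("n_out must be >= 1")
        if self.padding != "border":
            raise ValueError("only 'border' padding is supported")

    def to_dict(self) -> dict:
        return asdict(self)


_PAD_MODE = "nearest"  # scipy name for border/edge-replicate padding


def _rotation_matrix(angles_rad) -> np.ndarray:
    ax, ay, az = angles_rad
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _apply_affine(img: ImageVolume, msk: LabelMask, A: np.ndarray,
                  trans: np.ndarray, mirrored: bool):
    center = (np.array(img.shape, dtype=float) - 1.0) / 2.0
    Ainv = np.linalg.inv(A)
    offset = center - Ainv @ (center + trans)
    out_img = ndimage.affine_transform(img.data.astype(np.float32), Ainv, offset,
                                       order=1, mode=_PAD_MODE)
    out_msk = ndimage.affine_transform(msk.data, Ainv, offset, order=0,
                                       mode=_PAD_MODE)
    if mirrored:
        out_msk = MIRROR_LABEL_MAP[out_msk]
    return img.with_data(out_img), LabelMask(out_msk, msk.spacing)


def random_affine(img: ImageVolume, msk: LabelMask, cfg: AugmentConfig,
                  rng: np.random.Generator):
    """One sampled affine applied identically to image and mask.

    Transform order: mirror -> rotate -> scale -> translate, about the
    volume centre, evaluated in a single resampling.
    """
    if img.shape != msk.shape:
        raise ValueError(f"image {img.shape} and mask {msk.shape} shapes differ")
    mirrored = bool(rng.random() < cfg.mirror_prob)
    angles = np.deg2rad([rng.uniform(*iv) for iv in cfg.rot_deg])
    scales = 1.0 + np.array([rng.uniform(*cfg.scale_range) for _ in range(3)])
    trans = np.array([rng.uniform(*iv) for iv in cfg.trans_vox])
    M = np.diag([-1.0, 1.0, 1.0]) if mirrored else np.eye(3)
    # rotations emulate physical patient positioning, so they act in mm
    # coordinates; with anisotropic voxels a rotation applied to raw voxel
    # indices would shear severely along the thick-slice axis
    sp = np.diag(img.spacing)
    R_vox = np.linalg.inv(sp) @ _rotation_matrix(angles) @ sp
    A = np.diag(scales) @ R_vox @ M
    return _apply_affine(img, msk, A, trans, mirrored)


def elastic_deform(img: ImageVolume, msk: LabelMask, cfg: AugmentConfig,
                   rng: np.random.Generator):
    """Random dense elastic warp, shared by image and mask."""
    if img.shape != msk.shape:
        raise ValueError(f"image {img.shape} and mask {msk.shape} shapes differ")
    sigma = rng.uniform(*cfg.elastic_sigma)
    magnitude = rng.uniform(*cfg.elastic_magnitude)
    coords = np.indices(img.shape, dtype=np.float64)
    for ax in range(3):
        noise = rng.uniform(-1.0, 1.0, size=img.shape)
        coords[ax] += magnitude * ndimage.gaussian_filter(noise, sigma, mode="constant")
    out_img = ndimage.map_coordinates(img.data.astype(np.float32), coords,
                                      order=1, mode=_PAD_MODE)
    out_msk = ndimage.map_coordinates(msk.data, coords, order=0, mode=_PAD_MODE)
    return img.with_data(out_img), LabelMask(out_msk, msk.spacing)


def augment_pair(img: ImageVolume, msk: LabelMask, cfg: AugmentConfig,
                 rng: np.random.Generator):
    img, msk = random_affine(img, msk, cfg, rng)
    if cfg.apply_elastic:
        img, msk = elastic_deform(img, msk, cfg, rng)
    return img, msk


def augment_dataset(manifest, cfg: AugmentConfig, out_dir: str) -> str:
    """Expand a training manifest to exactly ``cfg.n_out`` augmented pairs.

    Source subjects are cycled uniformly, so with 50 subjects and the
    default ``n_out=1000`` each source is used 20 times. Per-item randomness
    derives from ``(cfg.seed, item_index)``; two runs with the same seed
    produce identical files. Returns the augmented manifest path.
    """
    df = read_manifest(manifest) if not isinstance(manifest, pd.DataFrame) else manifest
    if len(df) == 0:
        raise ValueError("source manifest is empty")
    os.makedirs(out_dir, exist_ok=True)
    cache: dict[int, tuple[ImageVolume, LabelMask]] = {}
    rows = []
    for i in range(cfg.n_out):
        src = i % len(df)
        if src not in cache:
            row = df.iloc[src]
            cache[src] = read_pair(row["image"], row["mask"])
        img, msk = cache[src]
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), i]))
        aimg, amsk = augment_pair(img, msk, cfg, rng)
        sid = f"aug{i:04d}"
        ipath = os.path.join(out_dir, f"{sid}_img.nii.gz")
        mpath = os.path.join(out_dir, f"{sid}_msk.nii.gz")
        write_volume(aimg, ipath)
        write_volume(amsk, mpath)
        rows.append({"subject_id": sid, "image": ipath, "mask": mpath})
    out_manifest = os.path.join(out_dir, "manifest.csv")
    write_manifest(rows, out_manifest)
    return out_manifest
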