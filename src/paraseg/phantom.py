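"""Synthetic lumbar-like phantom volumes.

The study's MRI data is not public, so this module generates image/label
pairs that reproduce the statistical structure the pipeline relies on:

* six bilaterally placed tube-like muscle regions (left/right multifidus,
  erector spinae, psoas major), swept elliptical cross-sections along z with
  smooth per-slice jitter, mirror-symmetric in expectation;
* expected volumes that follow the cohort ordering
  erector spinae > psoas major > multifidus, rescaled from the cohort means
  to the phantom field of view;
* T2-like contrast: muscle darker than the fatty surround, bright
  intramuscular fat speckle at a per-subject fat fraction;
* a smooth multiplicative bias field and additive Gaussian noise.

Geometry is procedural (no atlas), so expected volumes are controllable and
the generator needs no external data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, LabelMask, write_manifest, write_volume

# Cohort mean muscle volumes (ml), averaged over sides so left/right are
# exchangeable in expectation, then rescaled to the phantom field of view
# (default grid spans ~100 x 100 x 60 mm vs ~200 mm of lumbar coverage in
# the cohort; factor 0.15 keeps total muscle near 30% of the phantom FOV).
_COHORT_MEAN_ML = {"erector_spinae": (300.3 + 294.7) / 2,
                   "psoas": (157.3 + 160.3) / 2,
                   "multifidus": (120.6 + 119.9) / 2}
_FOV_RESCALE = 0.15
DEFAULT_MEAN_VOLUME_ML = {m: v * _FOV_RESCALE for m, v in _COHORT_MEAN_ML.items()}

# (muscle, left-label, right-label, lateral offset, anterior offset) in
# fractions of the in-plane grid; y is posterior -> anterior. Painting
# priority = tuple order: the slender multifidus goes first so neighbouring
# regions cannot bite it apart.
_PLACEMENT = (
    ("multifidus", 1, 2, 0.075, 0.26),
    ("erector_spinae", 3, 4, 0.235, 0.38),
    ("psoas", 5, 6, 0.16, 0.65),
)
# in-plane aspect (semi-axis ratio ax/ay) per muscle
_ASPECT = {"erector_spinae": 1.15, "psoas": 1.0, "multifidus": 0.45}

_MUSCLE_BASE = {"erector_spinae": 0.33, "psoas": 0.38, "multifidus": 0.30}
_FAT_INTENSITY = 0.85
_BODY_INTENSITY = 0.55
_RIM_INTENSITY = 0.80
_AIR_INTENSITY = 0.03


class PhantomConfigError(ValueError):
    pass


@dataclass
class PhantomConfig:
    """Parameters of the phantom population (one config = one cohort model)."""

    grid_shape: tuple[int, int, int] = (64, 64, 12)
    spacing: tuple[float, float, float] = (1.56, 1.56, 5.0)
    mean_volume_ml: dict = field(default_factory=lambda: dict(DEFAULT_MEAN_VOLUME_ML))
    volume_cv: float = 0.2
    fat_fraction_range: tuple[float, float] = (0.05, 0.30)
    bias_amplitude: float = 0.2
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 1:
            raise PhantomConfigError(f"bad grid_shape {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise PhantomConfigError(f"spacing must be positive, got {self.spacing}")
        if any(v <= 0 for v in self.mean_volume_ml.values()):
            raise PhantomConfigError("mean volumes must be positive")
        lo, hi = self.fat_fraction_range
        if not (0 <= lo <= hi < 1):
            raise PhantomConfigError(f"fat_fraction_range must lie in [0, 1), got {self.fat_fraction_range}")
        if self.noise_sd < 0 or self.bias_amplitude < 0 or self.volume_cv < 0:
            raise PhantomConfigError("noise_sd, bias_amplitude and volume_cv must be >= 0")
        if min(self.grid_shape[:2]) < 32 or self.grid_shape[2] < 2:
            raise PhantomConfigError(
                f"grid {self.grid_shape} too small to place six bilateral regions "
                "(need >= 32 in-plane voxels and >= 2 slices)")


def _smooth_walk(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Smooth zero-mean per-slice jitter (random walk band-limited along z)."""
    w = rng.normal(0.0, sd, size=n)
    if n >= 3:
        w = ndimage.uniform_filter1d(w, size=3, mode="nearest")
    return w - w.mean()


def _label_volume(cfg: PhantomConfig, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    nx, ny, nz = cfg.grid_shape
    sx, sy, sz = cfg.spacing
    labels = np.zeros(cfg.grid_shape, dtype=np.uint8)
    xg, yg = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")

    # per-subject size factor per muscle, shared by the two sides so the
    # bilateral volumes stay correlated as in a real subject
    size_factor = {m: max(0.4, 1.0 + cfg.volume_cv * rng.normal())
                   for m in cfg.mean_volume_ml}
    meta = {"size_factor": size_factor}

    for muscle, lab_l, lab_r, fx, fy in _PLACEMENT:
        target_ml = cfg.mean_volume_ml[muscle] * size_factor[muscle]
        area_mm2 = target_ml * 1000.0 / (nz * sz)  # per-slice cross-section
        area_vox = area_mm2 / (sx * sy)
        aspect = _ASPECT[muscle]
        ay = np.sqrt(area_vox / (np.pi * aspect))
        ax = aspect * ay
        for lab, side in ((lab_l, -1), (lab_r, +1)):
            cx0 = (nx - 1) / 2 + side * fx * nx + rng.normal(0, 0.6)
            cy0 = fy * ny + rng.normal(0, 0.6)
            jx = _smooth_walk(rng, nz, 0.8)
            jy = _smooth_walk(rng, nz, 0.8)
            # modulation fades to zero at the end slices so the expected
            # cross-section there equals the nominal one (keeps volumes
            # stable under small z shifts with border padding)
            taper = np.sin(np.linspace(0, np.pi, nz)) ** 0.5 if nz > 1 else np.ones(1)
            rmod = 1.0 + 0.03 * taper * _smooth_walk(rng, nz, 1.0)
            for k in range(nz):
                r2 = (((xg - cx0 - jx[k]) / (ax * rmod[k])) ** 2
                      + ((yg - cy0 - jy[k]) / (ay * rmod[k])) ** 2)
                sl = labels[:, :, k]
                inside = (r2 <= 1.0) & (sl == 0)  # earlier muscles keep contested voxels
                sl[inside] = lab

    # painting can strand the odd voxel behind a neighbour's bite; keep only
    # the largest 6-connected component per label so each region is a single
    # dense component
    for lab in range(1, 7):
        comp, nc = ndimage.label(labels == lab)
        if nc > 1:
            sizes = ndimage.sum_labels(np.ones(comp.shape), comp, index=range(1, nc + 1))
            keep = int(np.argmax(sizes)) + 1
            labels[(comp > 0) & (comp != keep)] = 0
    return labels, meta


def generate_phantom(cfg: PhantomConfig, subject_seed: int) -> tuple[ImageVolume, LabelMask]:
    """Generate one deterministic image/label pair.

    The stream of random draws is fixed by ``(cfg.seed, subject_seed)``, so
    the same arguments always return voxel-identical volumes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), int(subject_seed)]))
    nx, ny, nz = cfg.grid_shape
    labels, _ = _label_volume(cfg, rng)

    # body contour: a large ellipse; its rim emulates subcutaneous fat
    xg, yg = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    bx, by = 0.46 * nx, 0.44 * ny
    cx, cy = (nx - 1) / 2, (ny - 1) / 2 + 0.02 * ny
    r2 = ((xg - cx) / bx) ** 2 + ((yg - cy) / by) ** 2
    body = r2 <= 1.0
    rim = body & (r2 >= (1.0 - 3.0 / min(bx, by)) ** 2)

    img = np.full(cfg.grid_shape, _AIR_INTENSITY, dtype=np.float32)
    img[np.broadcast_to(body[:, :, None], img.shape)] = _BODY_INTENSITY
    img[np.broadcast_to(rim[:, :, None], img.shape)] = _RIM_INTENSITY
    for muscle, lab_l, lab_r, _, _ in _PLACEMENT:
        img[(labels == lab_l) | (labels == lab_r)] = _MUSCLE_BASE[muscle]

    # intramuscular fat speckle: threshold spatially-correlated noise inside
    # the muscle mask at the quantile implied by the sampled fat fraction
    lo, hi = cfg.fat_fraction_range
    fat_fraction = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    muscle_mask = labels > 0
    if fat_fraction > 0 and muscle_mask.any():
        g = ndimage.gaussian_filter(rng.normal(size=cfg.grid_shape), sigma=(1.5, 1.5, 0.5))
        vals = g[muscle_mask]
        thr = np.quantile(vals, 1.0 - fat_fraction)
        img[muscle_mask & (g > thr)] = _FAT_INTENSITY

    if cfg.bias_amplitude > 0:
        b = ndimage.gaussian_filter(rng.normal(size=cfg.grid_shape),
                                    sigma=(nx / 4, ny / 4, max(nz / 4, 1)))
        peak = np.abs(b).max()
        if peak > 0:
            img *= 1.0 + cfg.bias_amplitude * (b / peak)
    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, size=cfg.grid_shape).astype(np.float32)

    return (ImageVolume(img.astype(np.float32), cfg.spacing),
            LabelMask(labels, cfg.spacing))


def generate_cohort(n: int, cfg: PhantomConfig, seed: int, out_dir: str) -> str:
    """Write ``n`` phantom pairs plus a manifest CSV; returns the manifest path.

    Subject seeds derive deterministically from ``(seed, index)``; two runs
    with the same arguments produce byte-identical volumes.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    os.makedirs(out_dir, exist_ok=True)
    cohort_cfg = PhantomConfig(**{**cfg.__dict__, "seed": int(seed)})
    rows = []
    for i in range(n):
        img, msk = generate_phantom(cohort_cfg, i)
        sid = f"subj{i:03d}"
        ipath = os.path.join(out_dir, f"{sid}_img.nii.gz")
        mpath = os.path.join(out_dir, f"{sid}_msk.nii.gz")
        write_volume(img, ipath)
        write_volume(msk, mpath)
        rows.append({"subject_id": sid, "image": ipath, "mask": mpath})
    manifest = os.path.join(out_dir, "manifest.csv")
    write_manifest(rows, manifest)
    return manifest
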