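"""Volume containers and NIfTI I/O.

The package works on paired image/label volumes in a fixed axis convention:
axis 0 = x (left -> right), axis 1 = y (posterior -> anterior),
axis 2 = z (inferior -> superior), i.e. RAS+. Files in other orientations
are reoriented on load. Geometry is carried as a (sx, sy, sz) voxel spacing
in mm; orientation matrices beyond axis flips/permutations are not used.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

#: label IDs for the six bilateral paraspinal muscles (0 = background)
LABEL_NAMES = {
    0: "background",
    1: "multifidus_left",
    2: "multifidus_right",
    3: "erector_spinae_left",
    4: "erector_spinae_right",
    5: "psoas_left",
    6: "psoas_right",
}
MUSCLE_LABELS = (1, 2, 3, 4, 5, 6)
#: label remapping applied when a volume is mirrored along the left-right axis
MIRROR_LABEL_MAP = np.array([0, 2, 1, 4, 3, 6, 5], dtype=np.uint8)


class GeometryError(ValueError):
    """Shape or spacing mismatch between paired volumes."""


class LabelError(ValueError):
    """Label values outside the allowed {0..6} set."""


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with physical voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise GeometryError(f"expected a 3D grid, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=data)


@dataclass
class LabelMask(ImageVolume):
    """A 3D integer grid over the label IDs in :data:`LABEL_NAMES`."""

    label_map: dict = field(default_factory=lambda: dict(LABEL_NAMES))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded, atol=1e-6):
                raise LabelError("label mask contains non-integer values")
            self.data = rounded.astype(np.uint8)
        super().__post_init__()
        bad = np.setdiff1d(np.unique(self.data), list(self.label_map))
        if bad.size:
            raise LabelError(f"label values {bad.tolist()} outside allowed set {sorted(self.label_map)}")

    def volumes_ml(self) -> dict[int, float]:
        """Per-muscle volume in millilitres (voxel count x voxel volume / 1000)."""
        vv = self.voxel_volume_mm3 / 1000.0
        return {lab: float(np.count_nonzero(self.data == lab)) * vv for lab in MUSCLE_LABELS}


def _check_geometry(a: ImageVolume, b: ImageVolume) -> None:
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, rtol=1e-4):
        raise GeometryError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


def _load_canonical(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.as_closest_canonical(nib.load(os.fspath(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_image(path: str) -> ImageVolume:
    data, spacing = _load_canonical(path)
    data = np.nan_to_num(np.asarray(data, dtype=np.float32), copy=False)
    return ImageVolume(data, spacing)


def read_mask(path: str) -> LabelMask:
    data, spacing = _load_canonical(path)
    return LabelMask(data, spacing)


def read_pair(image_path: str, mask_path: str) -> tuple[ImageVolume, LabelMask]:
    """Load a geometry-consistent image/mask pair, validating labels."""
    img = read_image(image_path)
    msk = read_mask(mask_path)
    _check_geometry(img, msk)
    return img, msk


def write_volume(vol: ImageVolume, path: str) -> None:
    """Write a volume as NIfTI-1 with an RAS+ affine built from the spacing."""
    affine = np.diag(list(vol.spacing) + [1.0])
    data = vol.data
    if isinstance(vol, LabelMask):
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), os.fspath(path))


def read_manifest(path: str) -> pd.DataFrame:
    """Read a cohort manifest CSV (columns: subject_id, image, mask).

    Relative paths are resolved against the manifest's directory.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "image", "mask"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    base = os.path.dirname(os.path.abspath(os.fspath(path)))
    for col in ("image", "mask"):
        df[col] = [p if os.path.isabs(p) else os.path.join(base, p) for p in df[col]]
    return df


def write_manifest(rows: list[dict], path: str) -> None:
    pd.DataFrame(rows, columns=["subject_id", "image", "mask"]).to_csv(path, index=False)
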