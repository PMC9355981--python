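"""Resampling to a fixed voxel grid and per-subject intensity normalization.

The pipeline default resamples every volume to 0.39 x 0.39 x 5 mm voxels
(anisotropic axial acquisition) and min-max rescales intensities to [0, 1]
per subject before any training or inference.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, LabelMask

#: pipeline default target spacing in mm (in-plane x, y, slice thickness z)
DEFAULT_SPACING = (0.39, 0.39, 5.0)


def resample(vol: ImageVolume, target_spacing=DEFAULT_SPACING) -> ImageVolume:
    """Resample a volume to ``target_spacing``.

    The output grid has shape ``round(shape * spacing / target_spacing)``.
    Images are interpolated trilinearly; label masks use nearest-neighbour
    so the label set is preserved.
    """
    target = tuple(float(s) for s in target_spacing)
    if len(target) != 3 or any(s <= 0 for s in target):
        raise ValueError(f"target spacing must be three positive values, got {target_spacing}")
    factors = np.asarray(vol.spacing, dtype=float) / np.asarray(target, dtype=float)
    if np.allclose(factors, 1.0):
        return vol.with_data(vol.data.copy())
    is_mask = isinstance(vol, LabelMask)
    order = 0 if is_mask else 1
    data = ndimage.zoom(vol.data, factors, order=order, mode="nearest", grid_mode=False)
    out = vol.with_data(data)
    out.spacing = target
    return out


def normalize_intensity(vol: ImageVolume) -> ImageVolume:
    """Min-max rescale intensities to [0, 1] per subject.

    A constant volume cannot be rescaled; it maps to all zeros with a warning.
    """
    data = vol.data.astype(np.float32)
    lo = float(data.min())
    hi = float(data.max())
    if hi == lo:
        warnings.warn("constant-intensity volume: normalization returns all zeros", stacklevel=2)
        return vol.with_data(np.zeros_like(data))
    return vol.with_data((data - lo) / (hi - lo))
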