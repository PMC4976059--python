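"""Physical-unit binary morphology on anisotropic voxel grids.

All operations take a radius in mm and honour the voxel spacing through
Euclidean distance transforms, which makes them exact ball-structuring-element
operations even when the slice thickness differs from the in-plane spacing.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def dilate_mm(mask: np.ndarray, radius_mm: float, spacing_mm) -> np.ndarray:
    """Dilate by a ball of the given physical radius."""
    mask = np.asarray(mask, dtype=bool)
    if radius_mm <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing_mm)
    return dist <= radius_mm


def erode_mm(mask: np.ndarray, radius_mm: float, spacing_mm) -> np.ndarray:
    """Erode by a ball of the given physical radius."""
    mask = np.asarray(mask, dtype=bool)
    if radius_mm <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(mask, sampling=spacing_mm)
    return dist > radius_mm


def close_mm(mask: np.ndarray, radius_mm: float, spacing_mm) -> np.ndarray:
    return erode_mm(dilate_mm(mask, radius_mm, spacing_mm), radius_mm, spacing_mm)


def open_mm(mask: np.ndarray, radius_mm: float, spacing_mm) -> np.ndarray:
    return dilate_mm(erode_mm(mask, radius_mm, spacing_mm), radius_mm, spacing_mm)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 26-connected component of a binary mask (empty in → empty out)."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return np.zeros_like(np.asarray(mask, dtype=bool))
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))
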