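"""Core in-memory containers shared across the pipeline.

All modules operate in voxel index space plus a physical spacing in mm;
axis order is fixed to the array's native (i, j, k) order with spacing_mm
giving the physical size of a voxel step along each axis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError

#: CT number range of a signed 12-bit scanner; values are clamped to it.
HU_MIN = -1024.0
HU_MAX = 3071.0


def _check_spacing(spacing_mm) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing_mm must be three positive reals, got {spacing_mm}")
    return spacing


@dataclass
class CTVolume:
    """A 3D CT image in Hounsfield units with voxel spacing and acquisition time.

    Parameters
    ----------
    voxels : ndarray, 3D
        HU values; non-finite values are rejected, out-of-range values are
        clamped to ``[HU_MIN, HU_MAX]``.
    spacing_mm : (float, float, float)
        Physical voxel size along each array axis, mm.
    time_h : float
        Acquisition time in hours post-mortem.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    time_h: float = 0.0

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.float32)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise ValueError(f"voxels must be a 3D array, got shape {vox.shape}")
        if not np.isfinite(vox).all():
            raise ValueError("HU values must be finite")
        self.voxels = np.clip(vox, HU_MIN, HU_MAX)
        self.spacing_mm = _check_spacing(self.spacing_mm)
        self.time_h = float(self.time_h)
        if self.time_h < 0:
            raise ValueError("time_h must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        s = self.spacing_mm
        return s[0] * s[1] * s[2]


def check_same_grid(a_shape, b_shape, what: str = "arrays") -> None:
    if tuple(a_shape) != tuple(b_shape):
        raise GridMismatchError(f"{what} must share a grid: {tuple(a_shape)} vs {tuple(b_shape)}")


@dataclass
class GroundTruth:
    """Known segmentation truth attached to a synthetic volume."""

    lcv_mask: np.ndarray
    true_volume_ml: float
    true_mean_hu: float

    def __post_init__(self) -> None:
        self.lcv_mask = np.asarray(self.lcv_mask, dtype=bool)


@dataclass
class SeedSet:
    """Hard-constraint foreground (ventricle) and background voxel sets.

    Both masks live on the same grid, are nonempty and disjoint.
    """

    fg: np.ndarray
    bg: np.ndarray

    def __post_init__(self) -> None:
        self.fg = np.asarray(self.fg, dtype=bool)
        self.bg = np.asarray(self.bg, dtype=bool)
        check_same_grid(self.fg.shape, self.bg.shape, "seed masks")
        if not self.fg.any():
            raise ValueError("foreground seed mask is empty")
        if not self.bg.any():
            raise ValueError("background seed mask is empty")
        if (self.fg & self.bg).any():
            raise ValueError("foreground and background seeds overlap")


class QCFlag(str, enum.Enum):
    """Per-time-point quality-control outcome of the measurement step."""

    OK = "ok"
    COLLAPSED = "collapsed"
    FAILED = "failed"


@dataclass
class Measurement:
    """Volume and mean attenuation of the segmented ventricles at one time point."""

    time_h: float
    volume_ml: float
    mean_hu: float
    voxel_count: int
    qc_flag: QCFlag = QCFlag.OK

    def __post_init__(self) -> None:
        self.qc_flag = QCFlag(self.qc_flag)
        self.voxel_count = int(self.voxel_count)
        if self.voxel_count < 0:
            raise ValueError("voxel_count must be non-negative")
        if self.volume_ml < 0:
            raise ValueError("volume_ml must be non-negative")
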