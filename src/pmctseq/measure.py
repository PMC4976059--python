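"""Volume and mean-attenuation quantification of a segmented ventricle.

Volume is voxel counting times the physical voxel volume; mean HU is the
arithmetic mean of the stored (unresampled) HU values over the labeled
voxels. Both lateral ventricles are measured as one combined region. A
measurement whose volume falls below the collapse threshold is flagged
``collapsed`` — the operational stand-in for the regime where the ventricle
has narrowed too far to measure; an empty segmentation is flagged ``failed``
with zero sentinel fields (never NaN).
"""

from __future__ import annotations

import numpy as np

from .core import CTVolume, Measurement, QCFlag, check_same_grid
from .graphcut import Segmentation


def measure(
    vol: CTVolume,
    seg: Segmentation | np.ndarray,
    collapse_threshold_ml: float = 2.0,
) -> Measurement:
    """Measure one time point from its segmentation labels."""
    labels = seg.labels if isinstance(seg, Segmentation) else np.asarray(seg)
    check_same_grid(vol.shape, labels.shape, "volume and segmentation")
    mask = labels.astype(bool)
    voxel_count = int(mask.sum())
    volume_ml = voxel_count * vol.voxel_volume_mm3 / 1000.0
    if voxel_count == 0:
        return Measurement(vol.time_h, 0.0, 0.0, 0, QCFlag.FAILED)
    mean_hu = float(vol.voxels[mask].mean())
    flag = QCFlag.COLLAPSED if volume_ml < collapse_threshold_ml else QCFlag.OK
    return Measurement(vol.time_h, volume_ml, mean_hu, voxel_count, flag)
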