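"""Seed-region construction from a rough observer delineation.

A human (or the phantom's simulated observer) supplies only a sloppy trace of
the ventricles. The trace is smoothed by morphological closing then opening
with a ball structuring element of physical radius, eroded inward to obtain
foreground seeds safely clear of the partial-volume boundary, and surrounded
by a background shell taken between two dilations of the trace. Foreground
and background are disjoint by construction.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._morph import close_mm, dilate_mm, erode_mm, largest_component, open_mm
from .core import SeedSet
from .errors import EmptyMaskError, GridTooSmallError


def seeds_from_rough(
    rough: np.ndarray,
    erode_mm_r: float = 2.0,
    bg_inner_mm: float = 4.0,
    bg_outer_mm: float = 8.0,
    spacing_mm=(1.0, 1.0, 1.0),
    smooth_mm: float = 1.0,
) -> SeedSet:
    """Turn a rough ventricle trace into hard foreground/background seeds.

    Parameters
    ----------
    rough : binary 3D mask
        Observer's rough delineation of the ventricles.
    erode_mm_r : float
        Inward erosion of the smoothed trace, mm. Should exceed the trace's
        boundary uncertainty so foreground seeds stay inside the true CSF.
    bg_inner_mm, bg_outer_mm : float
        The background shell is ``dilate(rough, outer) − dilate(rough, inner)``;
        requires ``bg_outer_mm > bg_inner_mm >= erode_mm_r``.
    smooth_mm : float
        Radius of the closing-then-opening smoothing ball.

    Raises
    ------
    EmptyMaskError
        If the rough mask is empty.
    GridTooSmallError
        If the background shell is empty (the trace touches the image border);
        regenerate on a larger grid.
    """
    rough = np.asarray(rough, dtype=bool)
    if not rough.any():
        raise EmptyMaskError("rough delineation is empty")
    if not (bg_outer_mm > bg_inner_mm >= erode_mm_r):
        raise ValueError("need bg_outer_mm > bg_inner_mm >= erode_mm")

    smoothed = open_mm(close_mm(rough, smooth_mm, spacing_mm), smooth_mm, spacing_mm)
    if not smoothed.any():
        smoothed = rough
    fg = erode_mm(smoothed, erode_mm_r, spacing_mm)
    if not fg.any():
        warnings.warn(
            "erosion emptied the foreground seeds; falling back to the largest "
            "connected component of the smoothed trace",
            stacklevel=2,
        )
        fg = largest_component(smoothed)

    bg = dilate_mm(rough, bg_outer_mm, spacing_mm) & ~dilate_mm(rough, bg_inner_mm, spacing_mm)
    if not bg.any():
        raise GridTooSmallError(
            "background shell is empty — the trace touches the image border; "
            "use a larger grid or a thinner shell"
        )
    return SeedSet(fg=fg, bg=bg)
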