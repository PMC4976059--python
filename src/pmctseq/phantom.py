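"""Synthetic sequential head-CT phantom with known ventricle ground truth.

The phantom emulates what the segmentation pipeline needs from a real
post-mortem head series: a CSF-filled lateral-ventricle compartment inside
brain tissue inside a skull shell inside air, scanned repeatedly over the
first post-mortem day. Two temporal trends are imposed exactly on the ground
truth: the ventricle volume changes linearly at ``vol_rate_ml_per_h`` and the
CSF attenuation changes linearly at ``hu_rate_per_h``. Partial-volume effects
are modelled by a Gaussian point-spread blur, reconstruction noise by i.i.d.
additive Gaussian noise applied after the blur.

The ventricle is a mirrored pair of curved, tapering tubes: a thick central
body arching over the thalamus with thin frontal and posterior horns, which
reproduces the characteristic narrowing of the horns as the volume shrinks.
The pair is voxelized through a single precomputed normalized-distance field;
a scale factor on the tube radii is found by bisection so that the voxelized
mask volume matches the linear volume model to voxelization precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._morph import dilate_mm, erode_mm
from .core import CTVolume, GroundTruth
from .errors import CollapseError, EmptyMaskError, GridTooSmallError

#: upper bound for the radius scale searched by bisection
_S_MAX = 3.5
_N_CURVE_SAMPLES = 160


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic sequential series.

    Defaults reproduce a typical case: a ~27 ml ventricle shrinking at
    0.27 ml/h while the CSF rises from ~11 HU at 0.23 HU/h, scanned hourly
    from 2 to 20 h post-mortem on a 128³ grid at 1 mm isotropic. The blur
    FWHM approximates the in-plane point spread of a standard head
    reconstruction kernel.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    v0_ml: float = 27.08
    vol_rate_ml_per_h: float = -0.27
    hu0_csf: float = 11.12
    hu_rate_per_h: float = 0.23
    hu_brain: float = 35.0
    hu_skull: float = 700.0
    hu_air: float = -1000.0
    blur_fwhm_mm: float = 1.0
    noise_sd_hu: float = 2.0
    schedule_h: tuple[float, ...] = tuple(float(t) for t in range(2, 21))
    deform_amp_mm: float = 0.0
    rng_seed: int = 0
    on_collapse: str = "raise"  # "raise" or "clamp"

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 1 for n in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm components must be > 0")
        sched = tuple(float(t) for t in self.schedule_h)
        if not sched:
            raise ValueError("schedule_h must be nonempty")
        if any(t < 0 for t in sched) or any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("schedule_h must be strictly increasing and non-negative")
        if self.blur_fwhm_mm < 0 or self.noise_sd_hu < 0 or self.deform_amp_mm < 0:
            raise ValueError("blur/noise/deformation amplitudes must be non-negative")
        if self.on_collapse not in ("raise", "clamp"):
            raise ValueError('on_collapse must be "raise" or "clamp"')
        object.__setattr__(self, "schedule_h", sched)

    def volume_at(self, t: float) -> float:
        return self.v0_ml + self.vol_rate_ml_per_h * t

    def csf_hu_at(self, t: float) -> float:
        return self.hu0_csf + self.hu_rate_per_h * t


def _grid_coords_mm(shape, spacing):
    axes = [np.arange(n, dtype=np.float64) * s for n, s in zip(shape, spacing)]
    return axes


def _ventricle_curves(center_mm: np.ndarray):
    """Centerline samples and base radii (mm) of the bilateral ventricle pair."""
    t = np.linspace(0.0, 1.0, _N_CURVE_SAMPLES)
    arch = np.sin(np.pi * t)
    centers = []
    radii = []
    for side in (+1.0, -1.0):
        cx = center_mm[0] + side * (12.0 + 4.0 * arch)
        cy = center_mm[1] + (t - 0.5) * 68.0
        cz = center_mm[2] + 10.0 * arch - 3.0
        centers.append(np.stack([cx, cy, cz], axis=1))
        radii.append(5.0 * (0.35 + 0.65 * arch ** 0.7))
    return np.concatenate(centers, axis=0), np.concatenate(radii, axis=0)


def _ventricle_field(shape, spacing) -> np.ndarray:
    """Normalized distance field f with mask(s) = (f < s).

    f(x) = min over centerline samples i of |x - c_i| / r_i, so thresholding
    at a scale s yields the union of balls of radius s·r_i along the curve —
    a smooth tapering tube whose radii scale with s.
    """
    shape = tuple(int(n) for n in shape)
    extent = np.array(shape, dtype=np.float64) * np.array(spacing, dtype=np.float64)
    center = extent / 2.0
    centers, radii = _ventricle_curves(center)
    field_arr = np.full(shape, np.inf, dtype=np.float32)
    axes = _grid_coords_mm(shape, spacing)
    for c, r in zip(centers, radii):
        reach = r * _S_MAX
        los = [max(0, int(np.floor((c[d] - reach) / spacing[d]))) for d in range(3)]
        his = [min(shape[d], int(np.ceil((c[d] + reach) / spacing[d])) + 1) for d in range(3)]
        if any(lo >= hi for lo, hi in zip(los, his)):
            continue
        sub = tuple(slice(lo, hi) for lo, hi in zip(los, his))
        dx = axes[0][sub[0]] - c[0]
        dy = axes[1][sub[1]] - c[1]
        dz = axes[2][sub[2]] - c[2]
        d2 = dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        np.minimum(field_arr[sub], np.sqrt(d2, dtype=np.float32) / r, out=field_arr[sub])
    return field_arr


def _head_masks(shape, spacing):
    """Skull shell and brain interior as ellipsoid masks centred in the grid."""
    extent = np.array(shape, dtype=np.float64) * np.array(spacing, dtype=np.float64)
    center = extent / 2.0
    outer = np.array([50.0, 58.0, 50.0])
    thickness = 4.0
    axes = _grid_coords_mm(shape, spacing)
    def ellipsoid(radii):
        q = ((axes[0] - center[0]) / radii[0]) ** 2
        q = q[:, None, None] + (((axes[1] - center[1]) / radii[1]) ** 2)[None, :, None]
        q = q + (((axes[2] - center[2]) / radii[2]) ** 2)[None, None, :]
        return q <= 1.0
    head = ellipsoid(outer)
    brain = ellipsoid(outer - thickness)
    skull = head & ~brain
    return skull, brain


def _smooth_displacement(shape, spacing, amp_mm, rng) -> np.ndarray:
    """Random smooth displacement field (mm), shape (3, *grid), max |d| ≈ amp."""
    ctrl = rng.uniform(-1.0, 1.0, size=(3, 5, 5, 5))
    zoom = [n / 5.0 for n in shape]
    dense = np.stack(
        [ndimage.zoom(ctrl[d], zoom, order=3, mode="nearest", grid_mode=True) for d in range(3)]
    )
    peak = np.abs(dense).max()
    if peak > 0:
        dense *= amp_mm / peak
    return dense.astype(np.float32)


def _voxelize_to_volume(field_arr, target_ml, voxel_mm3, spacing) -> np.ndarray:
    """Bisection on the radius scale so the voxelized volume matches target_ml."""
    target_vox = target_ml * 1000.0 / voxel_mm3
    count_at = lambda s: int(np.count_nonzero(field_arr < s))
    if count_at(_S_MAX) < target_vox:
        raise GridTooSmallError(
            f"cannot fit {target_ml:.2f} ml on this grid; enlarge the grid or shrink v0_ml"
        )
    lo, hi = 0.0, _S_MAX
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if count_at(mid) < target_vox:
            lo = mid
        else:
            hi = mid
    n_lo, n_hi = count_at(lo), count_at(hi)
    s = lo if abs(n_lo - target_vox) < abs(n_hi - target_vox) else hi
    mask = field_arr < s
    # voxelization error bound: half a voxel layer over the surface
    surface = mask & ~ndimage.binary_erosion(mask)
    bound_ml = max(surface.sum(), 1) * voxel_mm3 / 1000.0
    achieved_ml = mask.sum() * voxel_mm3 / 1000.0
    if abs(achieved_ml - target_ml) > 0.5 * bound_ml + voxel_mm3 / 1000.0:
        raise GridTooSmallError(
            f"voxelization error too large: wanted {target_ml:.3f} ml, got {achieved_ml:.3f} ml"
        )
    return mask


def make_phantom_series(spec: PhantomSpec) -> list[tuple[CTVolume, GroundTruth]]:
    """Generate one synthetic series, one ``(CTVolume, GroundTruth)`` per time point.

    The ground-truth mask at time t is voxelized to match
    ``v0_ml + vol_rate_ml_per_h * t`` to voxelization precision and carries
    ``true_mean_hu = hu0_csf + hu_rate_per_h * t`` (the clean CSF value before
    blur and noise). With ``deform_amp_mm > 0`` every non-reference time point
    is additionally perturbed by a seeded smooth deformation of the ventricle,
    emulating small inter-scan tissue shifts for seed-propagation testing.

    Raises
    ------
    CollapseError
        If the target volume is ≤ 0 at some time point and
        ``on_collapse="raise"``; with ``"clamp"`` the mask is empty there.
    GridTooSmallError
        If the requested volume cannot be voxelized inside the brain.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = tuple(float(s) for s in spec.spacing_mm)
    voxel_mm3 = spacing[0] * spacing[1] * spacing[2]
    base_field = _ventricle_field(shape, spacing)
    skull, brain = _head_masks(shape, spacing)
    sigma_vox = [spec.blur_fwhm_mm / 2.354820045 / s for s in spacing]

    out: list[tuple[CTVolume, GroundTruth]] = []
    for ti, t in enumerate(spec.schedule_h):
        target_ml = spec.volume_at(t)
        if target_ml <= 0:
            if spec.on_collapse == "raise":
                raise CollapseError(
                    f"ventricle volume {target_ml:.3f} ml ≤ 0 at t = {t:g} h"
                )
            mask = np.zeros(shape, dtype=bool)
        else:
            field_t = base_field
            if spec.deform_amp_mm > 0 and ti > 0:
                rng_d = np.random.default_rng([spec.rng_seed, 1000 + ti])
                disp = _smooth_displacement(shape, spacing, spec.deform_amp_mm, rng_d)
                idx = np.indices(shape, dtype=np.float32)
                coords = idx + disp / np.asarray(spacing, dtype=np.float32)[:, None, None, None]
                field_t = ndimage.map_coordinates(base_field, coords, order=1, mode="nearest")
            mask = _voxelize_to_volume(field_t, target_ml, voxel_mm3, spacing)
            if (mask & ~brain).any():
                raise GridTooSmallError("ventricle does not fit inside the brain compartment")

        csf_hu = spec.csf_hu_at(t)
        img = np.full(shape, spec.hu_air, dtype=np.float32)
        img[skull] = spec.hu_skull
        img[brain] = spec.hu_brain
        img[mask] = csf_hu
        if spec.blur_fwhm_mm > 0:
            img = ndimage.gaussian_filter(img, sigma=sigma_vox)
        if spec.noise_sd_hu > 0:
            rng_n = np.random.default_rng([spec.rng_seed, ti])
            img = img + rng_n.normal(0.0, spec.noise_sd_hu, size=shape).astype(np.float32)

        gt = GroundTruth(
            lcv_mask=mask,
            true_volume_ml=int(mask.sum()) * voxel_mm3 / 1000.0,
            true_mean_hu=csf_hu,
        )
        out.append((CTVolume(img, spacing, time_h=t), gt))
    return out


def make_rough_delineation(
    gt: GroundTruth,
    dilate_mm_r: float,
    jitter_seed: int,
    spacing_mm=(1.0, 1.0, 1.0),
    jitter_frac: float = 0.2,
) -> np.ndarray:
    """Simulate a sloppy human mouse trace of the ventricle.

    The ground-truth mask is dilated by ``dilate_mm_r`` and its boundary is
    jittered by randomly adding outer-boundary voxels and removing
    inner-boundary voxels with probability ``jitter_frac`` (set to 0 for no
    jitter). With ``dilate_mm_r = 0`` and jitter off the trace is exactly the
    ground truth.
    """
    mask = np.asarray(gt.lcv_mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("ground-truth mask is empty")
    rough = dilate_mm(mask, dilate_mm_r, spacing_mm)
    if jitter_frac > 0:
        rng = np.random.default_rng(jitter_seed)
        outer = dilate_mm(rough, max(spacing_mm), spacing_mm) & ~rough
        inner = rough & ~erode_mm(rough, max(spacing_mm), spacing_mm)
        add = outer & (rng.random(rough.shape) < jitter_frac)
        drop = inner & (rng.random(rough.shape) < jitter_frac)
        rough = (rough | add) & ~drop
    if not rough.any():
        raise EmptyMaskError("rough delineation came out empty")
    return rough
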