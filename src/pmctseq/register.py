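"""Seed propagation across acquisitions via B-spline free-form deformation.

Sequential post-mortem series are acquired without moving the subject, so
inter-scan motion is absent or tiny; the default pipeline therefore
propagates seeds by identity. When a deformation is present (or requested),
a cubic B-spline free-form deformation (FFD) is estimated: displacement
vectors live on a coarse control-point lattice and are interpolated to a
dense field by the tensor-product cubic B-spline basis, so zero coefficients
give the identity and uniform coefficients give an exact translation
(partition of unity). The control displacements minimize the mean squared
HU difference between the fixed image and the warped moving image — the
natural metric for same-subject, same-modality alignment — by gradient
descent with a backtracking line search on the analytic gradient. The
objective is non-increasing across accepted steps and the whole procedure
is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._morph import erode_mm
from .core import CTVolume, SeedSet, check_same_grid
from .errors import RegistrationDivergenceError


def _bspline_weight_matrix(n_vox: int, spacing: float, grid_mm: float) -> np.ndarray:
    """Per-axis weights W[v, c]: cubic B-spline basis of control c at voxel v."""
    pos = np.arange(n_vox, dtype=np.float64) * spacing
    u = pos / grid_mm
    i = np.floor(u).astype(int)
    t = u - i
    basis = [
        (1.0 - t) ** 3 / 6.0,
        (3.0 * t**3 - 6.0 * t**2 + 4.0) / 6.0,
        (-3.0 * t**3 + 3.0 * t**2 + 3.0 * t + 1.0) / 6.0,
        t**3 / 6.0,
    ]
    n_ctrl = int(np.floor(pos[-1] / grid_mm)) + 4 if n_vox > 1 else 4
    w = np.zeros((n_vox, n_ctrl))
    rows = np.arange(n_vox)
    for l, b in enumerate(basis):
        w[rows, i + l] = b  # control index i+l-1, stored with a +1 pad offset
    return w


@dataclass
class FFDTransform:
    """A cubic B-spline FFD: control-lattice displacements in mm.

    ``displacements`` has shape ``(3, nci, ncj, nck)`` (one vector component
    per leading index, in array axis order); all-zero displacements are the
    identity mapping. The lattice covers the image with one control-cell pad
    on each side so every voxel has full cubic support.
    """

    control_grid_spacing_mm: tuple[float, float, float]
    displacements: np.ndarray
    image_shape: tuple[int, int, int]
    image_spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        if self.displacements.ndim != 4 or self.displacements.shape[0] != 3:
            raise ValueError("displacements must have shape (3, nci, ncj, nck)")

    def _weight_matrices(self):
        return [
            _bspline_weight_matrix(n, s, g)
            for n, s, g in zip(self.image_shape, self.image_spacing_mm,
                               self.control_grid_spacing_mm)
        ]

    @classmethod
    def identity(cls, image_shape, image_spacing_mm, grid_spacing_mm: float = 16.0) -> "FFDTransform":
        shape = tuple(int(n) for n in image_shape)
        spacing = tuple(float(s) for s in image_spacing_mm)
        grids = (float(grid_spacing_mm),) * 3
        n_ctrl = [
            int(np.floor((n - 1) * s / g)) + 4 if n > 1 else 4
            for n, s, g in zip(shape, spacing, grids)
        ]
        return cls(grids, np.zeros((3, *n_ctrl)), shape, spacing)

    @classmethod
    def translation(cls, image_shape, image_spacing_mm, offset_mm,
                    grid_spacing_mm: float = 16.0) -> "FFDTransform":
        """Exact uniform translation by the B-spline partition of unity."""
        out = cls.identity(image_shape, image_spacing_mm, grid_spacing_mm)
        for d in range(3):
            out.displacements[d] = float(offset_mm[d])
        return out

    def dense_displacement_mm(self) -> np.ndarray:
        """Dense field, shape ``(3, *image_shape)``, mm, array axis order."""
        wx, wy, wz = self._weight_matrices()
        out = np.empty((3, *self.image_shape))
        for d in range(3):
            f = np.tensordot(wx, self.displacements[d], axes=(1, 0))
            f = np.tensordot(f, wy, axes=(1, 1))  # (x, z_ctrl? ...) -> reorder below
            # after first tensordot: (nx, ncj, nck); second: (nx, nck, ny)
            f = np.tensordot(f, wz, axes=(1, 1))  # (nx, ny, nz)
            out[d] = f
        return out

    def warp_coordinates(self) -> np.ndarray:
        """Voxel-index sampling coordinates x + d(x) for pulling the moving image."""
        disp = self.dense_displacement_mm()
        idx = np.indices(self.image_shape, dtype=np.float64)
        spacing = np.asarray(self.image_spacing_mm)[:, None, None, None]
        return idx + disp / spacing


def _warp_image(moving: np.ndarray, coords: np.ndarray, order: int) -> np.ndarray:
    return ndimage.map_coordinates(moving, coords, order=order, mode="nearest")


def register_ffd(
    fixed: CTVolume,
    moving: CTVolume,
    grid_spacing_mm: float = 16.0,
    max_iters: int = 60,
    tol: float = 1e-6,
    seed: int = 0,
    smooth_mm: float = 2.0,
    reg_weight: float = 10.0,
) -> FFDTransform:
    """Estimate the FFD warping ``moving`` onto ``fixed``.

    Gradient descent with backtracking line search on the mean squared HU
    difference; the step is taken in the control-displacement space with the
    analytic gradient (chain rule through the linear B-spline interpolation
    and the moving image's spatial gradient). Stops when the relative
    objective improvement falls below ``tol``, the line search cannot find a
    descent step, or ``max_iters`` accepted iterations. ``seed`` is accepted
    for interface stability; the procedure has no random component.
    """
    del seed
    check_same_grid(fixed.shape, moving.shape, "fixed and moving volumes")
    if tuple(fixed.spacing_mm) != tuple(moving.spacing_mm):
        raise RegistrationDivergenceError("fixed and moving spacings differ")

    transform = FFDTransform.identity(fixed.shape, fixed.spacing_mm, grid_spacing_mm)
    # fixed pre-smoothing widens the metric's capture range beyond the voxel
    # scale of sharp CT edges (symmetric blur leaves the optimum in place)
    sigma_vox = [smooth_mm / s for s in fixed.spacing_mm]
    f = ndimage.gaussian_filter(fixed.voxels.astype(np.float64), sigma_vox)
    m = ndimage.gaussian_filter(moving.voxels.astype(np.float64), sigma_vox)
    n = f.size
    m_grad = np.gradient(m, *fixed.spacing_mm)  # HU / mm
    wx, wy, wz = transform._weight_matrices()
    spacing = np.asarray(fixed.spacing_mm)[:, None, None, None]
    idx = np.indices(fixed.shape, dtype=np.float64)

    n_ctrl = transform.displacements[0].size

    def penalty(u: np.ndarray) -> float:
        # first-difference smoothness on the control lattice; zero for any
        # uniform field, so exact translations are never penalized
        p = 0.0
        for ax in range(1, 4):
            du = np.diff(u, axis=ax)
            p += float(np.sum(du**2))
        return reg_weight * p / n_ctrl

    def penalty_grad(u: np.ndarray) -> np.ndarray:
        g = np.zeros_like(u)
        for ax in range(1, 4):
            du = np.diff(u, axis=ax)
            lo = [slice(None)] * 4
            hi = [slice(None)] * 4
            lo[ax] = slice(0, -1)
            hi[ax] = slice(1, None)
            g[tuple(lo)] -= 2.0 * du
            g[tuple(hi)] += 2.0 * du
        return reg_weight * g / n_ctrl

    def objective(u: np.ndarray) -> tuple[float, np.ndarray]:
        disp = np.empty((3, *fixed.shape))
        for d in range(3):
            t1 = np.tensordot(wx, u[d], axes=(1, 0))
            t2 = np.tensordot(t1, wy, axes=(1, 1))
            disp[d] = np.tensordot(t2, wz, axes=(1, 1))
        coords = idx + disp / spacing
        warped = _warp_image(m, coords, order=1)
        resid = warped - f
        return float(np.mean(resid**2)) + penalty(u), coords

    wx2, wy2, wz2 = wx**2, wy**2, wz**2

    def gradient(coords: np.ndarray, u_current: tuple) -> tuple[np.ndarray, np.ndarray]:
        """Analytic gradient and diagonal Gauss-Newton curvature per control."""
        warped = _warp_image(m, coords, order=1)
        resid = (2.0 / n) * (warped - f)
        g = np.empty_like(transform.displacements)
        h = np.empty_like(g)
        for d in range(3):
            gm = _warp_image(m_grad[d], coords, order=1)
            vox_term = resid * gm  # d(mse)/d(dense displacement_d), per voxel
            t1 = np.tensordot(wx, vox_term, axes=(0, 0))
            t2 = np.tensordot(t1, wy, axes=(1, 0))
            g[d] = np.tensordot(t2, wz, axes=(1, 0))
            curv = (2.0 / n) * gm**2  # diag(J'J) of the linearized residual
            c1 = np.tensordot(wx2, curv, axes=(0, 0))
            c2 = np.tensordot(c1, wy2, axes=(1, 0))
            h[d] = np.tensordot(c2, wz2, axes=(1, 0))
        g += penalty_grad(u_current)
        h += 4.0 * reg_weight / n_ctrl
        return g, h

    u = transform.displacements
    mse, coords = objective(u)
    mse_identity = mse
    if not np.isfinite(mse):
        raise RegistrationDivergenceError("non-finite objective at identity")
    if mse == 0.0:
        return transform

    step = 1.0
    for _ in range(int(max_iters)):
        g, h = gradient(coords, u)
        if np.abs(g).max() == 0:
            break
        # diagonally preconditioned (Gauss-Newton) descent direction; the
        # damping floor keeps steps bounded where the image has no contrast
        direction = -g / (1.05 * h + 1e-7 * h.max() + 1e-30)
        np.clip(direction, -grid_spacing_mm, grid_spacing_mm, out=direction)
        accepted = False
        while step >= 1e-4:
            trial_mse, trial_coords = objective(u + step * direction)
            if trial_mse < mse:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        improvement = (mse - trial_mse) / mse
        u = u + step * direction
        mse, coords = trial_mse, trial_coords
        step = min(step * 1.5, 1.0)
        if improvement < tol:
            break

    if not np.isfinite(mse) or mse > mse_identity * (1.0 + 1e-12):
        raise RegistrationDivergenceError(
            f"objective did not decrease: identity {mse_identity:.6g} -> {mse:.6g}"
        )
    transform.displacements = u
    return transform


def warp_mask(mask: np.ndarray, transform: FFDTransform) -> np.ndarray:
    """Resample a binary mask through the FFD with nearest-neighbor interpolation.

    The identity transform returns the input mask bit-exactly.
    """
    mask = np.asarray(mask)
    check_same_grid(mask.shape, transform.image_shape, "mask and transform")
    if not np.any(transform.displacements):
        return mask.astype(bool).copy()
    coords = transform.warp_coordinates()
    return ndimage.map_coordinates(
        mask.astype(np.uint8), coords, order=0, mode="constant", cval=0
    ).astype(bool)


def propagate_seeds(
    seedset: SeedSet, transform: FFDTransform, guard_erode_vox: int = 1
) -> SeedSet | None:
    """Warp a SeedSet through the transform, keeping hard constraints safe.

    The warped foreground is eroded by ``guard_erode_vox`` voxels so that
    resampling edge effects cannot push hard foreground constraints onto
    boundary voxels; any voxel claimed by both classes after warping is
    removed from the background with a warning. Returns None when the warped
    foreground (or background) is empty.
    """
    fg = warp_mask(seedset.fg, transform)
    bg = warp_mask(seedset.bg, transform)
    if guard_erode_vox > 0:
        spacing = transform.image_spacing_mm
        fg = erode_mm(fg, guard_erode_vox * min(spacing), spacing)
    overlap = fg & bg
    if overlap.any():
        warnings.warn(
            f"{int(overlap.sum())} voxels claimed by both warped seed classes; "
            "removed from background",
            stacklevel=2,
        )
        bg = bg & ~fg
    if not fg.any() or not bg.any():
        return None
    return SeedSet(fg=fg, bg=bg)
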