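"""Per-class intensity models: 1D Gaussian mixtures fitted by EM.

For every acquisition, the HU samples under the foreground seeds (CSF) and
background seeds (brain/bone/air) are modelled independently by Gaussian
mixtures fitted with expectation–maximization. Initialization is a
deterministic quantile split of the sorted sample, so the whole pipeline is
reproducible without any random restarts; variances are floored to keep
degenerate (constant) samples well-defined. The fitted mixtures supply the
per-voxel negative log-likelihood maps that become the graph-cut data terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core import CTVolume, SeedSet
from .errors import PmctseqError

_LOG_DENSITY_FLOOR = np.log(1e-300)


@dataclass
class GaussianMixture1D:
    """A 1D Gaussian mixture: weights sum to 1, variances are floored."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik_history: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if not (len(self.weights) == len(self.means) == len(self.variances)):
            raise ValueError("component arrays must have equal length")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if (self.variances <= 0).any():
            raise ValueError("variances must be positive")

    @property
    def k(self) -> int:
        return len(self.weights)

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """Elementwise log p(x) under the mixture."""
        x = np.asarray(x, dtype=float)
        comp = (
            np.log(self.weights)
            - 0.5 * np.log(2.0 * np.pi * self.variances)
            - 0.5 * (x[..., None] - self.means) ** 2 / self.variances
        )
        return logsumexp(comp, axis=-1)


@dataclass
class MixtureModel:
    """Foreground (CSF) and background intensity mixtures for one acquisition."""

    fg: GaussianMixture1D
    bg: GaussianMixture1D


def _quantile_init(x: np.ndarray, k: int, var_floor: float) -> GaussianMixture1D:
    xs = np.sort(x)
    blocks = np.array_split(xs, k)
    weights = np.array([len(b) for b in blocks], dtype=float)
    weights /= weights.sum()
    means = np.array([b.mean() for b in blocks])
    variances = np.maximum([b.var() for b in blocks], var_floor)
    return GaussianMixture1D(weights, means, variances)


def fit_gmm_1d(
    x: np.ndarray,
    k: int,
    max_iters: int = 200,
    tol: float = 1e-7,
    var_floor: float = 0.25,
) -> GaussianMixture1D:
    """Fit a k-component 1D Gaussian mixture by EM with quantile initialization.

    The log-likelihood is non-decreasing across iterations (standard EM
    guarantee; the variance floor can only be active on degenerate samples,
    where a warning is emitted). Iteration stops when the relative
    improvement drops below ``tol`` or after ``max_iters`` iterations.
    """
    x = np.asarray(x, dtype=float).ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(x) < k:
        raise PmctseqError(f"need at least {k} samples to fit {k} components, got {len(x)}")
    if np.ptp(x) == 0 and k > 1:
        warnings.warn("all samples identical; mixture collapses onto the variance floor",
                      stacklevel=2)

    gm = _quantile_init(x, k, var_floor)
    if k == 1:
        # closed-form MLE: sample mean and (floored) sample variance
        gm = GaussianMixture1D(
            np.array([1.0]),
            np.array([x.mean()]),
            np.array([max(x.var(), var_floor)]),
        )
        ll = float(gm.log_density(x).sum())
        gm.loglik_history = (ll,)
        return gm

    history: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iters):
        log_comp = (
            np.log(gm.weights)
            - 0.5 * np.log(2.0 * np.pi * gm.variances)
            - 0.5 * (x[:, None] - gm.means) ** 2 / gm.variances
        )
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(log_norm.sum())
        history.append(ll)
        if ll - prev_ll < tol * (abs(prev_ll) + 1.0) and np.isfinite(prev_ll):
            break
        prev_ll = ll
        resp = np.exp(log_comp - log_norm[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        gm = GaussianMixture1D(nk / len(x), means, np.maximum(variances, var_floor))
    gm.loglik_history = tuple(history)
    return gm


def fit_em(
    vol: CTVolume,
    seedset: SeedSet,
    k_fg: int = 1,
    k_bg: int = 3,
    max_iters: int = 200,
    tol: float = 1e-7,
    seed: int = 0,
    var_floor: float = 0.25,
) -> MixtureModel:
    """Fit per-class Gaussian mixtures to the seed-voxel HU samples.

    CSF is near-homogeneous, so one foreground component suffices by default;
    the background shell mixes brain, bone and sometimes air, hence three
    components. ``seed`` is accepted for interface stability but unused: the
    quantile initialization makes the fit deterministic.
    """
    del seed
    fg_x = vol.voxels[seedset.fg]
    bg_x = vol.voxels[seedset.bg]
    return MixtureModel(
        fg=fit_gmm_1d(fg_x, k_fg, max_iters, tol, var_floor),
        bg=fit_gmm_1d(bg_x, k_bg, max_iters, tol, var_floor),
    )


def neg_log_likelihood(vol: CTVolume, model: MixtureModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel −log p(HU | class) under each class mixture.

    Densities are floored at 1e-300, so the returned maps are finite
    everywhere and bounded by ≈ 690.8.
    """
    x = vol.voxels.astype(np.float64)
    nll_fg = -np.maximum(model.fg.log_density(x), _LOG_DENSITY_FLOOR)
    nll_bg = -np.maximum(model.bg.log_density(x), _LOG_DENSITY_FLOOR)
    return nll_fg, nll_bg
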