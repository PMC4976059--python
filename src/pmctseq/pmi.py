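"""Linear post-mortem-interval (PMI) models and their inversion.

Ventricle volume falls and CSF attenuation rises approximately linearly over
the first post-mortem day, so each quantity y is modelled as
``y = slope · t + intercept`` by ordinary least squares on the
quality-controlled measurements. Inverting a fit turns a new measurement
into a PMI estimate ``t̂ = (y − intercept) / slope`` with a first-order
(delta-method in the slope) confidence interval. Because the volume slope is
shallow relative to its scatter, a combined estimator weights the HU- and
volume-based estimates by their inverse variances, which automatically leans
on the attenuation trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import Measurement, QCFlag
from .errors import PmctseqError, ZeroSlopeError

_Z95 = 1.959963984540054


@dataclass
class LinearFit:
    """OLS fit of a quantity against hours post-mortem."""

    slope: float
    intercept: float
    slope_se: float
    r2: float
    n: int
    quantity: str  # "volume" or "hu"

    def __post_init__(self) -> None:
        if self.quantity not in ("volume", "hu"):
            raise ValueError('quantity must be "volume" or "hu"')
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError("r2 must lie in [0, 1]")
        if self.slope_se < 0:
            raise ValueError("slope_se must be non-negative")
        if self.n < 3:
            raise ValueError("a fit needs at least 3 points")


@dataclass
class PmiEstimate:
    """A PMI point estimate with a first-order confidence interval (hours)."""

    pmi_h: float
    ci_low_h: float
    ci_high_h: float
    source: str  # "hu", "volume" or "combined"
    clipped: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low_h <= self.pmi_h <= self.ci_high_h):
            raise ValueError("confidence interval must contain the estimate")


def _valid_points(measurements, quantity: str):
    ts, ys = [], []
    for m in measurements:
        if m.qc_flag != QCFlag.OK:
            continue
        ts.append(m.time_h)
        ys.append(m.volume_ml if quantity == "volume" else m.mean_hu)
    return np.asarray(ts, dtype=float), np.asarray(ys, dtype=float)


def fit_linear(measurements, quantity: str) -> LinearFit:
    """OLS of the chosen quantity on time, excluding non-OK time points.

    Degenerate data are handled by convention: a constant response gives
    slope 0 and r² = 0.
    """
    if quantity not in ("volume", "hu"):
        raise ValueError('quantity must be "volume" or "hu"')
    t, y = _valid_points(measurements, quantity)
    if len(t) < 3:
        raise PmctseqError(f"need >= 3 valid measurements, got {len(t)}")
    if len(np.unique(t)) < 2 or np.ptp(t) == 0:
        raise PmctseqError("zero time variance: all measurements at the same time")
    if np.ptp(y) == 0:
        return LinearFit(0.0, float(y[0]), 0.0, 0.0, len(t), quantity)
    res = stats.linregress(t, y)
    r2 = float(res.rvalue**2)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        r2=min(max(r2, 0.0), 1.0),
        n=len(t),
        quantity=quantity,
    )


def predict(fit: LinearFit, t: float) -> float:
    return fit.slope * t + fit.intercept


def estimate_pmi(value: float, fit: LinearFit) -> PmiEstimate:
    """Invert a linear fit: t̂ = (value − intercept) / slope.

    The interval propagates only the slope's standard error to first order
    (sd(t̂) ≈ |t̂| · slope_se / |slope|) — a documented approximation that
    ignores intercept uncertainty and measurement noise in ``value``.
    Negative estimates are clipped to zero and flagged.
    """
    if fit.slope == 0:
        raise ZeroSlopeError("cannot invert a zero-slope fit")
    pmi = (value - fit.intercept) / fit.slope
    sd = abs(pmi) * fit.slope_se / abs(fit.slope)
    lo, hi = pmi - _Z95 * sd, pmi + _Z95 * sd
    clipped = pmi < 0
    if clipped:
        pmi, lo, hi = 0.0, 0.0, max(hi, 0.0)
    else:
        lo = max(lo, 0.0)
    source = "hu" if fit.quantity == "hu" else "volume"
    return PmiEstimate(pmi, lo, hi, source, clipped)


def _variance(est: PmiEstimate) -> float:
    return ((est.ci_high_h - est.ci_low_h) / (2.0 * _Z95)) ** 2


def estimate_pmi_combined(volume_ml: float, mean_hu: float, fits) -> PmiEstimate:
    """Inverse-variance-weighted combination of the volume- and HU-based PMI.

    ``fits`` is a pair (volume LinearFit, hu LinearFit). When one estimate's
    variance dominates (e.g. the shallow volume trend), its weight vanishes
    and the combination approaches the other single-source estimate; when
    both variances are zero the estimates are averaged.
    """
    vol_fit, hu_fit = fits
    if vol_fit.quantity != "volume" or hu_fit.quantity != "hu":
        raise ValueError("fits must be (volume fit, hu fit)")
    e_v = estimate_pmi(volume_ml, vol_fit)
    e_h = estimate_pmi(mean_hu, hu_fit)
    var_v, var_h = _variance(e_v), _variance(e_h)
    if var_v == 0.0 and var_h == 0.0:
        pmi = 0.5 * (e_v.pmi_h + e_h.pmi_h)
        return PmiEstimate(pmi, pmi, pmi, "combined", e_v.clipped or e_h.clipped)
    if not np.isfinite(var_v) or var_v == np.inf:
        w_v, w_h = 0.0, 1.0 / var_h
    elif not np.isfinite(var_h):
        w_v, w_h = 1.0 / var_v, 0.0
    else:
        w_v = 1.0 / var_v if var_v > 0 else np.inf
        w_h = 1.0 / var_h if var_h > 0 else np.inf
        if np.isinf(w_v) or np.isinf(w_h):
            # a zero-variance source dominates entirely
            src = e_v if np.isinf(w_v) else e_h
            return PmiEstimate(src.pmi_h, src.pmi_h, src.pmi_h, "combined", src.clipped)
    pmi = (w_v * e_v.pmi_h + w_h * e_h.pmi_h) / (w_v + w_h)
    var = 1.0 / (w_v + w_h)
    sd = np.sqrt(var)
    lo, hi = pmi - _Z95 * sd, pmi + _Z95 * sd
    clipped = pmi < 0
    if clipped:
        pmi, lo, hi = 0.0, 0.0, max(hi, 0.0)
    else:
        lo = max(lo, 0.0)
    return PmiEstimate(pmi, lo, hi, "combined", clipped or e_v.clipped or e_h.clipped)


# --------------------------------------------------------------------------
# simulation helpers for parameter-recovery studies


def simulate_measurements(
    slope: float,
    intercept: float,
    schedule_h,
    noise_sd: float,
    rng: np.random.Generator,
    quantity: str = "hu",
) -> list[Measurement]:
    """Draw one synthetic measurement series from a linear trend plus noise."""
    out = []
    for t in schedule_h:
        y = slope * t + intercept + rng.normal(0.0, noise_sd)
        if quantity == "volume":
            out.append(Measurement(t, max(y, 0.0), 0.0, 0, QCFlag.OK))
        else:
            out.append(Measurement(t, 0.0, y, 0, QCFlag.OK))
    return out


def replicate_fits(
    slope: float,
    intercept: float,
    schedule_h,
    noise_sd: float,
    n_replicates: int,
    seed: int,
    quantity: str = "hu",
) -> list[LinearFit]:
    """Repeatedly simulate a series from the trend and refit OLS.

    Used for slope/intercept recovery studies: the distribution of the
    refitted coefficients around the generating values characterizes how
    well a given scan schedule pins down the trend.
    """
    fits = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        ms = simulate_measurements(slope, intercept, schedule_h, noise_sd, rng, quantity)
        fits.append(fit_linear(ms, quantity))
    return fits
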