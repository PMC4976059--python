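import numpy as np
import pytest

from pmctseq import (
    REFERENCE_CASES,
    estimate_pmi,
    estimate_pmi_combined,
    fit_linear,
    predict,
    replicate_fits,
    simulate_measurements,
)
from pmctseq.core import Measurement, QCFlag
from pmctseq.errors import PmctseqError, ZeroSlopeError
from pmctseq.pmi import LinearFit


def exact_line(slope, intercept, times, quantity="hu"):
    rows = []
    for t in times:
        y = slope * t + intercept
        if quantity == "volume":
            rows.append(Measurement(t, y, 0.0, 0, QCFlag.OK))
        else:
            rows.append(Measurement(t, 0.0, y, 0, QCFlag.OK))
    return rows


def test_noiseless_recovery_of_reference_volume_trend():
    c1 = REFERENCE_CASES["case1"]
    rows = exact_line(c1.volume.slope, c1.volume.intercept, c1.schedule_h, "volume")
    fit = fit_linear(rows, "volume")
    assert fit.slope == pytest.approx(-0.27, abs=1e-12)
    assert fit.intercept == pytest.approx(27.08, abs=1e-10)
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)
    assert fit.n == 19


def test_constant_response_convention():
    rows = exact_line(0.0, 5.0, (1.0, 2.0, 3.0, 4.0))
    fit = fit_linear(rows, "hu")
    assert fit.slope == 0.0
    assert fit.r2 == 0.0
    assert fit.slope_se == 0.0


def test_r2_one_iff_zero_residuals():
    rng = np.random.default_rng(0)
    t = np.arange(10, dtype=float)
    rows = [Measurement(ti, 0.0, 2.0 * ti + 1.0 + rng.normal(0, 0.5), 0, QCFlag.OK)
            for ti in t]
    noisy = fit_linear(rows, "hu")
    assert noisy.r2 < 1.0
    exact = fit_linear(exact_line(2.0, 1.0, t), "hu")
    resid = [2.0 * ti + 1.0 - predict(exact, ti) for ti in t]
    assert exact.r2 == pytest.approx(1.0, abs=1e-12)
    assert max(abs(r) for r in resid) < 1e-12


@pytest.mark.parametrize("seed", range(20))
def test_ols_matches_grid_search_oracle(seed):
    """Closed-form OLS agrees with brute-force SSE minimization on a grid."""
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, 24, 8))
    y = rng.uniform(-1, 1) * t + rng.uniform(0, 40) + rng.normal(0, 1, 8)
    rows = [Measurement(ti, 0.0, yi, 0, QCFlag.OK) for ti, yi in zip(t, y)]
    fit = fit_linear(rows, "hu")
    slopes = np.linspace(fit.slope - 0.5, fit.slope + 0.5, 201)
    intercepts = np.linspace(fit.intercept - 2, fit.intercept + 2, 201)
    sse = ((y[None, None, :] - (slopes[:, None, None] * t[None, None, :]
                                + intercepts[None, :, None])) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    assert slopes[i] == pytest.approx(fit.slope, abs=0.5 / 200 * 2 + 1e-9)
    assert intercepts[j] == pytest.approx(fit.intercept, abs=2 / 200 * 2 + 1e-9)


def test_collapsed_points_excluded():
    c1 = REFERENCE_CASES["case1"]
    rows = exact_line(c1.volume.slope, c1.volume.intercept, c1.schedule_h, "volume")
    rows += [Measurement(21.0, 0.0, 0.0, 0, QCFlag.COLLAPSED),
             Measurement(22.0, 0.0, 0.0, 0, QCFlag.FAILED)]
    fit = fit_linear(rows, "volume")
    assert fit.n == 19
    assert fit.slope == pytest.approx(-0.27, abs=1e-12)


def test_insufficient_or_degenerate_data():
    with pytest.raises(PmctseqError):
        fit_linear(exact_line(1.0, 0.0, (1.0, 2.0)), "hu")
    same_time = [Measurement(5.0, 0.0, float(v), 0, QCFlag.OK) for v in (1, 2, 3)]
    with pytest.raises(PmctseqError):
        fit_linear(same_time, "hu")


class TestEstimatePmi:
    def test_reference_hu_inversion(self):
        fit = LinearFit(0.23, 11.12, 0.33, 0.92, 19, "hu")
        est = estimate_pmi(13.42, fit)
        assert est.pmi_h == pytest.approx(10.0, abs=1e-9)
        assert est.ci_low_h <= est.pmi_h <= est.ci_high_h

    def test_intercept_maps_to_zero(self):
        fit = LinearFit(0.23, 11.12, 0.33, 0.92, 19, "hu")
        est = estimate_pmi(11.12, fit)
        assert est.pmi_h == 0.0

    def test_round_trip_inverse_identity(self):
        fit = fit_linear(exact_line(0.34, 11.28, tuple(range(1, 17))), "hu")
        for t in (0.0, 3.5, 12.0, 24.0):
            assert estimate_pmi(predict(fit, t), fit).pmi_h == pytest.approx(t, abs=1e-9)

    def test_negative_clipped(self):
        fit = LinearFit(0.23, 11.12, 0.33, 0.92, 19, "hu")
        est = estimate_pmi(10.0, fit)
        assert est.pmi_h == 0.0
        assert est.clipped

    def test_zero_slope_rejected(self):
        fit = LinearFit(0.0, 5.0, 0.0, 0.0, 4, "hu")
        with pytest.raises(ZeroSlopeError):
            estimate_pmi(5.0, fit)


class TestCombinedEstimate:
    def _fits(self, vol_se=0.02, hu_se=0.01):
        return (LinearFit(-0.27, 27.08, vol_se, 0.98, 19, "volume"),
                LinearFit(0.23, 11.12, hu_se, 0.92, 19, "hu"))

    def test_agreeing_sources(self):
        fits = self._fits()
        t = 10.0
        est = estimate_pmi_combined(predict(fits[0], t), predict(fits[1], t), fits)
        assert est.pmi_h == pytest.approx(t, abs=1e-9)
        assert est.source == "combined"

    def test_infinite_volume_variance_reduces_to_hu(self):
        fits = self._fits(vol_se=1e9, hu_se=0.01)
        est = estimate_pmi_combined(20.0, 13.42, fits)
        hu_only = estimate_pmi(13.42, fits[1])
        assert est.pmi_h == pytest.approx(hu_only.pmi_h, abs=1e-3)

    def test_combined_variance_never_worse(self):
        fits = self._fits(vol_se=0.05, hu_se=0.04)
        v, h = predict(fits[0], 8.0), predict(fits[1], 12.0)
        est = estimate_pmi_combined(v, h, fits)
        e_v, e_h = estimate_pmi(v, fits[0]), estimate_pmi(h, fits[1])

        def width(e):
            return e.ci_high_h - e.ci_low_h

        assert width(est) <= min(width(e_v), width(e_h)) + 1e-9


def test_slope_recovery_within_three_se():
    """Refitting simulated series recovers the slope within 3 SE in >=95 %."""
    c2 = REFERENCE_CASES["case2"]
    fits = replicate_fits(c2.hu.slope, c2.hu.intercept, c2.schedule_h, 0.8, 200, 77, "hu")
    ok = sum(abs(f.slope - c2.hu.slope) <= 3.0 * f.slope_se for f in fits)
    assert ok >= 190


def test_simulated_measurements_deterministic():
    rng1 = np.random.default_rng(5)
    rng2 = np.random.default_rng(5)
    a = simulate_measurements(0.3, 11.0, (1.0, 2.0, 3.0), 0.8, rng1)
    b = simulate_measurements(0.3, 11.0, (1.0, 2.0, 3.0), 0.8, rng2)
    assert a == b
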