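"""Preprocessing: ERETIC scaling, referencing, ALS baseline, masking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spcpanel.config import BaselineParams, ExclusionRegions
from spcpanel.processing import (
    als_baseline,
    apply_eretic,
    calibrate_reference,
    mask_regions,
    preprocess,
)
from spcpanel.spectrum import Spectrum


def _flat(n=2001, lo=0.4, hi=9.5, value=0.0, **kw):
    ppm = np.linspace(lo, hi, n)
    return Spectrum(ppm, np.full(n, float(value)), **kw)


# ---------------------------------------------------------------------------
# ERETIC


def test_eretic_identity_and_scaling():
    s = _flat(value=4.0, eretic_factor=1.0)
    assert np.allclose(apply_eretic(s).intensity, 4.0)
    s2 = _flat(value=4.0, eretic_factor=2.0)
    assert np.allclose(apply_eretic(s2).intensity, 2.0)


def test_eretic_double_application_rejected():
    s = apply_eretic(_flat(value=4.0, eretic_factor=2.0))
    before = s.intensity.copy()
    with pytest.raises(RuntimeError):
        apply_eretic(s)
    np.testing.assert_array_equal(s.intensity, before)


def test_nonpositive_eretic_rejected():
    with pytest.raises(ValueError):
        Spectrum(np.array([1.0, 2.0]), np.zeros(2), eretic_factor=0.0)


# ---------------------------------------------------------------------------
# reference calibration


def _water_line(center, height=100.0, n=18201):
    ppm = np.linspace(0.4, 9.5, n)
    y = height * 0.01**2 / ((ppm - center) ** 2 + 0.01**2)
    return Spectrum(ppm, y, water_ppm=4.70)


def test_calibration_no_shift_when_on_reference():
    out = calibrate_reference(_water_line(4.70))
    assert abs(out.flags["calibration_shift"]) < 1e-4
    assert not out.flags.get("calibration_warning", False)


def test_calibration_corrects_offset_peak():
    # argmax oracle: line synthesized at 4.72, reference 4.70 -> shift -0.02
    out = calibrate_reference(_water_line(4.72))
    assert out.flags["calibration_shift"] == pytest.approx(0.02, abs=2e-4)
    sel = (out.ppm >= 4.5) & (out.ppm <= 4.9)
    assert out.ppm[sel][np.argmax(out.intensity[sel])] == pytest.approx(4.70, abs=1e-3)


def test_calibration_flat_spectrum_flagged():
    out = calibrate_reference(_flat())
    assert out.flags["calibration_warning"]
    assert out.flags["calibration_shift"] == 0.0


# ---------------------------------------------------------------------------
# ALS baseline


def test_als_constant_is_fixed_point():
    y = np.full(1000, 7.5)
    z = als_baseline(y, BaselineParams())
    assert np.max(np.abs(z - y)) <= 1e-6 * 7.5


def test_als_transmits_linear_ramp():
    # the second-difference penalty is blind to linear trends
    x = np.linspace(0, 1, 1500)
    y = 3.0 + 2.0 * x
    z = als_baseline(y, BaselineParams())
    assert np.max(np.abs(z - y) / np.abs(y)) <= 1e-4


def test_als_stays_under_isolated_spike():
    n = 2000
    x = np.linspace(0, 1, n)
    spike = 100.0 * 0.002**2 / ((x - 0.5) ** 2 + 0.002**2)
    z = als_baseline(spike, BaselineParams())
    assert z[n // 2] <= 0.02 * 100.0


def _dense_als(y, params):
    """Dense least-squares oracle for the penalised Whittaker system.

    Solves the same normal equations with a dense np.linalg.solve; linear
    detrending (a penalty null-space component) conditions both solvers
    identically without changing the solution."""
    n = y.size
    x = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    trend = intercept + slope * x
    r = y - trend
    d2 = np.diff(np.eye(n), 2, axis=0)
    pen = params.lam * d2.T @ d2
    w = np.ones(n)
    for _ in range(params.n_iter):
        z = trend + np.linalg.solve(np.diag(w) + pen, w * r)
        w = np.where(y > z, params.p, 1.0 - params.p)
    return z


def test_als_banded_solver_matches_dense_oracle():
    rng = np.random.default_rng(42)
    x = np.linspace(0, 1, 1200)
    y = 5 + 3 * np.sin(2 * x) + rng.normal(0, 0.1, x.size)
    y[400:410] += 50.0
    params = BaselineParams(lam=1e5, p=1e-3, n_iter=6)
    z_banded = als_baseline(y, params)
    z_dense = _dense_als(y, params)
    assert np.max(np.abs(z_banded - z_dense)) <= 1e-8


@pytest.mark.parametrize("bad", [np.array([1.0, np.nan, 2.0]), np.array([1.0, np.inf, 2.0])])
def test_als_rejects_nonfinite(bad):
    with pytest.raises(ValueError):
        als_baseline(bad)


def test_als_rejects_too_short():
    with pytest.raises(ValueError):
        als_baseline(np.array([1.0, 2.0]))


@settings(deadline=None, derandomize=True, max_examples=20)
@given(a=st.floats(-5, 5), b=st.floats(-5, 5))
def test_baseline_neutral_to_linear_offsets(a, b):
    """Adding a + b*ppm to a spectrum leaves post-subtraction residuals
    essentially unchanged (<= 1e-3 relative to the signal scale)."""
    ppm = np.linspace(0.4, 9.5, 4001)
    rng = np.random.default_rng(0)
    signal = 50 * np.exp(-0.5 * ((ppm - 3.25) / 0.01) ** 2) + rng.normal(0, 0.05, ppm.size)
    r0 = signal - als_baseline(signal)
    r1 = (signal + a + b * ppm) - als_baseline(signal + a + b * ppm)
    assert np.max(np.abs(r1 - r0)) <= 1e-3 * 50


# ---------------------------------------------------------------------------
# masking


def test_mask_water_and_noise_regions():
    ppm = np.array([0.39, 0.40, 2.07, 4.49, 4.50, 4.70, 4.90, 4.91, 9.50, 9.51])
    s = Spectrum(ppm, np.ones_like(ppm))
    out = mask_regions(s, ExclusionRegions())
    expected = [False, True, True, True, False, False, False, True, True, False]
    assert out.mask.tolist() == expected


def test_masking_idempotent():
    ppm = np.linspace(0.3, 9.6, 500)
    s = Spectrum(ppm, np.ones_like(ppm))
    once = mask_regions(s)
    twice = mask_regions(once)
    np.testing.assert_array_equal(once.mask, twice.mask)


def test_invalid_exclusions_rejected():
    with pytest.raises(ValueError):
        ExclusionRegions(water=(4.9, 4.5)).validate()
    with pytest.raises(ValueError):
        ExclusionRegions(water=(0.1, 4.9)).validate()


# ---------------------------------------------------------------------------
# composed preprocessing


def test_preprocess_records_all_steps():
    s = _water_line(4.70)
    out = preprocess(s)
    assert out.steps == ["eretic", "calibrate", "baseline", "mask"]
    assert out.is_preprocessed
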