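import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from criticalhr import (fit_critical_hr, fit_critical_speed,
                        fit_inverse_time_form, predict_time, predicted_hrmax,
                        prescribe_intensity, relative_intensity)
from criticalhr.errors import ConfigError, FitError


def normal_equations(x, y):
    """Independent closed-form OLS oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xb, yb = x.mean(), y.mean()
    slope = ((x - xb) * (y - yb)).sum() / ((x - xb) ** 2).sum()
    return slope, yb - slope * xb


class TestCriticalSpeedFit:
    def test_collinear_through_origin(self):
        fit = fit_critical_speed([(400, 250), (800, 500), (1200, 750)])
        assert fit.slope == pytest.approx(1.6, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_exact_line_with_intercept(self):
        # d = 1.2 t + 50  =>  t = (d - 50) / 1.2
        pts = [(d, (d - 50.0) / 1.2) for d in (400.0, 800.0, 1200.0)]
        fit = fit_critical_speed(pts)
        assert fit.slope == pytest.approx(1.2, abs=1e-10)
        assert fit.intercept == pytest.approx(50.0, abs=1e-7)

    def test_perturbed_points_match_normal_equations(self):
        t = np.array([(d - 50.0) / 1.2 for d in (400.0, 800.0, 1200.0)])
        t += np.array([2.0, -2.0, 1.3])
        d = np.array([400.0, 800.0, 1200.0])
        fit = fit_critical_speed(list(zip(d, t)))
        slope, intercept = normal_equations(t, d)
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)

    def test_units_consistency(self):
        fit = fit_critical_speed([(400, 290), (800, 610), (1200, 935)])
        assert fit.slope_m_per_min == pytest.approx(60.0 * fit.slope, rel=1e-15)

    def test_too_few_points(self):
        with pytest.raises(FitError, match="at least 2"):
            fit_critical_speed([(400, 250)])

    def test_identical_times_singular(self):
        with pytest.raises(FitError, match="singular"):
            fit_critical_speed([(400, 250), (800, 250), (1200, 250)])

    def test_two_points_accepted_with_warning(self):
        with pytest.warns(UserWarning, match="recommends 3"):
            fit = fit_critical_speed([(400, 250), (1200, 750)])
        assert fit.slope == pytest.approx(1.6)

    @given(st.lists(st.tuples(st.floats(100, 2000), st.floats(60, 1500)),
                    min_size=3, max_size=6))
    def test_oracle_equivalence_random(self, pts):
        t = np.array([p[1] for p in pts])
        if np.unique(t).size < 2 or np.ptp(t) < 1.0:  # skip near-singular designs
            return
        fit = fit_critical_speed(pts)
        slope, intercept = normal_equations(t, [p[0] for p in pts])
        assert fit.slope == pytest.approx(slope, abs=1e-9, rel=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-6, rel=1e-9)


class TestCriticalHRFit:
    def test_exact_line(self):
        # HB = 130 t(min) + 20
        fit = fit_critical_hr([(670, 300), (1320, 600), (2100, 960)])
        assert fit.slope == pytest.approx(130.0, abs=1e-9)
        assert fit.intercept == pytest.approx(20.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_proportional(self):
        fit = fit_critical_hr([(140 * 5.0, 300), (140 * 10.0, 600), (140 * 16.0, 960)])
        assert fit.slope == pytest.approx(140.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)

    def test_noisy_matches_oracle(self, rng):
        t = np.array([300.0, 600.0, 960.0])
        hb = 130.0 * t / 60.0 + 20.0 + rng.normal(0, 5, 3)
        fit = fit_critical_hr(list(zip(hb, t)))
        slope, intercept = normal_equations(t / 60.0, hb)
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)

    def test_negative_heartbeats_rejected(self):
        with pytest.raises(FitError):
            fit_critical_hr([(-5, 300), (1320, 600)])


class TestInverseTimeForm:
    def test_agrees_on_exact_line(self):
        pts = [(d, (d - 50.0) / 1.2) for d in (400.0, 800.0, 1200.0)]
        direct = fit_critical_speed(pts)
        inverse = fit_inverse_time_form(pts)
        assert inverse.slope == pytest.approx(direct.slope, abs=1e-9)
        assert inverse.intercept == pytest.approx(direct.intercept, abs=1e-6)
        assert inverse.parameterization == "inverse_time"

    def test_origin_line(self):
        fit = fit_inverse_time_form([(400, 250), (800, 500), (1200, 750)])
        assert fit.slope == pytest.approx(1.6, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)

    def test_differs_under_noise_and_is_reported(self, rng):
        d = np.array([400.0, 800.0, 1200.0])
        t = (d - 40.0) / 1.3 * (1 + rng.normal(0, 0.03, 3))
        direct = fit_critical_speed(list(zip(d, t)))
        inverse = fit_inverse_time_form(list(zip(d, t)))
        # both are reported; they genuinely disagree on noisy data
        assert direct.slope != pytest.approx(inverse.slope, abs=1e-12)


class TestPredictTime:
    def test_origin_model(self):
        fit = fit_critical_speed([(400, 250), (800, 500), (1200, 750)])
        assert predict_time(fit, 800.0) == pytest.approx(500.0, abs=1e-9)

    def test_algebraic_inversion(self):
        pts = [(d, (d - 50.0) / 1.2) for d in (400.0, 800.0, 1200.0)]
        fit = fit_critical_speed(pts)
        assert predict_time(fit, 1200.0) == pytest.approx(1150.0 / 1.2, abs=1e-6)

    def test_distance_below_reserve_is_domain_error(self):
        pts = [(d, (d - 50.0) / 1.2) for d in (400.0, 800.0, 1200.0)]
        fit = fit_critical_speed(pts)
        with pytest.raises(ValueError, match="D'"):
            predict_time(fit, 40.0)

    @given(st.floats(100.0, 5000.0), st.floats(100.0, 5000.0))
    def test_strictly_monotone_in_distance(self, d1, d2):
        pts = [(d, (d - 50.0) / 1.2) for d in (400.0, 800.0, 1200.0)]
        fit = fit_critical_speed(pts)
        if d1 == d2:
            return
        lo, hi = sorted((d1, d2))
        assert predict_time(fit, lo) < predict_time(fit, hi)


class TestPrescription:
    @pytest.mark.parametrize("target,zone", [
        (140.0, "above_chr"), (130.0, "at_chr"), (120.0, "below_chr"),
        (133.0, "at_chr"), (133.5, "above_chr"),
    ])
    def test_zones(self, target, zone):
        fit = fit_critical_hr([(130 * 5.0, 300), (130 * 10.0, 600), (130 * 16.0, 960)])
        assert prescribe_intensity(fit, target).zone == zone

    def test_speed_fit_rejected(self):
        fit = fit_critical_speed([(400, 250), (800, 500), (1200, 750)])
        with pytest.raises(TypeError):
            prescribe_intensity(fit, 130.0)


class TestRelativeIntensity:
    def test_fox_formula(self):
        assert relative_intensity(104.0, 60.0, "fox") == pytest.approx(65.0)

    def test_tanaka_formula(self):
        # HRmax(65) = 208 - 45.5 = 162.5
        assert predicted_hrmax(65.0) == pytest.approx(162.5)
        assert relative_intensity(110.5, 65.0, "tanaka") == pytest.approx(68.0)

    def test_gellish_formula(self):
        assert predicted_hrmax(70.0, "gellish") == pytest.approx(158.0)

    def test_age_out_of_range(self):
        with pytest.raises(ValueError):
            relative_intensity(104.0, 10.0)

    def test_unknown_formula(self):
        with pytest.raises(ConfigError):
            relative_intensity(104.0, 60.0, "magic")
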