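import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from criticalhr import (PairedMeasurements, cv_percent, icc, mdc,
                        paired_effect, reliability_report, sem, typical_error)
from criticalhr.errors import DataValidationError
from criticalhr.reliability import MDC_FACTOR, effect_band, holm_adjusted_p


def pairs_of(test, retest, metric="m"):
    return PairedMeasurements.from_arrays(metric, test, retest)


class TestTypicalError:
    def test_identical_sessions(self):
        assert typical_error(pairs_of([1, 2, 3], [1, 2, 3])) == 0.0

    def test_alternating_differences(self):
        # diffs [1,-1,1,-1]: SD = sqrt(4/3), TE = sqrt(4/3)/sqrt(2)
        p = pairs_of([2, 1, 2, 1], [1, 2, 1, 2])
        assert typical_error(p) == pytest.approx(math.sqrt(4 / 3) / math.sqrt(2))
        assert typical_error(p) == pytest.approx(0.8165, abs=5e-5)

    def test_converges_to_noise_sd(self, rng):
        # each session = subject value + independent N(0, sigma) noise
        sigma, n = 3.0, 10_000
        base = rng.normal(50, 10, n)
        p = pairs_of(base + rng.normal(0, sigma, n), base + rng.normal(0, sigma, n))
        assert typical_error(p) == pytest.approx(sigma, rel=0.03)

    def test_single_pair_rejected(self):
        with pytest.raises(DataValidationError):
            pairs_of([1], [2])

    @given(shift=st.floats(-50, 50))
    def test_shift_invariance(self, shift):
        base = pairs_of([10.0, 12.0, 9.0, 11.5], [10.5, 11.0, 9.8, 12.0])
        shifted = pairs_of([x + shift for x in base.test],
                           [x + shift for x in base.retest])
        assert typical_error(shifted) == pytest.approx(typical_error(base), abs=1e-9)


class TestCVPercent:
    def test_ratio_method_hand_computed(self):
        # diffs [10, -10]: SD = 10*sqrt(2), TE = 10; grand mean 100 -> 10%
        p = pairs_of([105.0, 95.0], [95.0, 105.0])
        assert typical_error(p) == pytest.approx(10.0, abs=1e-12)
        assert cv_percent(p) == pytest.approx(10.0, abs=1e-12)

    def test_identical_sessions_zero(self):
        assert cv_percent(pairs_of([100, 200], [100, 200])) == 0.0

    def test_log_method_hand_computed(self):
        p = pairs_of([100.0, 200.0], [110.0, 220.0])
        dlog = np.log([100 / 110, 200 / 220])
        expected = 100 * (math.exp(np.std(dlog, ddof=1) / math.sqrt(2)) - 1)
        assert cv_percent(p, method="log") == pytest.approx(expected, abs=1e-12)
        # equal ratios -> zero log-scale variation
        assert cv_percent(p, method="log") == pytest.approx(0.0, abs=1e-12)

    def test_log_method_requires_positive(self):
        with pytest.raises(DataValidationError):
            cv_percent(pairs_of([1.0, -2.0], [1.0, 2.0]), method="log")

    def test_not_shift_invariant(self):
        base = pairs_of([10.0, 12.0, 9.0, 11.5], [10.5, 11.0, 9.8, 12.0])
        shifted = pairs_of([x + 100 for x in base.test],
                           [x + 100 for x in base.retest])
        assert cv_percent(shifted) < cv_percent(base)


class TestICC:
    def test_perfect_agreement(self):
        assert icc(pairs_of([1, 2, 3, 4], [1, 2, 3, 4])) == pytest.approx(1.0)

    def test_constant_session_shift_hand_anova(self):
        # test = [1..4], retest = test + 1: consistency perfect, absolute
        # agreement penalized.  Hand ANOVA: MSR = 10/3, MSC = 2, MSE = 0
        # => ICC(2,1) = (10/3)/(10/3 + (2/4)*2) = 10/13.
        p = pairs_of([1, 2, 3, 4], [2, 3, 4, 5])
        assert icc(p, "icc31") == pytest.approx(1.0, abs=1e-12)
        assert icc(p, "icc21") == pytest.approx(10 / 13, abs=1e-12)
        assert icc(p, "icc21") < 1.0

    def test_long_form_names_accepted(self):
        p = pairs_of([1, 2, 3, 4], [2, 3, 4, 5])
        assert icc(p, "two_way_random_absolute") == icc(p, "icc21")
        assert icc(p, "two_way_mixed_consistency") == icc(p, "icc31")

    def test_independent_sessions_near_zero(self, rng):
        a, b = rng.normal(0, 1, 4000), rng.normal(0, 1, 4000)
        assert abs(icc(pairs_of(a, b))) < 0.05

    def test_zero_between_subject_variance_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            value = icc(pairs_of([5.0, 5.0, 5.0], [5.0, 5.0, 5.0]))
        assert math.isnan(value)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        a = rng.normal(100, 12, 12)
        b = a + rng.normal(1.5, 4, 12)
        p = pairs_of(a, b)
        long = pd.DataFrame({
            "subject": list(range(12)) * 2,
            "rater": ["t"] * 12 + ["r"] * 12,
            "score": np.concatenate([a, b]),
        })
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="score").set_index("Type")["ICC"]
        assert icc(p, "icc21") == pytest.approx(ref["ICC(A,1)"], abs=1e-9)
        assert icc(p, "icc31") == pytest.approx(ref["ICC(C,1)"], abs=1e-9)

    @given(shift=st.floats(0.1, 5.0))
    def test_consistency_at_least_absolute_under_shift(self, shift):
        base = [10.0, 14.0, 9.0, 16.0, 12.0]
        p = pairs_of(base, [x + shift for x in base])
        assert icc(p, "icc31") >= icc(p, "icc21")


class TestSemMdc:
    def test_sem_closed_form(self):
        assert sem(10.0, 0.84) == pytest.approx(4.0, abs=1e-12)
        assert sem(16.6, 0.75) == pytest.approx(8.3, abs=1e-12)
        assert sem(7.0, 1.0) == 0.0

    def test_sem_rejects_icc_above_one(self):
        with pytest.raises(ValueError):
            sem(10.0, 1.01)

    def test_mdc_closed_form(self):
        assert mdc(4.0) == pytest.approx(4.0 * 1.96 * math.sqrt(2), abs=1e-12)
        assert mdc(4.0) == pytest.approx(11.0874, abs=5e-4)
        assert mdc(0.0) == 0.0
        assert mdc(1.0) == pytest.approx(2.7718, abs=1e-4)

    def test_mdc_rejects_negative(self):
        with pytest.raises(ValueError):
            mdc(-1.0)


class TestPairedEffect:
    def test_identical_sessions(self):
        eff = paired_effect(pairs_of([1, 2, 3], [1, 2, 3]))
        assert eff.d == 0.0 and eff.band == "small"
        assert eff.p_value == 1.0

    @pytest.mark.parametrize("d,band", [
        (0.0, "small"), (0.20, "small"), (0.35, "moderate"), (0.50, "moderate"),
        (0.65, "large"), (0.80, "large"), (0.85, "very_large"), (-0.85, "very_large"),
    ])
    def test_banding_rule_boundaries(self, d, band):
        assert effect_band(d) == band

    def test_matches_scipy(self, rng):
        from scipy import stats
        a, b = rng.normal(10, 2, 9), rng.normal(11, 2, 9)
        eff = paired_effect(pairs_of(a, b))
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert eff.t_stat == pytest.approx(float(t_ref))
        assert eff.p_value == pytest.approx(float(p_ref))

    def test_zero_variance_nonzero_diff_limiting_p(self):
        eff = paired_effect(pairs_of([2.0, 3.0, 4.0], [1.0, 2.0, 3.0]))
        assert eff.degenerate and eff.p_value == 0.0 and eff.mean_diff == 1.0

    def test_dz_variant(self):
        p = pairs_of([2.0, 3.0, 5.0], [1.0, 2.5, 3.0])
        diffs = np.array(p.test) - np.array(p.retest)
        expected = diffs.mean() / np.std(diffs, ddof=1)
        assert paired_effect(p, d_method="dz").d == pytest.approx(expected)


class TestReliabilityReport:
    def test_identity_invariants(self, rng):
        a = rng.normal(100, 15, 20)
        b = a + rng.normal(0, 4, 20)
        rep = reliability_report(pairs_of(a, b, "x"))
        assert rep.sem == pytest.approx(rep.sd_used * math.sqrt(1 - rep.icc), abs=1e-9)
        assert rep.mdc == pytest.approx(rep.sem * MDC_FACTOR, abs=1e-9)
        assert rep.mdc / rep.sem == pytest.approx(MDC_FACTOR, abs=1e-12)
        assert rep.te >= 0

    def test_identical_sessions_degenerate_panel(self):
        rep = reliability_report(pairs_of([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert rep.te == 0.0 and rep.icc == pytest.approx(1.0)
        assert rep.sem == pytest.approx(0.0) and rep.mdc == pytest.approx(0.0)

    def test_icc_approaches_analytic_value(self, rng):
        # ICC -> sigma_b^2 / (sigma_b^2 + sigma_e^2) for large n
        sigma_b, sigma_e, n = 10.0, 5.0, 500
        expected = sigma_b ** 2 / (sigma_b ** 2 + sigma_e ** 2)
        base = rng.normal(0, sigma_b, n)
        rep = reliability_report(pairs_of(base + rng.normal(0, sigma_e, n),
                                          base + rng.normal(0, sigma_e, n)))
        assert rep.icc == pytest.approx(expected, abs=0.05)
        assert rep.te == pytest.approx(sigma_e, rel=0.1)

    def test_sem_sd_session_switch(self, rng):
        a = rng.normal(100, 15, 12)
        b = a + rng.normal(0, 5, 12)
        pooled = reliability_report(pairs_of(a, b), sem_sd="pooled")
        first = reliability_report(pairs_of(a, b), sem_sd="test")
        assert first.sd_used == pytest.approx(float(np.std(a, ddof=1)))
        assert pooled.sd_used != pytest.approx(first.sd_used, abs=1e-12)


def test_holm_adjustment_orders_and_caps():
    adj = holm_adjusted_p({"a": 0.01, "b": 0.04, "c": 0.4})
    assert adj["a"] == pytest.approx(0.03)
    assert adj["b"] == pytest.approx(0.08)
    assert adj["c"] == pytest.approx(0.4)
    assert all(0 <= v <= 1 for v in adj.values())
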