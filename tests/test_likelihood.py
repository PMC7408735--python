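"""Screening-history likelihood: kernels, detection modes, cohort sums."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from sojourn import (
    Cohort,
    DetectionMode,
    NaturalHistoryParams,
    FeatureClass,
    WomanRecord,
    cohort_log_likelihood,
    woman_log_likelihood,
)
from sojourn.interval_cancer import ie_closed_form
from sojourn.likelihood import (
    CompiledCohort,
    detection_mode_masses,
    interval_cancer_components,
    lik_censored,
    lik_clinical_unscreened_density,
    lik_interval_cancer_density,
    lik_screen_detected,
    pcdp_kernel,
)


def kernel_quadrature(lam1, lam2, a, b, T):
    """Brute-force numerical integral defining the PCDP kernel."""
    val, _ = integrate.quad(
        lambda u: lam1 * math.exp(-lam1 * u) * math.exp(-lam2 * (T - u)),
        a, b, epsabs=1e-14, epsrel=1e-12,
    )
    return val


class TestKernel:
    @given(
        lam1=st.floats(1e-4, 1.0), lam2=st.floats(1e-4, 1.0),
        a=st.floats(0.0, 5.0), width=st.floats(0.01, 5.0), slack=st.floats(0.0, 5.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_numerical_integration(self, lam1, lam2, a, width, slack):
        b = a + width
        T = b + slack
        assert pcdp_kernel(lam1, lam2, a, b, T) == pytest.approx(
            kernel_quadrature(lam1, lam2, a, b, T), abs=1e-10
        )

    def test_degenerate_rates(self):
        got = pcdp_kernel(0.3, 0.3, 1.0, 2.0, 2.0)
        assert got == pytest.approx(kernel_quadrature(0.3, 0.3 + 1e-12, 1.0, 2.0, 2.0), abs=1e-10)


class TestScreenDetected:
    def test_perfect_sensitivity_collapses_to_last_window(self, typical_params):
        p = NaturalHistoryParams(0.002, 0.266, 1.0)
        got = lik_screen_detected(p, (2.0, 4.0), 2)
        only_last = pcdp_kernel(p.lambda1, p.lambda2, 2.0, 4.0, 4.0)
        assert got == pytest.approx(only_last, rel=1e-12)

    def test_quadrature_oracle(self, typical_params):
        p = typical_params
        got = lik_screen_detected(p, (2.0, 4.0), 2)
        expected = p.sensitivity * (
            (1 - p.sensitivity) * kernel_quadrature(p.lambda1, p.lambda2, 0, 2, 4)
            + kernel_quadrature(p.lambda1, p.lambda2, 2, 4, 4)
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_round_ordering_matches_oracle(self, typical_params):
        """With equal windows, round 2 = decayed fresh pool + surviving misses:
        larger than round 1 when S < 1, smaller when S = 1 (pure pools)."""
        p = typical_params
        p1 = lik_screen_detected(p, (2.0, 4.0), 1)
        p2 = lik_screen_detected(p, (2.0, 4.0), 2)
        oracle2 = p.sensitivity * (
            (1 - p.sensitivity) * kernel_quadrature(p.lambda1, p.lambda2, 0, 2, 4)
            + kernel_quadrature(p.lambda1, p.lambda2, 2, 4, 4)
        )
        assert p2 == pytest.approx(oracle2, abs=1e-10)
        assert p2 > p1  # the 20% miss carry-over outweighs the e^{-2*lambda1} decay
        perfect = NaturalHistoryParams(p.lambda1, p.lambda2, 1.0)
        assert lik_screen_detected(perfect, (2.0, 4.0), 1) > lik_screen_detected(
            perfect, (2.0, 4.0), 2
        )

    def test_invalid_round(self, typical_params):
        with pytest.raises(ValueError):
            lik_screen_detected(typical_params, (2.0, 4.0), 3)
        with pytest.raises(ValueError):
            lik_screen_detected(typical_params, (4.0, 2.0), 1)


class TestIntervalCancer:
    def test_no_false_negatives_at_perfect_sensitivity(self):
        p = NaturalHistoryParams(0.002, 0.266, 1.0)
        fn, new = interval_cancer_components(p, (2.0,), 2.5)
        assert fn == 0.0
        assert new > 0.0

    def test_quadrature_oracle(self, typical_params):
        p = typical_params
        got = lik_interval_cancer_density(p, (2.0,), 2.5)
        expected = p.lambda2 * (
            (1 - p.sensitivity) * kernel_quadrature(p.lambda1, p.lambda2, 0, 2, 2.5)
            + kernel_quadrature(p.lambda1, p.lambda2, 2, 2.5, 2.5)
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_surfacing_must_follow_last_screen(self, typical_params):
        with pytest.raises(ValueError):
            lik_interval_cancer_density(typical_params, (2.0,), 1.5)

    def test_one_round_window_recovers_closed_form_ie(self):
        """Integrated interval mass over one cycle / (lambda1 * delta) tends to
        the steady-state I/E as the onset rate vanishes (S = 1, one screen)."""
        mst, delta, t1 = 3.76, 2.0, 40.0
        lam1 = 1e-7
        p = NaturalHistoryParams(lam1, 1.0 / mst, 1.0)
        mass, _ = integrate.quad(
            lambda v: lik_interval_cancer_density(p, (t1,), v),
            t1, t1 + delta, epsabs=1e-16, epsrel=1e-12,
        )
        assert mass / (lam1 * delta) == pytest.approx(
            ie_closed_form(mst, 1.0, delta), rel=1e-3
        )


class TestCensoredAndClinical:
    def test_no_screen_reduction(self, typical_params):
        p = typical_params
        got = lik_censored(p, (), 6.0)
        expected = math.exp(-p.lambda1 * 6.0) + pcdp_kernel(p.lambda1, p.lambda2, 0, 6.0, 6.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_no_disease_no_information(self):
        p = NaturalHistoryParams(1e-15, 0.3, 0.8)
        assert lik_censored(p, (2.0, 4.0), 6.0) == pytest.approx(1.0, abs=1e-12)

    def test_quadrature_oracle(self, typical_params):
        p = typical_params
        S = p.sensitivity
        got = lik_censored(p, (2.0, 4.0), 6.0)
        expected = (
            math.exp(-p.lambda1 * 6.0)
            + (1 - S) ** 2 * kernel_quadrature(p.lambda1, p.lambda2, 0, 2, 6)
            + (1 - S) * kernel_quadrature(p.lambda1, p.lambda2, 2, 4, 6)
            + kernel_quadrature(p.lambda1, p.lambda2, 4, 6, 6)
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_clinical_density_vanishes_at_origin(self, typical_params):
        assert lik_clinical_unscreened_density(typical_params, 1e-9) == pytest.approx(0.0, abs=1e-9)

    def test_clinical_degenerate_rates(self):
        p = NaturalHistoryParams(0.3, 0.3, 0.8)
        assert lik_clinical_unscreened_density(p, 1.0) == pytest.approx(
            0.09 * math.exp(-0.3), rel=1e-9
        )

    def test_clinical_density_integrates_to_onset_mass(self, typical_params):
        p = typical_params
        tau = 8.0
        mass, _ = integrate.quad(
            lambda v: lik_clinical_unscreened_density(p, v), 0, tau,
            epsabs=1e-13, epsrel=1e-11,
        )
        assert mass == pytest.approx(1.0 - lik_censored(p, (), tau), abs=1e-9)

    def test_censor_before_last_screen_rejected(self, typical_params):
        with pytest.raises(ValueError):
            lik_censored(typical_params, (2.0, 4.0), 3.0)


class TestTotalProbability:
    @given(
        lam1=st.floats(1e-4, 1.0), lam2=st.floats(1e-4, 1.0),
        sens=st.floats(0.3, 1.0), k=st.integers(0, 4),
        delta=st.floats(0.5, 3.0), lead=st.floats(0.5, 3.0), tail=st.floats(0.0, 3.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_masses_sum_to_one(self, lam1, lam2, sens, k, delta, lead, tail):
        """Screen-detected + surfacing + censored masses form a distribution."""
        p = NaturalHistoryParams(lam1, lam2, sens)
        screens = tuple(lead + i * delta for i in range(k))
        tau = (screens[-1] if screens else 0.0) + tail
        m = detection_mode_masses(p, screens, tau)
        assert m["total"] == pytest.approx(1.0, abs=1e-8)

    def test_monotone_in_lambda1_and_sensitivity(self):
        lam2 = 0.3
        screens = (2.0, 4.0)
        cens = [lik_censored(NaturalHistoryParams(l1, lam2, 0.8), screens, 6.0)
                for l1 in (1e-4, 1e-3, 1e-2, 1e-1)]
        assert all(b < a for a, b in zip(cens, cens[1:]))
        masses = [detection_mode_masses(NaturalHistoryParams(0.002, lam2, s), screens, 6.0)["interval"]
                  for s in (0.3, 0.5, 0.8, 1.0)]
        assert all(b < a for a, b in zip(masses, masses[1:]))


def _record_screen(id_, screens, j, feature=FeatureClass.STELLATE):
    return WomanRecord(id=id_, screen_times=screens, outcome=DetectionMode.SCREEN_DETECTED,
                       outcome_time=screens[j - 1], outcome_round=j, feature=feature)


class TestWomanAndCohort:
    def test_censored_no_disease_rate_gives_zero(self):
        p = NaturalHistoryParams(1e-300, 0.3, 0.8)
        rec = WomanRecord(id="w0", screen_times=(2.0,), outcome=DetectionMode.CENSORED,
                          outcome_time=5.0)
        assert woman_log_likelihood(p, rec) == pytest.approx(0.0, abs=1e-12)

    def test_single_feature_matches_mode_ops(self, typical_params):
        p = typical_params
        rec = _record_screen("w0", (2.0, 4.0), 2)
        assert woman_log_likelihood(p, rec) == pytest.approx(
            math.log(lik_screen_detected(p, (2.0, 4.0), 2)), rel=1e-12
        )
        rec_i = WomanRecord(id="w1", screen_times=(2.0,), outcome=DetectionMode.INTERVAL_CANCER,
                            outcome_time=2.5, feature=FeatureClass.STELLATE)
        assert woman_log_likelihood(p, rec_i) == pytest.approx(
            math.log(lik_interval_cancer_density(p, (2.0,), 2.5)), rel=1e-12
        )

    def test_multifeature_event_plus_other_censored(self, typical_params):
        pmap = {
            FeatureClass.STELLATE: typical_params,
            FeatureClass.CIRCULAR: NaturalHistoryParams(0.001, 0.4, 0.9),
        }
        rec = _record_screen("w0", (2.0, 4.0), 2)
        expected = math.log(lik_screen_detected(pmap[FeatureClass.STELLATE], (2.0, 4.0), 2))
        expected += math.log(lik_censored(pmap[FeatureClass.CIRCULAR], (2.0, 4.0), 4.0))
        assert woman_log_likelihood(pmap, rec) == pytest.approx(expected, rel=1e-12)

    def test_empty_cohort_zero(self, typical_params):
        assert cohort_log_likelihood(typical_params, Cohort([])) == 0.0

    def test_duplicated_record_doubles(self, typical_params):
        rec = _record_screen("w0", (2.0, 4.0), 1)
        rec2 = _record_screen("w1", (2.0, 4.0), 1)
        single = cohort_log_likelihood(typical_params, Cohort([rec]))
        double = cohort_log_likelihood(typical_params, Cohort([rec, rec2]))
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_compiled_matches_naive_sum(self, rng, period2_params):
        """Flat-array evaluation equals the per-record loop on a synthetic cohort."""
        from sojourn.simulate import ScenarioConfig, generate_cohort

        cfg = ScenarioConfig(n=500, params=dict(period2_params), interval=2.0,
                             horizon=10.0, lead_in=1.5, seed=99,
                             attendance=0.9)
        cohort, _ = generate_cohort(cfg)
        compiled = CompiledCohort(cohort, list(period2_params))
        naive = cohort_log_likelihood(period2_params, cohort, list(period2_params))
        fast = compiled.loglik(period2_params)
        assert fast == pytest.approx(naive, abs=1e-10 * max(1, abs(naive)))

    def test_cancer_without_feature_rejected(self):
        with pytest.raises(ValueError):
            WomanRecord(id="w0", screen_times=(2.0,), outcome=DetectionMode.INTERVAL_CANCER,
                        outcome_time=2.5)


class TestRecordValidation:
    def test_unsorted_screens(self):
        with pytest.raises(ValueError):
            WomanRecord(id="w0", screen_times=(4.0, 2.0), outcome=DetectionMode.CENSORED,
                        outcome_time=5.0)

    def test_interval_time_must_follow_last_screen(self):
        with pytest.raises(ValueError):
            WomanRecord(id="w0", screen_times=(2.0,), outcome=DetectionMode.INTERVAL_CANCER,
                        outcome_time=1.5, feature=FeatureClass.STELLATE)

    def test_duplicate_ids_rejected(self):
        recs = [
            WomanRecord(id="w0", screen_times=(), outcome=DetectionMode.CENSORED, outcome_time=5.0)
            for _ in range(2)
        ]
        with pytest.raises(ValueError):
            Cohort(recs)
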