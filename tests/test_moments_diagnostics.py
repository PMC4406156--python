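import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvnmix import (
    ScenarioSpec,
    cov_diagnostic,
    diagnose,
    mom_mixed_poisson,
    mom_poisson,
    nb_diagnostic2,
    sample_moments,
    simulate_counts,
    validate_counts,
)
from mvnmix.moments_diagnostics import diagnostic_signs


class TestSampleMoments:
    def test_known_matrix(self, toy_counts):
        m = sample_moments(toy_counts)
        assert (m.m1, m.m2, m.m11) == (2.5, 7.5, 7.0)

    def test_all_zero(self):
        m = sample_moments([[0, 0], [0, 0]])
        assert (m.m1, m.m2, m.m11) == (0.0, 0.0, 0.0)

    def test_t3_pairwise_average(self):
        m = sample_moments([[1, 2, 3]])
        assert m.m11 == pytest.approx((1 * 2 + 1 * 3 + 2 * 3) / 3)

    def test_requires_two_occasions(self):
        with pytest.raises(ValueError):
            sample_moments([[1], [2]])


class TestDiagnostics:
    def test_constant_counts_give_zero_d1(self):
        assert cov_diagnostic([[1, 1], [1, 1]]) == pytest.approx(0.0)

    def test_anticorrelated_counts(self, anticorrelated_counts):
        assert cov_diagnostic(anticorrelated_counts) == pytest.approx(-1.0)

    def test_d2_known_matrix(self, toy_counts):
        assert nb_diagnostic2(toy_counts) == pytest.approx(2.0)

    def test_d2_equals_m1_under_equal_columns(self):
        counts = [[2, 2], [0, 0], [3, 3]]
        m = sample_moments(counts)
        assert nb_diagnostic2(counts) == pytest.approx(m.m1)
        assert nb_diagnostic2(counts) > 0

    def test_d1_sampling_mean_is_p2_lambda(self):
        # Cov(Y_t, Y_u) = p^2 Var(N) = p^2 lam for Poisson abundance
        lam, p = 5.0, 0.3
        vals = [
            cov_diagnostic(simulate_counts(
                ScenarioSpec(family="poisson", lam=lam, p=p, T=2, S=20_000,
                             n_sim=1, seed=500 + r)))
            for r in range(12)
        ]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - p**2 * lam) < 3 * se

    def test_d2_over_m1_estimates_p(self):
        lam, p = 4.0, 0.35
        vals = []
        for r in range(12):
            cm = simulate_counts(ScenarioSpec(
                family="negbin", lam=lam, p=p, a=2.0, T=3, S=20_000,
                n_sim=1, seed=900 + r))
            m = sample_moments(cm)
            vals.append(nb_diagnostic2(cm) / m.m1)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - p) < 3 * se

    def test_report_flags_follow_nonpositive_rule(self, anticorrelated_counts):
        rep = diagnose(anticorrelated_counts)
        assert rep.d1_negative and rep.predicted_infinite_poisson
        rep2 = diagnose([[1, 1], [1, 1]])
        assert rep2.d1_negative  # exact zero counts as non-positive
        assert not rep2.d2_negative  # D2 = m1 = 1 > 0


class TestExactSigns:
    def test_tie_detected_exactly(self):
        # 0/1 counts with no within-site double detection: D2 is exactly zero
        counts = [[1, 0], [0, 1], [0, 0], [1, 0]]
        s1, s2 = diagnostic_signs(counts)
        assert s2 == 0
        assert s1 == -1  # m11 = 0 with detections present

    def test_all_zero_is_double_tie(self):
        assert diagnostic_signs([[0, 0], [0, 0]]) == (0, 0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_signs_agree_with_float_values_away_from_zero(self, seed):
        cm = simulate_counts(ScenarioSpec(
            family="poisson", lam=3, p=0.4, T=2, S=15, n_sim=1, seed=seed))
        s1, s2 = diagnostic_signs(cm)
        d1, d2 = cov_diagnostic(cm), nb_diagnostic2(cm)
        if abs(d1) > 1e-9:
            assert s1 == np.sign(d1)
        if abs(d2) > 1e-9:
            assert s2 == np.sign(d2)


class TestMomPoisson:
    def test_perfect_correlation(self):
        counts = [[1, 1], [3, 3], [0, 0]]
        est = mom_poisson(counts)
        assert est.p_hat == pytest.approx(1.0)
        assert est.lambda_hat == pytest.approx(np.mean(counts))

    def test_anticorrelation_flags_infinite(self, anticorrelated_counts):
        est = mom_poisson(anticorrelated_counts)
        assert est.p_hat == pytest.approx(-1.0)
        assert not est.valid and est.infinite_lambda

    def test_zero_variance_occasion_invalid(self):
        est = mom_poisson([[1, 1], [1, 2]])
        assert not est.valid
        assert any("zero variance" in r for r in est.reasons)

    def test_population_correlation_equals_p(self):
        # Var(Y) = p*lam, Cov = p^2*lam, so Corr = p exactly for Poisson mixing
        lam, p = 5.0, 0.25
        vals = [
            mom_poisson(simulate_counts(ScenarioSpec(
                family="poisson", lam=lam, p=p, T=2, S=10_000,
                n_sim=1, seed=300 + r))).p_hat
            for r in range(12)
        ]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - p) < 3 * se


class TestMomMixedPoisson:
    def test_known_matrix(self, toy_counts):
        est = mom_mixed_poisson(toy_counts)
        assert est.p_hat == pytest.approx(0.8)
        assert est.lambda_hat == pytest.approx(3.125)
        assert est.sigma2_hat < 0 and est.a_hat is None
        assert any("Poisson-compatible" in r for r in est.reasons)

    def test_no_detections_invalid(self):
        est = mom_mixed_poisson([[0, 0], [0, 0]])
        assert not est.valid and not est.infinite_lambda

    def test_d2_nonpositive_flags_infinite(self, anticorrelated_counts):
        est = mom_mixed_poisson(anticorrelated_counts)
        assert est.infinite_lambda and np.isinf(est.lambda_hat)

    def test_parameter_recovery(self):
        lam, a, p = 5.0, 2.0, 0.4
        ests = [
            mom_mixed_poisson(simulate_counts(ScenarioSpec(
                family="negbin", lam=lam, p=p, a=a, T=3, S=30_000,
                n_sim=1, seed=700 + r)))
            for r in range(10)
        ]
        for attr, truth in (("p_hat", p), ("lambda_hat", lam), ("a_hat", a)):
            vals = [getattr(e, attr) for e in ests]
            se = np.std(vals, ddof=1) / np.sqrt(len(vals))
            assert abs(np.mean(vals) - truth) < 3 * se

    def test_bias_shrinks_with_sites(self):
        lam, a, p = 5.0, 2.0, 0.4
        bias = {}
        for S in (100, 1000, 10_000):
            vals = [
                mom_mixed_poisson(simulate_counts(ScenarioSpec(
                    family="negbin", lam=lam, p=p, a=a, T=3, S=S,
                    n_sim=1, seed=40 + r))).p_hat
                for r in range(15)
            ]
            bias[S] = abs(np.mean(vals) - p)
        assert bias[10_000] < bias[100] + 0.02  # monotone within MC noise

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_cauchy_schwarz_upper_bound(self, seed):
        cm = simulate_counts(ScenarioSpec(
            family="negbin", lam=4, p=0.3, a=1.5, T=3, S=30, n_sim=1, seed=seed))
        m = sample_moments(cm)
        assert m.m2 >= m.m11 - 1e-9  # implied p_hat <= 1
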