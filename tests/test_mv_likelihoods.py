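import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from mvnmix import (
    DatasetCache,
    ModelParams,
    ScenarioSpec,
    bivariate_pois_pmf,
    dataset_loglik,
    mvnb_pmf,
    mvpois_pmf,
    simulate_counts,
    validate_counts,
    zip_pmf,
)


def mixture_pmf_oracle(y, mix_pmf, p, K):
    """Direct truncated N-mixture sum: sum_N f(N) prod_t Bin(y_t; N, p)."""
    N = np.arange(K + 1)
    val = mix_pmf(N)
    for yt in y:
        val = val * stats.binom.pmf(yt, N, p)
    return float(val.sum())


class TestBivariatePoisson:
    def test_zero_vector(self):
        lam, p = 1.0, 0.5
        assert bivariate_pois_pmf(0, 0, lam, p) == pytest.approx(np.exp(-0.75))

    def test_one_one_closed_form(self):
        # exp(-0.75) * (theta1*theta2 + theta12) with theta1=theta2=0.25, theta12=0.25
        assert bivariate_pois_pmf(1, 1, 1.0, 0.5) == pytest.approx(
            np.exp(-0.75) * 0.3125
        )

    @pytest.mark.parametrize("lam", [0.5, 2.0, 7.5])
    @pytest.mark.parametrize("p", [0.05, 0.4, 0.9])
    def test_identical_to_multivariate_form(self, lam, p):
        for y1, y2 in itertools.product(range(5), range(5)):
            assert bivariate_pois_pmf(y1, y2, lam, p) == pytest.approx(
                mvpois_pmf([y1, y2], lam, p), rel=1e-12
            )


class TestMultivariatePoisson:
    def test_zero_vector_closed_form(self):
        assert mvpois_pmf([0, 0], 1.0, 0.5) == pytest.approx(np.exp(-0.75))

    def test_single_detection(self):
        assert mvpois_pmf([1, 0], 1.0, 0.5) == pytest.approx(0.25 * np.exp(-0.75))

    @pytest.mark.parametrize("T", [2, 3])
    @pytest.mark.parametrize("lam, p", [(2.0, 0.25), (5.0, 0.1), (1.0, 0.6)])
    def test_matches_truncated_mixture_oracle(self, T, lam, p):
        oracle = lambda y: mixture_pmf_oracle(
            y, lambda N: stats.poisson.pmf(N, lam), p, K=500
        )
        for y in itertools.product(range(3), repeat=T):
            assert mvpois_pmf(list(y), lam, p) == pytest.approx(
                oracle(y), rel=1e-10
            )

    def test_near_independence_for_small_p(self):
        # as p -> 0 at fixed p*lam the visits decouple into independent
        # thinned Poissons
        p, mean = 1e-4, 1.0
        lam = mean / p
        joint = mvpois_pmf([2, 3], lam, p)
        indep = stats.poisson.pmf(2, mean) * stats.poisson.pmf(3, mean)
        assert joint == pytest.approx(indep, rel=5e-3)

    def test_normalization_via_tail_bound(self):
        lam, p, ymax = 2.0, 0.4, 30
        total = sum(
            bivariate_pois_pmf(y1, y2, lam, p)
            for y1 in range(ymax + 1)
            for y2 in range(ymax + 1)
        )
        assert 1 - stats.poisson.sf(ymax, lam) - 1e-9 <= total <= 1 + 1e-9


class TestMultivariateNegbin:
    def test_t1_thinned_negbin_closed_form(self):
        lam, a, p, y = 3.0, 2.0, 0.4, 4
        b = a / lam
        expected = np.exp(
            y * np.log(p) - gammaln(y + 1) + gammaln(a + y) - gammaln(a)
            + a * np.log(b) - (a + y) * np.log(b + p)
        )
        assert mvnb_pmf([y], lam, a, p) == pytest.approx(float(expected), rel=1e-12)

    @pytest.mark.parametrize("T", [2, 3])
    @pytest.mark.parametrize("lam, a, p", [(2.0, 5.0, 0.25), (5.0, 1.25, 0.1)])
    def test_matches_truncated_mixture_oracle(self, T, lam, a, p):
        b = a / lam
        oracle = lambda y: mixture_pmf_oracle(
            y, lambda N: stats.nbinom.pmf(N, a, b / (1 + b)), p, K=1000
        )
        for y in itertools.product(range(3), repeat=T):
            assert mvnb_pmf(list(y), lam, a, p) == pytest.approx(oracle(y), rel=1e-10)

    @pytest.mark.parametrize("y", [(0, 0), (1, 2), (3, 1)])
    @pytest.mark.parametrize("lam, p", [(1.0, 0.5), (4.0, 0.2)])
    def test_poisson_limit_large_shape(self, y, lam, p):
        assert mvnb_pmf(list(y), lam, 1e6, p) == pytest.approx(
            mvpois_pmf(list(y), lam, p), rel=1e-4
        )

    def test_normalization_via_tail_bound(self):
        lam, a, p, ymax = 2.0, 1.5, 0.4, 60
        b = a / lam
        total = sum(
            mvnb_pmf([y1, y2], lam, a, p)
            for y1 in range(ymax + 1)
            for y2 in range(ymax + 1)
        )
        assert 1 - stats.nbinom.sf(ymax, a, b / (1 + b)) - 1e-9 <= total <= 1 + 1e-9


class TestZeroInflatedPoisson:
    def test_reduces_to_poisson_at_zero_mass(self):
        assert zip_pmf([1, 2], 2.0, 0.3, 0.0) == pytest.approx(
            mvpois_pmf([1, 2], 2.0, 0.3), rel=1e-12
        )

    def test_zero_vector_mixture_mass(self):
        lam, p, psi, T = 2.0, 0.3, 0.4, 3
        expected = psi + (1 - psi) * np.exp(-lam * (1 - (1 - p) ** T))
        assert zip_pmf([0, 0, 0], lam, p, psi) == pytest.approx(expected, rel=1e-12)

    def test_nonzero_count_scales_poisson_mass(self):
        assert zip_pmf([1, 1], 1.0, 0.5, 0.3) == pytest.approx(
            0.7 * bivariate_pois_pmf(1, 1, 1.0, 0.5), rel=1e-12
        )


class TestDatasetLoglik:
    def test_single_zero_site(self):
        ll = dataset_loglik([[0, 0]], ModelParams(lam=1.0, p=0.5), "poisson")
        assert ll == pytest.approx(-0.75)

    @pytest.mark.parametrize("family, params", [
        ("poisson", ModelParams(lam=2.0, p=0.3)),
        ("negbin", ModelParams(lam=2.0, p=0.3, a=1.5)),
        ("zip", ModelParams(lam=2.0, p=0.3, psi=0.2)),
    ])
    def test_identical_sites_scale_linearly(self, family, params):
        single = dataset_loglik([[2, 1]], params, family)
        repeated = dataset_loglik([[2, 1]] * 7, params, family)
        assert repeated == pytest.approx(7 * single, rel=1e-12)

    def test_cache_reuse_matches_direct(self):
        cm = simulate_counts(
            ScenarioSpec(family="poisson", lam=3, p=0.4, T=3, S=50, n_sim=1, seed=7)
        )
        cache = DatasetCache(validate_counts(cm))
        params = ModelParams(lam=2.5, p=0.35)
        assert cache.loglik(params, "poisson") == pytest.approx(
            dataset_loglik(cm, params, "poisson"), rel=1e-12
        )

    def test_simulated_marginal_mean(self):
        # E(Y_t) = p * lam under every mixing family
        spec = ScenarioSpec(family="poisson", lam=4, p=0.3, T=2, S=200_000,
                            n_sim=1, seed=99)
        y = simulate_counts(spec).counts
        se = y.std() / np.sqrt(y.size)
        assert abs(y.mean() - 1.2) < 3 * se
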