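"""Beta-binomial pmf, mixture likelihood, reparameterization and priors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import gammaln

from betacall import (
    AlleleCount,
    ComponentParams,
    MixtureParams,
    PriorSpec,
    betabin_logpmf,
    log_prior,
    mixture_loglik,
    reparam_from_ab,
    reparam_to_ab,
)


def make_params(theta, mu, kappa):
    return MixtureParams(
        theta=np.asarray(theta, float),
        components=ComponentParams(mu=np.asarray(mu, float), kappa=np.asarray(kappa, float)),
    )


class TestBetabinLogpmf:
    def test_empty_observation_has_probability_one(self):
        assert betabin_logpmf(0, 0, 0.3, 7.0) == 0.0

    def test_alpha_beta_one_gives_discrete_uniform(self):
        # mu=0.5, kappa=2 -> alpha=beta=1 -> uniform on 0..n
        for k in range(11):
            assert betabin_logpmf(k, 10, 0.5, 2.0) == pytest.approx(math.log(1 / 11))

    def test_matches_direct_beta_function_evaluation(self):
        # C(10,3) * B(3+2, 7+2) / B(2,2) for mu=0.5, kappa=4
        from scipy.special import beta as beta_fn, comb

        expected = math.log(comb(10, 3, exact=True) * beta_fn(5, 9) / beta_fn(2, 2))
        assert betabin_logpmf(3, 10, 0.5, 4.0) == pytest.approx(expected, abs=1e-10)

    def test_matches_scipy_betabinom(self):
        mu, kappa = 0.37, 13.0
        ref = stats.betabinom.logpmf(np.arange(26), 25, mu * kappa, (1 - mu) * kappa)
        ours = betabin_logpmf(np.arange(26), 25, mu, kappa)
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    @given(
        mu=st.floats(0.01, 0.99),
        kappa=st.floats(0.1, 1e4),
        n=st.integers(0, 200),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pmf_normalizes(self, mu, kappa, n):
        total = np.exp(betabin_logpmf(np.arange(n + 1), n, mu, kappa)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    @given(
        mu=st.floats(0.05, 0.95),
        kappa=st.floats(0.5, 1e3),
        n=st.integers(1, 100),
        k_frac=st.floats(0, 1),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_allele_swap_symmetry(self, mu, kappa, n, k_frac):
        k = int(round(k_frac * n))
        assert betabin_logpmf(k, n, mu, kappa) == pytest.approx(
            betabin_logpmf(n - k, n, 1.0 - mu, kappa), rel=1e-9, abs=1e-9
        )

    def test_binomial_limit_at_large_concentration(self):
        for n, mu in [(50, 0.3), (100, 0.73)]:
            ours = np.exp(betabin_logpmf(np.arange(n + 1), n, mu, 1e8))
            ref = stats.binom.pmf(np.arange(n + 1), n, mu)
            assert np.max(np.abs(ours - ref)) < 1e-6

    def test_overdispersion_exceeds_binomial_variance(self):
        # MC moments: mean ~ n*mu, variance above binomial for finite kappa
        rng = np.random.default_rng(5)
        n, mu, kappa = 40, 0.4, 8.0
        p = rng.beta(mu * kappa, (1 - mu) * kappa, size=20000)
        draws = rng.binomial(n, p)
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - n * mu) < 4 * se
        assert draws.var() > n * mu * (1 - mu)

    def test_no_overflow_at_extreme_depth(self):
        val = betabin_logpmf(500_000, 1_000_000, 0.5, 50.0)
        assert np.isfinite(val)

    def test_domain_errors_name_the_argument(self):
        with pytest.raises(ValueError, match="n_alt"):
            betabin_logpmf(11, 10, 0.5, 1.0)
        with pytest.raises(ValueError, match="mu"):
            betabin_logpmf(1, 10, 1.5, 1.0)
        with pytest.raises(ValueError, match="kappa"):
            betabin_logpmf(1, 10, 0.5, -1.0)


class TestMixtureLoglik:
    def test_degenerate_mixture_reduces_to_single_component(self):
        counts = [AlleleCount(f"s{i}", k, 20) for i, k in enumerate([0, 1, 3, 10])]
        params = make_params([1.0, 0.0, 0.0], [0.01, 0.5, 0.99], [100.0, 20.0, 100.0])
        expected = sum(betabin_logpmf(c.n_alt, c.n_total, 0.01, 100.0) for c in counts)
        assert mixture_loglik(counts, params) == pytest.approx(expected, abs=1e-10)

    def test_zero_depth_site_contributes_nothing(self):
        params = make_params([0.3, 0.3, 0.4], [0.01, 0.5, 0.99], [100.0, 20.0, 100.0])
        base = [AlleleCount("a", 5, 10)]
        with_empty = base + [AlleleCount("b", 0, 0)]
        assert mixture_loglik(with_empty, params) == pytest.approx(
            mixture_loglik(base, params), abs=1e-12
        )

    def test_matches_bruteforce_per_site_sum(self):
        # plain (non-log) three-term mixture sum, 5 hand-picked sites
        counts = [
            AlleleCount("s1", 0, 12),
            AlleleCount("s2", 6, 13),
            AlleleCount("s3", 14, 14),
            AlleleCount("s4", 2, 30),
            AlleleCount("s5", 1, 1),
        ]
        theta = [0.55, 0.3, 0.15]
        mu = [0.004, 0.47, 0.996]
        kappa = [300.0, 15.0, 300.0]
        expected = 0.0
        for c in counts:
            site = sum(
                theta[g]
                * math.exp(betabin_logpmf(c.n_alt, c.n_total, mu[g], kappa[g]))
                for g in range(3)
            )
            expected += math.log(site)
        got = mixture_loglik(counts, make_params(theta, mu, kappa))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_site_order_invariance(self):
        rng = np.random.default_rng(3)
        counts = [
            AlleleCount(f"s{i}", int(rng.integers(0, 21)), 20) for i in range(50)
        ]
        params = make_params([0.5, 0.3, 0.2], [0.01, 0.5, 0.99], [100.0, 20.0, 100.0])
        a = mixture_loglik(counts, params)
        b = mixture_loglik(counts[::-1], params)
        assert a == pytest.approx(b, abs=1e-12)

    def test_empty_counts_rejected(self):
        params = make_params([0.5, 0.3, 0.2], [0.01, 0.5, 0.99], [100.0, 20.0, 100.0])
        with pytest.raises(ValueError):
            mixture_loglik([], params)


class TestReparam:
    def test_printed_hyperparameter_arithmetic(self):
        mu, lam = reparam_from_ab(10.0, 10.0)
        assert (mu, lam) == (0.5, pytest.approx(1 / 21))
        mu, lam = reparam_from_ab(1.0, 499.0)
        assert (mu, lam) == (pytest.approx(0.002), pytest.approx(1 / 501))

    @given(mu=st.floats(1e-6, 1 - 1e-6), lam=st.floats(1e-6, 1 - 1e-6))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip_identity(self, mu, lam):
        a, b = reparam_to_ab(mu, lam)
        mu2, lam2 = reparam_from_ab(a, b)
        assert mu2 == pytest.approx(mu, rel=1e-12)
        assert lam2 == pytest.approx(lam, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            reparam_from_ab(-1.0, 2.0)
        with pytest.raises(ValueError):
            reparam_to_ab(0.5, 1.5)


class TestLogPrior:
    def test_flat_dirichlet_term_is_log_two(self):
        # Dirichlet(1,1,1) density is Gamma(3) = 2 on the whole 2-simplex;
        # isolate it by differencing two theta values at fixed components.
        priors = PriorSpec()
        comp = dict(mu=[0.002, 0.5, 0.998], kappa=[500.0, 20.0, 500.0])
        lp1 = log_prior(make_params([0.2, 0.5, 0.3], **comp), priors)
        lp2 = log_prior(make_params([0.7, 0.1, 0.2], **comp), priors)
        assert lp1 == pytest.approx(lp2, abs=1e-10)
        # and the absolute theta contribution is log 2
        mu = np.array([0.002, 0.5, 0.998])
        kap = np.array([500.0, 20.0, 500.0])
        beta_terms = sum(
            stats.beta.logpdf(mu[g], priors.alpha_hyper[g], priors.beta_hyper[g])
            for g in range(3)
        )
        gamma_terms = sum(
            stats.gamma.logpdf(kap[g], priors.gamma_shape[g]) for g in range(3)
        )
        assert lp1 - beta_terms - gamma_terms == pytest.approx(math.log(2), abs=1e-10)

    def test_mu_term_matches_beta_density_oracle(self):
        priors = PriorSpec()
        base = log_prior(
            make_params([1 / 3, 1 / 3, 1 / 3], [0.002, 0.5, 0.998], [500.0, 20.0, 500.0]),
            priors,
        )
        moved = log_prior(
            make_params([1 / 3, 1 / 3, 1 / 3], [0.002, 0.45, 0.998], [500.0, 20.0, 500.0]),
            priors,
        )
        # independent density evaluation via log-gamma algebra, Beta(10, 10)
        def beta_logpdf(x, a, b):
            return (
                (a - 1) * math.log(x)
                + (b - 1) * math.log1p(-x)
                + gammaln(a + b)
                - gammaln(a)
                - gammaln(b)
            )

        assert moved - base == pytest.approx(
            beta_logpdf(0.45, 10, 10) - beta_logpdf(0.5, 10, 10), abs=1e-9
        )

    def test_kappa_term_matches_gamma_density_oracle(self):
        priors = PriorSpec()
        base = log_prior(
            make_params([1 / 3, 1 / 3, 1 / 3], [0.002, 0.5, 0.998], [500.0, 20.0, 500.0]),
            priors,
        )
        moved = log_prior(
            make_params([1 / 3, 1 / 3, 1 / 3], [0.002, 0.5, 0.998], [450.0, 20.0, 500.0]),
            priors,
        )

        def gamma_logpdf(x, shape):  # rate 1
            return (shape - 1) * math.log(x) - x - gammaln(shape)

        assert moved - base == pytest.approx(
            gamma_logpdf(450.0, 500.0) - gamma_logpdf(500.0, 500.0), abs=1e-9
        )

    def test_boundary_returns_neg_infinity(self):
        priors = PriorSpec(dirichlet_conc=np.array([2.0, 2.0, 2.0]))
        params = make_params([0.0, 0.5, 0.5], [0.002, 0.5, 0.998], [500.0, 20.0, 500.0])
        assert log_prior(params, priors) == -math.inf


class TestDomainTypes:
    def test_allele_count_invariants(self):
        with pytest.raises(ValueError):
            AlleleCount("x", 5, 3)
        with pytest.raises(ValueError):
            AlleleCount("x", -1, 3)

    def test_component_params_require_ascending_mu(self):
        with pytest.raises(ValueError, match="ascending"):
            ComponentParams(mu=np.array([0.5, 0.2, 0.9]), kappa=np.ones(3))

    def test_mixture_weights_must_be_simplex(self):
        comp = ComponentParams(mu=np.array([0.1, 0.5, 0.9]), kappa=np.ones(3))
        with pytest.raises(ValueError):
            MixtureParams(theta=np.array([0.5, 0.4, 0.4]), components=comp)

    def test_lambda_is_derived_from_concentration(self):
        comp = ComponentParams(
            mu=np.array([0.002, 0.5, 0.998]), kappa=np.array([500.0, 20.0, 500.0])
        )
        np.testing.assert_allclose(comp.lambda_overdisp, 1 / (1 + comp.kappa))
        np.testing.assert_allclose(comp.alpha + comp.beta, comp.kappa)
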