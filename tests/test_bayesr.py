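import itertools

import numpy as np
import pytest
from scipy import integrate, stats

from beefq.bayesr import (
    BayesRConfig,
    RankDeficientDesignError,
    fit_bayesr,
    heritability_summary,
    pip,
    snp_component_posterior,
)
from beefq.simulate import PhenotypeDesign, simulate_cohort


def quadrature_component_posterior(y, z, sigma_g2, sigma_e2, pi,
                                   gamma=(0.0, 1e-4, 1e-3, 1e-2)):
    """Independent oracle: component posterior for a single-SNP model by
    numerical integration of the effect out of the Gaussian likelihood."""
    like = []
    for k, g_k in enumerate(gamma):
        v = g_k * sigma_g2
        if v == 0:
            ml = np.prod(stats.norm.pdf(y, 0.0, np.sqrt(sigma_e2)))
        else:
            sd = np.sqrt(v)

            def integrand(b):
                return (
                    np.prod(stats.norm.pdf(y - z * b, 0.0, np.sqrt(sigma_e2)))
                    * stats.norm.pdf(b, 0.0, sd)
                )

            ml, _ = integrate.quad(integrand, -12 * sd, 12 * sd,
                                   epsabs=1e-16, epsrel=1e-13, limit=400)
        like.append(pi[k] * ml)
    like = np.asarray(like)
    return like / like.sum()


def enumeration_pip(y, Zc, sigma_g2, sigma_e2, pi,
                    gamma=(0.0, 1e-4, 1e-3, 1e-2)):
    """Exhaustive oracle over all 4^m indicator configurations: closed-form
    Gaussian marginal likelihood N(y; 0, Z V Z' + sigma_e2 I) per
    configuration, weighted by the mixture prior."""
    n, m = Zc.shape
    weights = []
    configs = list(itertools.product(range(4), repeat=m))
    for ks in configs:
        V = np.diag([gamma[k] * sigma_g2 for k in ks])
        cov = Zc @ V @ Zc.T + sigma_e2 * np.eye(n)
        logw = stats.multivariate_normal.logpdf(y, mean=np.zeros(n), cov=cov)
        logw += sum(np.log(pi[k]) for k in ks)
        weights.append(logw)
    w = np.exp(np.asarray(weights) - max(weights))
    w /= w.sum()
    pips = np.zeros(m)
    for wi, ks in zip(w, configs):
        for j, k in enumerate(ks):
            if k > 0:
                pips[j] += wi
    return pips


class TestConfig:
    def test_retained_sample_bookkeeping(self):
        cfg = BayesRConfig()
        assert (cfg.n_iter, cfg.burn_in, cfg.thin) == (25_000, 5_000, 10)
        assert cfg.n_retained == 2_000

    def test_gamma_invariants(self):
        with pytest.raises(ValueError):
            BayesRConfig(gamma=(1e-5, 1e-4, 1e-3, 1e-2))
        with pytest.raises(ValueError):
            BayesRConfig(gamma=(0.0, 1e-3, 1e-3, 1e-2))

    def test_thinning_must_divide(self):
        with pytest.raises(ValueError):
            BayesRConfig(n_iter=1001, burn_in=500, thin=10)


class TestComponentPosterior:
    def test_monomorphic_snp_returns_prior(self):
        pi = (0.7, 0.2, 0.08, 0.02)
        out = snp_component_posterior(rhs=0.0, ztz=0.0, sigma_g2=1.0,
                                      sigma_e2=1.0, pi=pi)
        np.testing.assert_allclose(out, pi, atol=1e-12)

    def test_degenerate_prior_is_returned(self):
        out = snp_component_posterior(rhs=50.0, ztz=100.0, sigma_g2=2.0,
                                      sigma_e2=1.0, pi=(1, 0, 0, 0))
        np.testing.assert_allclose(out, [1, 0, 0, 0])

    def test_extreme_inputs_stay_finite(self):
        out = snp_component_posterior(rhs=1e6, ztz=1e7, sigma_g2=10.0,
                                      sigma_e2=0.5, pi=(0.25,) * 4)
        assert np.all(np.isfinite(out))
        assert out.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        z = rng.standard_normal(n)
        y = rng.standard_normal(n) + 0.3 * z
        pi = (0.6, 0.2, 0.15, 0.05)
        sigma_g2, sigma_e2 = 4.0, 1.3
        expected = quadrature_component_posterior(y, z, sigma_g2, sigma_e2, pi)
        got = snp_component_posterior(
            rhs=float(z @ y), ztz=float(z @ z),
            sigma_g2=sigma_g2, sigma_e2=sigma_e2, pi=pi,
        )
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestFitBayesR:
    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_enumeration_oracle_small_instance(self, m):
        rng = np.random.default_rng(3)
        n = 50
        Zc = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        Zc -= Zc.mean(axis=0)
        beta_true = np.array([0.0, 0.9, 0.0])[:m]
        y = Zc @ beta_true + rng.standard_normal(n)
        y -= y.mean()
        pi = (0.5, 0.2, 0.2, 0.1)
        sigma_g2, sigma_e2 = 50.0, 1.0

        oracle = enumeration_pip(y, Zc, sigma_g2, sigma_e2, pi)
        cfg = BayesRConfig(
            n_iter=21_000, burn_in=1_000, thin=1, seed=7,
            update_variances=False, update_pi=False, pi_init=pi,
            scale_genotypes=False,
        )
        post = fit_bayesr(y, np.zeros((n, 0)), Zc, cfg,
                          sigma_g2_init=sigma_g2, sigma_e2_init=sigma_e2)
        np.testing.assert_allclose(post.pip, oracle, atol=0.02)

    def test_null_simulation_low_signal(self):
        rng = np.random.default_rng(5)
        n, m = 500, 1000
        Z = rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n, m)).astype(float)
        y = rng.standard_normal(n)
        # burn-in long enough for pi to drain from its interior start to the
        # null corner (the first ~4k iterations on data of this size)
        cfg = BayesRConfig(n_iter=8_000, burn_in=3_000, thin=5, seed=1)
        post = fit_bayesr(y, np.ones((n, 1)), Z, cfg)
        assert post.h2_samples.mean() < 0.1
        assert post.pip.mean() < 0.05

    def test_large_qtl_gets_top_pip(self):
        rng = np.random.default_rng(6)
        n, m = 600, 800
        Z = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(float)
        g = np.zeros(m)
        g[123] = 1.0
        signal = Z @ g
        # single QTL explaining ~10% of phenotypic variance
        e = rng.standard_normal(n) * np.sqrt(9 * signal.var())
        y = signal + e
        cfg = BayesRConfig(n_iter=4_000, burn_in=1_000, thin=3, seed=2)
        post = fit_bayesr(y, np.ones((n, 1)), Z, cfg)
        assert post.pip.argmax() == 123
        assert post.pip[123] > 0.8

    def test_seed_determinism_bit_identical(self):
        rng = np.random.default_rng(8)
        n, m = 80, 40
        Z = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        y = rng.standard_normal(n)
        cfg = BayesRConfig(n_iter=600, burn_in=100, thin=5, seed=11)
        a = fit_bayesr(y, np.ones((n, 1)), Z, cfg)
        b = fit_bayesr(y, np.ones((n, 1)), Z, cfg)
        np.testing.assert_array_equal(a.h2_samples, b.h2_samples)
        np.testing.assert_array_equal(a.mean_g, b.mean_g)
        np.testing.assert_array_equal(a.pi_samples, b.pi_samples)

    def test_posterior_invariants(self):
        rng = np.random.default_rng(9)
        n, m = 100, 60
        Z = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        y = rng.standard_normal(n) + Z[:, 0]
        cfg = BayesRConfig(n_iter=1_000, burn_in=200, thin=2, seed=3,
                           residual_check_every=100)
        post = fit_bayesr(y, np.ones((n, 1)), Z, cfg)
        assert post.n_retained == cfg.n_retained
        assert np.all((post.pip >= 0) & (post.pip <= 1))
        np.testing.assert_allclose(post.pi_samples.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(post.pi_samples >= 0)
        assert np.all((post.h2_samples > 0) & (post.h2_samples < 1))
        mean_pi = post.mean_pi
        assert mean_pi.min() >= 0 and mean_pi.sum() == pytest.approx(1.0)

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(10)
        n = 30
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        Z = rng.binomial(2, 0.5, size=(n, 10)).astype(float)
        with pytest.raises(RankDeficientDesignError, match="dup"):
            fit_bayesr(rng.standard_normal(n), X, Z,
                       BayesRConfig(n_iter=200, burn_in=100, thin=1),
                       fixed_names=["intercept", "x", "dup"])

    def test_incomplete_phenotype_rejected(self):
        y = np.array([1.0, np.nan, 2.0])
        with pytest.raises(ValueError, match="complete"):
            fit_bayesr(y, np.ones((3, 1)), np.zeros((3, 2)),
                       BayesRConfig(n_iter=200, burn_in=100, thin=1))


class TestSummaries:
    def _tiny_posterior(self, h2_samples):
        rng = np.random.default_rng(0)
        n, m = 40, 5
        Z = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        y = rng.standard_normal(n)
        cfg = BayesRConfig(n_iter=300, burn_in=100, thin=2, seed=4)
        post = fit_bayesr(y, np.ones((n, 1)), Z, cfg)
        post.h2_samples = np.asarray(h2_samples, dtype=float)
        return post

    def test_heritability_summary_moments(self):
        post = self._tiny_posterior([0.2, 0.4])
        mean, sd = heritability_summary(post)
        assert mean == pytest.approx(0.3)
        assert sd == pytest.approx(0.1)
        post = self._tiny_posterior([0.25, 0.25, 0.25])
        assert heritability_summary(post)[1] == 0.0

    def test_pip_accessor_matches_posterior(self):
        rng = np.random.default_rng(1)
        n, m = 60, 8
        Z = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        y = Z[:, 2] * 2 + rng.standard_normal(n) * 0.3
        cfg = BayesRConfig(n_iter=600, burn_in=200, thin=2, seed=5)
        post = fit_bayesr(y, np.ones((n, 1)), Z, cfg)
        np.testing.assert_array_equal(pip(post), post.pip)
        assert post.pip[2] > 0.9  # strong simulated signal is always included
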