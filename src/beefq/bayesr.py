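"""BayesR whole-genome regression fitted by Gibbs sampling.

The model is

    y = X beta + Z g + e,      e ~ N(0, sigma_e^2 I)

where X holds the fixed effects (intercept, contemporary-group dummies and
covariates, all with flat priors) and each SNP effect g_i is drawn from a
four-component normal mixture

    g_i ~ pi_1 N(0, 0) + pi_2 N(0, 1e-4 sigma_g^2)
        + pi_3 N(0, 1e-3 sigma_g^2) + pi_4 N(0, 1e-2 sigma_g^2),

so most SNPs have exactly zero effect and a few may have moderate to large
effects. The Gibbs sampler cycles over: each fixed effect (conditional
normal), each SNP (component indicator then effect, with incremental residual
updates), the mixture proportions pi (Dirichlet), and the two variance
components (scaled inverse chi-square conditionals). The component variances
use the *currently sampled* sigma_g^2 each iteration, so they adapt as the
genetic variance is learned.

Genotype columns are centred and scaled to unit variance inside the sampler
(better mixing, and it puts the gamma scale factors on a per-SNP-variance
scale); posterior effect means are reported back on the per-allele-copy scale
so predictions use raw allele dosages. SNP heritability is computed per
retained sample from the genic variance, h^2 = var(Zg) / (var(Zg) +
sigma_e^2), by default; the variance-parameter form sigma_g^2 / (sigma_g^2 +
sigma_e^2) sits behind ``h2_from_genic=False`` (see the config notes on why
it is only calibrated in the large-marker-count regime).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._kernels import gibbs_sweep

DEFAULT_GAMMA = (0.0, 1e-4, 1e-3, 1e-2)


class DivergenceError(RuntimeError):
    pass


class RankDeficientDesignError(ValueError):
    pass


@dataclass(frozen=True)
class BayesRConfig:
    """MCMC settings for :func:`fit_bayesr`.

    Defaults follow standard practice for this model family: 25,000 Gibbs
    iterations, the first 5,000 discarded as burn-in, thinning by 10, leaving
    2,000 retained samples.
    """

    gamma: tuple = DEFAULT_GAMMA
    n_iter: int = 25_000
    burn_in: int = 5_000
    thin: int = 10
    # sparsity-favouring Dirichlet prior on the mixture proportions: at
    # moderate marker counts the 1e-4*sigma_g2 component is individually
    # undetectable, and a flat Dirichlet(1,1,1,1) lets null SNPs drift into
    # it, inflating PIPs and the genic variance; small prior counts on the
    # nonzero components keep pi near the null corner unless the data insist
    dirichlet_prior: tuple = (1.0, 0.01, 0.01, 0.01)
    # weakly informative scaled-inverse-chi-square priors: nu = 4 for both
    # variances, scales split var(y) according to an assumed h2 of 0.5
    df_variance: float = 4.0
    prior_h2: float = 0.5
    pi_init: tuple = (0.5, 0.3, 0.15, 0.05)
    seed: int = 0
    update_variances: bool = True
    update_pi: bool = True
    random_sweep: bool = False
    scale_genotypes: bool = True
    # h2 per retained sample from the genic variance var(Zg) (well identified
    # at any marker count); False uses sigma_g2/(sigma_g2+sigma_e2), whose
    # sigma_g2 only approximates the genetic variance when the effect mixture
    # allocates about 1/gamma_4 SNPs to the largest component (large-m regime)
    h2_from_genic: bool = True
    save_effect_samples: bool = False
    residual_check_every: int = 1_000
    residual_check_tol: float = 1e-8

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        if g.shape != (4,):
            raise ValueError("gamma must have 4 entries")
        if g[0] != 0.0:
            raise ValueError("gamma[0] must be exactly 0 (the null component)")
        if not np.all(np.diff(g) > 0):
            raise ValueError("gamma must be strictly increasing")
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if (self.n_iter - self.burn_in) % self.thin != 0:
            raise ValueError("(n_iter - burn_in) must be divisible by thin")
        if not 0.0 < self.prior_h2 < 1.0:
            raise ValueError("prior_h2 must lie in (0, 1)")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    def with_(self, **kwargs) -> "BayesRConfig":
        return replace(self, **kwargs)


@dataclass
class BayesRPosterior:
    """Retained samples and posterior summaries from one BayesR fit."""

    mean_g: np.ndarray          # (m,) posterior mean SNP effect, per A1 copy
    pip: np.ndarray             # (m,) P(component != null)
    mean_component: np.ndarray  # (m,) posterior mean mixture index (1-based)
    mean_beta: np.ndarray       # (p,) posterior mean fixed effects
    fixed_names: list[str]
    beta_samples: np.ndarray    # (n_retained, p)
    sigma_g2_samples: np.ndarray
    sigma_e2_samples: np.ndarray
    h2_samples: np.ndarray
    pi_samples: np.ndarray      # (n_retained, 4)
    config: BayesRConfig
    genotype_center: np.ndarray  # column means used to centre Z
    genotype_scale: np.ndarray   # column sds used to scale Z (1.0 if unscaled)
    g_samples: np.ndarray | None = None  # (n_retained, m), per-allele scale

    @property
    def n_retained(self) -> int:
        return len(self.h2_samples)

    @property
    def mean_pi(self) -> np.ndarray:
        return self.pi_samples.mean(axis=0)

    def fixed_effect(self, name: str) -> float:
        try:
            j = self.fixed_names.index(name)
        except ValueError:
            raise KeyError(f"no fixed effect named {name!r}") from None
        return float(self.mean_beta[j])


def snp_component_posterior(rhs, ztz, sigma_g2, sigma_e2, pi,
                            gamma=DEFAULT_GAMMA) -> np.ndarray:
    """Conditional posterior over the four mixture components for one SNP.

    ``rhs`` is the covariance of the SNP column with the current residual
    (with the SNP's own contribution added back) and ``ztz`` the column sum
    of squares. Probability of component k is proportional to pi_k times the
    Gaussian marginal likelihood of the residual under effect variance
    gamma_k * sigma_g2; everything is computed in log space with the maximum
    subtracted, so extreme inputs cannot overflow.
    """
    pi = np.asarray(pi, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if ztz < 0:
        raise ValueError("ztz must be non-negative")
    if sigma_e2 <= 0 or sigma_g2 <= 0:
        raise ValueError("variances must be positive")
    with np.errstate(divide="ignore"):
        logp = np.log(pi)
    v = gamma * sigma_g2
    nonzero = (v > 0) & (ztz > 0)
    logp[nonzero] += (
        -0.5 * np.log1p(ztz * v[nonzero] / sigma_e2)
        + 0.5 * rhs * rhs * v[nonzero]
        / (sigma_e2 * (sigma_e2 + ztz * v[nonzero]))
    )
    logp -= logp.max()
    w = np.exp(logp)
    return w / w.sum()


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[1] == 0:
        return
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name the columns involved in the collinearity via QR pivoting
        _, Rm = np.linalg.qr(X)
        diag = np.abs(np.diag(Rm))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[j] for j in np.where(diag <= tol)[0]]
        raise RankDeficientDesignError(
            f"fixed design is rank deficient (rank {r} < {X.shape[1]}); "
            f"collinear columns include: {bad or 'unidentified'}"
        )


def fit_bayesr(
    y: np.ndarray,
    fixed_design: np.ndarray,
    Z: np.ndarray,
    config: BayesRConfig,
    fixed_names: list[str] | None = None,
    sigma_g2_init: float | None = None,
    sigma_e2_init: float | None = None,
) -> BayesRPosterior:
    """Fit the BayesR model by Gibbs sampling.

    Parameters
    ----------
    y
        Complete phenotype vector for the training animals.
    fixed_design
        (n, p) fixed-effect design, full column rank (drop one contemporary
        group level before calling). May have zero columns.
    Z
        (n, m) complete allele-dosage matrix (0..2 scale; centring/scaling is
        handled internally).
    config
        MCMC settings; ``config.seed`` drives all randomness.
    sigma_g2_init, sigma_e2_init
        Starting values; with ``update_variances=False`` they are held fixed
        for the whole chain (used by the enumeration-oracle checks).
    """
    y = np.ascontiguousarray(y, dtype=np.float64)
    X = np.asarray(fixed_design, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    Z = np.asarray(Z, dtype=np.float64)
    n = y.shape[0]
    if X.shape[0] != n or Z.shape[0] != n:
        raise ValueError("y, fixed_design and Z must agree on animal count")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be complete (drop unphenotyped animals first)")
    m = Z.shape[1]
    p = X.shape[1]
    if fixed_names is None:
        fixed_names = [f"x{j}" for j in range(p)]
    _check_full_rank(X, fixed_names)

    center = Z.mean(axis=0)
    sd = Z.std(axis=0)
    if config.scale_genotypes:
        scale = np.where(sd > 0, sd, 1.0)
    else:
        scale = np.ones(m)
    Zw = (Z - center) / scale
    Zt = np.ascontiguousarray(Zw.T)
    ztz = np.einsum("ij,ij->i", Zt, Zt)
    Xt = np.ascontiguousarray(X.T)
    xtx = np.einsum("ij,ij->i", Xt, Xt) if p else np.zeros(0)

    rng = np.random.default_rng(config.seed)
    gamma = np.asarray(config.gamma, dtype=np.float64)
    var_y = float(np.var(y)) if np.var(y) > 0 else 1.0
    nu0 = config.df_variance
    s0_g = config.prior_h2 * var_y
    s0_e = (1.0 - config.prior_h2) * var_y

    sigma_g2 = float(sigma_g2_init) if sigma_g2_init is not None else s0_g
    sigma_e2 = float(sigma_e2_init) if sigma_e2_init is not None else s0_e
    pi = np.asarray(config.pi_init, dtype=np.float64)
    pi = pi / pi.sum()

    beta = np.zeros(p)
    g = np.zeros(m)
    comp = np.zeros(m, dtype=np.int64)
    resid = y.copy()
    alpha0 = np.asarray(config.dirichlet_prior, dtype=np.float64)

    n_ret = config.n_retained
    sigma_g2_s = np.empty(n_ret)
    sigma_e2_s = np.empty(n_ret)
    h2_s = np.empty(n_ret)
    pi_s = np.empty((n_ret, 4))
    beta_s = np.empty((n_ret, p))
    g_sum = np.zeros(m)
    comp_sum = np.zeros(m)
    nonzero_count = np.zeros(m, dtype=np.int64)
    g_store = np.empty((n_ret, m)) if config.save_effect_samples else None

    base_order = np.arange(m, dtype=np.int64)
    kept = 0
    for it in range(config.n_iter):
        order = rng.permutation(m) if config.random_sweep else base_order
        beta_normals = rng.standard_normal(p)
        snp_uniforms = rng.random(m)
        snp_normals = rng.standard_normal(m)
        counts, ssq_scaled = gibbs_sweep(
            Xt, xtx, Zt, ztz, beta, g, comp, resid,
            np.log(pi), gamma, sigma_g2, sigma_e2,
            beta_normals, snp_uniforms, snp_normals, order,
        )

        if config.update_pi:
            pi = rng.dirichlet(alpha0 + counts)
            # guard against exact zeros from the gamma sampler at tiny alpha
            if np.any(pi <= 0):
                pi = np.clip(pi, 1e-12, None)
                pi /= pi.sum()

        if config.update_variances:
            q = int(counts[1:].sum())
            sigma_g2 = (nu0 * s0_g + ssq_scaled) / rng.chisquare(nu0 + q)
            sse = float(resid @ resid)
            sigma_e2 = (nu0 * s0_e + sse) / rng.chisquare(nu0 + n)

        if not np.isfinite(resid).all():
            raise DivergenceError(f"non-finite residual at iteration {it}")
        if (it + 1) % config.residual_check_every == 0:
            recomputed = y - X @ beta - Zw @ g
            if np.max(np.abs(recomputed - resid)) > config.residual_check_tol * (
                1.0 + np.max(np.abs(y))
            ):
                raise DivergenceError(
                    f"incremental residual drifted at iteration {it}"
                )
            resid = recomputed

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            sigma_g2_s[kept] = sigma_g2
            sigma_e2_s[kept] = sigma_e2
            if config.h2_from_genic:
                var_g = float(np.var(Zw @ g))
                h2_s[kept] = var_g / (var_g + sigma_e2)
            else:
                h2_s[kept] = sigma_g2 / (sigma_g2 + sigma_e2)
            pi_s[kept] = pi
            beta_s[kept] = beta
            g_allele = g / scale
            g_sum += g_allele
            comp_sum += comp
            nonzero_count += comp > 0
            if g_store is not None:
                g_store[kept] = g_allele
            kept += 1

    assert kept == n_ret
    return BayesRPosterior(
        mean_g=g_sum / n_ret,
        pip=nonzero_count / n_ret,
        mean_component=comp_sum / n_ret + 1.0,
        mean_beta=beta_s.mean(axis=0) if p else np.zeros(0),
        fixed_names=list(fixed_names),
        beta_samples=beta_s,
        sigma_g2_samples=sigma_g2_s,
        sigma_e2_samples=sigma_e2_s,
        h2_samples=h2_s,
        pi_samples=pi_s,
        config=config,
        genotype_center=center,
        genotype_scale=scale,
        g_samples=g_store,
    )


def heritability_summary(posterior: BayesRPosterior) -> tuple[float, float]:
    """Posterior mean and SD of SNP heritability."""
    h2 = posterior.h2_samples
    if len(h2) < 2:
        raise ValueError("need at least 2 retained samples")
    return float(h2.mean()), float(h2.std(ddof=0))


def pip(posterior: BayesRPosterior) -> np.ndarray:
    """Per-SNP posterior inclusion probability (fraction of retained samples
    with the SNP in a nonzero mixture component)."""
    return posterior.pip
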