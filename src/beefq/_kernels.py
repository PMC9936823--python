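"""Numba inner loops for the BayesR Gibbs sampler.

All randomness enters through pre-drawn arrays (one uniform and one standard
normal per SNP, one standard normal per fixed effect), so the kernels are
deterministic given their inputs and the full chain is reproducible from the
driver's single numpy Generator.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_sweep(
    Xt,            # (p, n) fixed design, rows contiguous
    xtx,           # (p,) column sums of squares
    Zt,            # (m, n) genotype design, rows contiguous
    ztz,           # (m,)
    beta,          # (p,) current fixed effects, updated in place
    g,             # (m,) current SNP effects, updated in place
    comp,          # (m,) current component index 0..3, updated in place
    resid,         # (n,) y - X beta - Z g, updated in place
    log_pi,        # (4,)
    gamma,         # (4,) variance scale factors, gamma[0] == 0
    sigma_g2,
    sigma_e2,
    beta_normals,  # (p,)
    snp_uniforms,  # (m,)
    snp_normals,   # (m,)
    order,         # (m,) SNP visit order
):
    """One full Gibbs sweep over fixed effects then SNPs (residual updated
    incrementally). Returns the per-component SNP counts and the sum of
    g_i^2 / gamma_{k_i} over SNPs in nonzero components (the sufficient
    statistic for the genetic-variance update)."""
    p = Xt.shape[0]
    m = Zt.shape[0]
    n = resid.shape[0]

    for j in range(p):
        if xtx[j] <= 0.0:
            continue
        rhs = xtx[j] * beta[j]
        for i in range(n):
            rhs += Xt[j, i] * resid[i]
        new = rhs / xtx[j] + beta_normals[j] * np.sqrt(sigma_e2 / xtx[j])
        diff = beta[j] - new
        if diff != 0.0:
            for i in range(n):
                resid[i] += Xt[j, i] * diff
        beta[j] = new

    counts = np.zeros(4, dtype=np.int64)
    ssq_scaled = 0.0
    logp = np.empty(4)
    for t in range(m):
        s = order[t]
        zs = Zt[s]
        rhs = ztz[s] * g[s]
        for i in range(n):
            rhs += zs[i] * resid[i]

        logp[0] = log_pi[0]
        for k in range(1, 4):
            v = gamma[k] * sigma_g2
            if ztz[s] <= 0.0 or v <= 0.0:
                logp[k] = log_pi[k]
            else:
                logp[k] = (
                    log_pi[k]
                    - 0.5 * np.log(1.0 + ztz[s] * v / sigma_e2)
                    + 0.5 * rhs * rhs * v / (sigma_e2 * (sigma_e2 + ztz[s] * v))
                )
        mx = logp[0]
        for k in range(1, 4):
            if logp[k] > mx:
                mx = logp[k]
        total = 0.0
        for k in range(4):
            logp[k] = np.exp(logp[k] - mx)
            total += logp[k]
        u = snp_uniforms[t] * total
        acc = 0.0
        k_new = 3
        for k in range(4):
            acc += logp[k]
            if u <= acc:
                k_new = k
                break

        if k_new == 0:
            g_new = 0.0
        else:
            v = gamma[k_new] * sigma_g2
            c = ztz[s] + sigma_e2 / v
            g_new = rhs / c + snp_normals[t] * np.sqrt(sigma_e2 / c)
            ssq_scaled += g_new * g_new / gamma[k_new]
        diff = g[s] - g_new
        if diff != 0.0:
            for i in range(n):
                resid[i] += zs[i] * diff
        g[s] = g_new
        comp[s] = k_new
        counts[k_new] += 1

    return counts, ssq_scaled
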