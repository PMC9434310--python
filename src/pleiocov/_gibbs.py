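"""Numba kernel for the bivariate spike-and-slab Gibbs sampler.

All 2x2 linear algebra is written out explicitly; the Inverse-Wishart draw uses
the Bartlett decomposition of the corresponding Wishart.  The kernel owns its
own RNG stream (numba's MT19937), seeded once per call, so a fit is
bit-reproducible given (data, config, seed).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _inv2(A):
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if det == 0.0:
        # degenerate (e.g. duplicated traits): nudge to the nearest invertible
        jit = 1e-10 * (abs(A[0, 0]) + abs(A[1, 1]) + 1.0)
        A = A.copy()
        A[0, 0] += jit
        A[1, 1] += jit
        det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    out = np.empty((2, 2))
    out[0, 0] = A[1, 1] / det
    out[1, 1] = A[0, 0] / det
    out[0, 1] = -A[0, 1] / det
    out[1, 0] = -A[1, 0] / det
    return out


@njit(cache=True)
def _chol2(A):
    """Lower Cholesky of a 2x2 SPD matrix, with escalating jitter on failure."""
    a, b, c = A[0, 0], A[1, 0], A[1, 1]
    jitter = 0.0
    for _ in range(40):
        aa = a + jitter
        cc = c + jitter
        if aa > 0.0:
            l11 = np.sqrt(aa)
            l21 = b / l11
            s = cc - l21 * l21
            if s > 0.0:
                L = np.zeros((2, 2))
                L[0, 0] = l11
                L[1, 0] = l21
                L[1, 1] = np.sqrt(s)
                return L
        jitter = 1e-10 if jitter == 0.0 else jitter * 10.0
    L = np.zeros((2, 2))
    L[0, 0] = np.sqrt(abs(a) + 1e-12)
    L[1, 1] = np.sqrt(abs(c) + 1e-12)
    return L


@njit(cache=True)
def _rinvwishart2(df, S):
    """One draw from InverseWishart(df, scale=S), 2x2."""
    L = _chol2(_inv2(S))
    a11 = np.sqrt(np.random.chisquare(df))
    a22 = np.sqrt(np.random.chisquare(df - 1.0))
    a21 = np.random.standard_normal()
    t11 = L[0, 0] * a11
    t21 = L[1, 0] * a11 + L[1, 1] * a21
    t22 = L[1, 1] * a22
    W = np.empty((2, 2))
    W[0, 0] = t11 * t11
    W[0, 1] = t11 * t21
    W[1, 0] = W[0, 1]
    W[1, 1] = t21 * t21 + t22 * t22
    return _inv2(W)


@njit(cache=True)
def run_gibbs(
    X, Y, sxx,
    n_iter, burn_in, thin,
    R_df, R_scale, S_df, S_scale, pi_a, pi_b,
    update_mu, fix_R, fix_Sigma, fix_pi,
    seed,
    mu, b, d, R, Sig, pi,
):
    """Run ``n_iter`` full Gibbs sweeps, mutating the state arrays in place.

    Update order per iteration: mu | rest, then per-SNP (indicator, latent
    effect) trait-within-SNP with residual updating, then Sigma | latents (IW),
    R | residuals (IW), pi_k | indicator counts (Beta).  Returns the retained
    draws (beta, indicators, R, Sigma, pi, mu) after burn-in/thinning.
    """
    np.random.seed(seed)
    n, m = X.shape
    K = (n_iter - burn_in) // thin

    beta_draws = np.zeros((K, m, 2))
    d_draws = np.zeros((K, m, 2), dtype=np.uint8)
    R_draws = np.zeros((K, 2, 2))
    S_draws = np.zeros((K, 2, 2))
    pi_draws = np.zeros((K, 2))
    mu_draws = np.zeros((K, 2))

    # current residuals E = Y - 1 mu' - X beta, with beta = d * b
    e1 = np.empty(n)
    e2 = np.empty(n)
    for i in range(n):
        e1[i] = Y[i, 0] - mu[0]
        e2[i] = Y[i, 1] - mu[1]
    for j in range(m):
        b0 = b[j, 0] if d[j, 0] == 1 else 0.0
        b1 = b[j, 1] if d[j, 1] == 1 else 0.0
        if b0 != 0.0 or b1 != 0.0:
            for i in range(n):
                e1[i] -= X[i, j] * b0
                e2[i] -= X[i, j] * b1

    for t in range(n_iter):
        # --- intercepts (flat prior): mu | rest ~ N(mu + colmean(E), R/n)
        if update_mu == 1:
            s0 = 0.0
            s1 = 0.0
            for i in range(n):
                s0 += e1[i]
                s1 += e2[i]
            L = _chol2(R)
            z0 = np.random.standard_normal()
            z1 = np.random.standard_normal()
            sq = np.sqrt(n)
            new0 = mu[0] + s0 / n + L[0, 0] * z0 / sq
            new1 = mu[1] + s1 / n + (L[1, 0] * z0 + L[1, 1] * z1) / sq
            d0 = mu[0] - new0
            d1 = mu[1] - new1
            for i in range(n):
                e1[i] += d0
                e2[i] += d1
            mu[0] = new0
            mu[1] = new1

        # --- per-SNP spike-and-slab sweep with residual updating
        Ci = _inv2(R)
        for j in range(m):
            t0 = 0.0
            t1 = 0.0
            for i in range(n):
                t0 += X[i, j] * e1[i]
                t1 += X[i, j] * e2[i]
            for k in range(2):
                kk = 1 - k
                sxk = Sig[0, 1]
                vxx = Sig[kk, kk]
                if vxx < 1e-300:
                    vxx = 1e-300
                m0 = sxk / vxx * b[j, kk]
                v0 = Sig[k, k] - sxk * sxk / vxx
                if v0 < 1e-12:
                    v0 = 1e-12
                beta_old = b[j, k] if d[j, k] == 1 else 0.0
                tk = t0 if k == 0 else t1
                tx = t1 if k == 0 else t0
                zk = Ci[k, k] * (tk + beta_old * sxx[j]) + Ci[k, kk] * tx
                a = Ci[k, k] * sxx[j]
                v1 = 1.0 / (a + 1.0 / v0)
                m1 = v1 * (zk + m0 / v0)
                log_odds = (
                    np.log(pi[k]) - np.log1p(-pi[k])
                    + 0.5 * np.log(v1 / v0)
                    + 0.5 * (m1 * m1 / v1 - m0 * m0 / v0)
                )
                if log_odds > 0.0:
                    p1 = 1.0 / (1.0 + np.exp(-log_odds))
                else:
                    ex = np.exp(log_odds)
                    p1 = ex / (1.0 + ex)
                if np.random.random() < p1:
                    d[j, k] = 1
                    b[j, k] = m1 + np.sqrt(v1) * np.random.standard_normal()
                    beta_new = b[j, k]
                else:
                    # spike: observed effect 0; refresh the latent slab
                    # component from its conditional prior (keeps Sigma's
                    # Inverse-Wishart update conjugate)
                    d[j, k] = 0
                    b[j, k] = m0 + np.sqrt(v0) * np.random.standard_normal()
                    beta_new = 0.0
                delta = beta_new - beta_old
                if delta != 0.0:
                    if k == 0:
                        for i in range(n):
                            e1[i] -= delta * X[i, j]
                        t0 -= delta * sxx[j]
                    else:
                        for i in range(n):
                            e2[i] -= delta * X[i, j]
                        t1 -= delta * sxx[j]

        # --- slab covariance Sigma | latent effects
        if fix_Sigma == 0:
            s00 = S_scale[0, 0]
            s01 = S_scale[0, 1]
            s11 = S_scale[1, 1]
            for j in range(m):
                s00 += b[j, 0] * b[j, 0]
                s01 += b[j, 0] * b[j, 1]
                s11 += b[j, 1] * b[j, 1]
            Sb = np.empty((2, 2))
            Sb[0, 0] = s00
            Sb[0, 1] = s01
            Sb[1, 0] = s01
            Sb[1, 1] = s11
            Sig[:, :] = _rinvwishart2(S_df + m, Sb)

        # --- residual covariance R | residuals
        if fix_R == 0:
            r00 = R_scale[0, 0]
            r01 = R_scale[0, 1]
            r11 = R_scale[1, 1]
            for i in range(n):
                r00 += e1[i] * e1[i]
                r01 += e1[i] * e2[i]
                r11 += e2[i] * e2[i]
            Sr = np.empty((2, 2))
            Sr[0, 0] = r00
            Sr[0, 1] = r01
            Sr[1, 0] = r01
            Sr[1, 1] = r11
            R[:, :] = _rinvwishart2(R_df + n, Sr)

        # --- inclusion probabilities pi_k | indicator counts
        if fix_pi == 0:
            for k in range(2):
                nk = 0
                for j in range(m):
                    nk += d[j, k]
                pi[k] = np.random.beta(pi_a + nk, pi_b + (m - nk))

        # --- record retained draw
        it = t + 1
        if it > burn_in and (it - burn_in) % thin == 0:
            s = (it - burn_in) // thin - 1
            if s < K:
                for j in range(m):
                    for k in range(2):
                        beta_draws[s, j, k] = b[j, k] if d[j, k] == 1 else 0.0
                        d_draws[s, j, k] = d[j, k]
                R_draws[s] = R
                S_draws[s] = Sig
                pi_draws[s, 0] = pi[0]
                pi_draws[s, 1] = pi[1]
                mu_draws[s, 0] = mu[0]
                mu_draws[s, 1] = mu[1]

    return beta_draws, d_draws, R_draws, S_draws, pi_draws, mu_draws
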