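"""Bivariate multitrait regression with per-(SNP, trait) spike-and-slab effects.

The model for one chromosomal segment is

    Y = 1 mu' + X beta + E,      E_i ~ N_2(0, R)  iid over individuals,

with per-SNP effect pairs beta_j = d_j * b_j where b_j ~ N_2(0, Sigma) is a
latent bivariate slab effect, d_jk ~ Bernoulli(pi_k) are per-(SNP, trait)
inclusion indicators, R and Sigma carry Inverse-Wishart priors and each pi_k a
Beta prior.  A SNP may therefore be active for one trait only.  Posterior
draws come from a Gibbs sampler (see ``_gibbs``); burn-in and thinning follow
the chain settings in ``MTModelConfig``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from ._gibbs import run_gibbs

__all__ = [
    "MTModelConfig",
    "MTPosterior",
    "GibbsState",
    "retained_draw_count",
    "fit_segment",
    "gibbs_sweeps",
    "sample_prior",
    "draw_initial_state",
    "simulate_given_state",
]


@dataclass(eq=False)
class MTModelConfig:
    """Chain settings and priors.

    ``R_scale`` / ``Sigma_scale`` of ``None`` request data-scaled defaults at
    fit time: the Inverse-Wishart prior mode assigns half of each trait's
    sample variance to the error term, and the slab scale is set so the
    implied genomic variance covers the other half given the prior expected
    number of active SNPs (prior mean of pi times segment size).

    ``fix_R`` / ``fix_Sigma`` / ``fix_pi`` clamp a parameter block at a given
    value instead of sampling it (used for sampler validation, e.g. the
    conjugate ridge limit with ``fix_pi=(1, 1)``).  ``update_mu=False`` pins
    the intercepts at zero.
    """

    n_iter: int = 5000
    burn_in: int = 250
    thin: int = 10
    R_df: float = 5.0
    R_scale: np.ndarray | None = None
    Sigma_df: float = 5.0
    Sigma_scale: np.ndarray | None = None
    pi_a: float = 0.1
    pi_b: float = 9.9
    rng_seed: int = 0
    update_mu: bool = True
    fix_R: np.ndarray | None = None
    fix_Sigma: np.ndarray | None = None
    fix_pi: tuple | None = None

    def __post_init__(self):
        if not self.n_iter > self.burn_in >= 0:
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.R_df <= 1 or self.Sigma_df <= 1:
            raise ValueError("Inverse-Wishart df must exceed dimension - 1 = 1")
        if self.pi_a <= 0 or self.pi_b <= 0:
            raise ValueError("Beta prior parameters must be positive")
        for name in ("R_scale", "Sigma_scale", "fix_R", "fix_Sigma"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=np.float64)
                if v.shape != (2, 2) or not np.allclose(v, v.T):
                    raise ValueError(f"{name} must be a symmetric 2x2 matrix")
                setattr(self, name, v)

    @property
    def n_retained(self) -> int:
        return retained_draw_count(self.n_iter, self.burn_in, self.thin)


@dataclass(eq=False)
class MTPosterior:
    """Retained MCMC draws for one segment fit.

    ``beta_draws``: retained x m x 2 effects (trait units per allele; exactly 0
    where the matching indicator is 0).  ``R_draws`` / ``Sigma_draws`` are
    retained x 2 x 2 SPD matrices, ``pi_draws`` retained x 2 in (0, 1).
    """

    beta_draws: np.ndarray
    indicator_draws: np.ndarray
    R_draws: np.ndarray
    Sigma_draws: np.ndarray
    pi_draws: np.ndarray
    mu_draws: np.ndarray
    segment: object = None
    config: MTModelConfig | None = None

    @property
    def n_retained(self) -> int:
        return self.beta_draws.shape[0]

    def save(self, path) -> None:
        import json

        meta = {}
        if self.config is not None:
            c = self.config
            meta = {
                "n_iter": c.n_iter, "burn_in": c.burn_in, "thin": c.thin,
                "rng_seed": c.rng_seed, "pi_a": c.pi_a, "pi_b": c.pi_b,
                "R_df": c.R_df, "Sigma_df": c.Sigma_df,
                "centering": "dosages mean-imputed and mean-centered, not standardized",
            }
        np.savez_compressed(
            path,
            beta_draws=self.beta_draws,
            indicator_draws=self.indicator_draws,
            R_draws=self.R_draws,
            Sigma_draws=self.Sigma_draws,
            pi_draws=self.pi_draws,
            mu_draws=self.mu_draws,
            meta=json.dumps(meta),
        )

    @classmethod
    def load(cls, path) -> "MTPosterior":
        z = np.load(path, allow_pickle=False)
        return cls(
            beta_draws=z["beta_draws"],
            indicator_draws=z["indicator_draws"],
            R_draws=z["R_draws"],
            Sigma_draws=z["Sigma_draws"],
            pi_draws=z["pi_draws"],
            mu_draws=z["mu_draws"],
        )


@dataclass(eq=False)
class GibbsState:
    """Full sampler state, exposed for stepwise validation runs."""

    mu: np.ndarray
    b: np.ndarray       # m x 2 latent slab effects
    d: np.ndarray       # m x 2 uint8 indicators
    R: np.ndarray
    Sigma: np.ndarray
    pi: np.ndarray

    @property
    def beta(self) -> np.ndarray:
        return np.where(self.d == 1, self.b, 0.0)


def retained_draw_count(n_iter: int, burn_in: int, thin: int) -> int:
    """Number of retained draws: iterations past burn-in kept every ``thin``."""
    if not n_iter > burn_in >= 0:
        raise ValueError("need n_iter > burn_in >= 0")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    return (n_iter - burn_in) // thin


def _resolved_priors(config: MTModelConfig, X: np.ndarray, Y: np.ndarray):
    """Materialize data-scaled default prior scales (see MTModelConfig)."""
    n, m = X.shape
    vary = Y.var(axis=0, ddof=1)
    R_scale = config.R_scale
    if R_scale is None:
        # IW mode S/(df + p + 1) = half the trait variance
        R_scale = np.diag(0.5 * vary * (config.R_df + 3.0))
    S_scale = config.Sigma_scale
    if S_scale is None:
        pibar = config.pi_a / (config.pi_a + config.pi_b)
        sum_var_x = max(float((X ** 2).sum() / max(n - 1, 1)), 1e-12)
        slab_var = 0.5 * vary / (pibar * sum_var_x)
        S_scale = np.diag(slab_var * (config.Sigma_df + 3.0))
    return np.ascontiguousarray(R_scale), np.ascontiguousarray(S_scale)


def _initial_state(config: MTModelConfig, X, Y, R_scale, S_scale) -> GibbsState:
    m = X.shape[1]
    mu = Y.mean(axis=0) if config.update_mu else np.zeros(2)
    R0 = np.cov(Y, rowvar=False, ddof=1)
    Sig0 = S_scale / max(config.Sigma_df - 3.0, 1.0)
    pi0 = np.full(2, config.pi_a / (config.pi_a + config.pi_b))
    if config.fix_R is not None:
        R0 = config.fix_R.copy()
    if config.fix_Sigma is not None:
        Sig0 = config.fix_Sigma.copy()
    if config.fix_pi is not None:
        pi0 = np.asarray(config.fix_pi, dtype=np.float64).copy()
    return GibbsState(
        mu=np.asarray(mu, dtype=np.float64).copy(),
        b=np.zeros((m, 2)),
        d=np.zeros((m, 2), dtype=np.uint8),
        R=np.ascontiguousarray(R0, dtype=np.float64),
        Sigma=np.ascontiguousarray(Sig0, dtype=np.float64),
        pi=pi0,
    )


def _run(X, Y, config: MTModelConfig, state: GibbsState, n_iter, burn_in, thin, seed):
    X = np.asfortranarray(X, dtype=np.float64)
    Y = np.ascontiguousarray(Y, dtype=np.float64)
    sxx = np.ascontiguousarray((X ** 2).sum(axis=0))
    R_scale, S_scale = _resolved_priors(config, X, Y)
    return run_gibbs(
        X, Y, sxx,
        n_iter, burn_in, thin,
        float(config.R_df), R_scale, float(config.Sigma_df), S_scale,
        float(config.pi_a), float(config.pi_b),
        1 if config.update_mu else 0,
        1 if config.fix_R is not None else 0,
        1 if config.fix_Sigma is not None else 0,
        1 if config.fix_pi is not None else 0,
        int(seed),
        state.mu, state.b, state.d, state.R, state.Sigma, state.pi,
    )


def fit_segment(X_seg: np.ndarray, Y: np.ndarray, config: MTModelConfig,
                segment=None) -> MTPosterior:
    """Fit the model to one segment's centered dosages and return the retained
    posterior draws.

    ``X_seg`` holds the segment's core plus flank SNP columns (imputed and
    mean-centered); rows align with ``Y``.  The run is deterministic given
    ``config.rng_seed``.
    """
    X_seg = np.asarray(X_seg, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X_seg.ndim != 2 or Y.ndim != 2 or Y.shape[1] != 2:
        raise ValueError("X_seg must be n x m and Y must be n x 2")
    if X_seg.shape[0] != Y.shape[0]:
        raise ValueError("X_seg and Y row counts differ")
    if X_seg.shape[0] < 3:
        raise ValueError("need at least 3 individuals")
    if not np.all(np.isfinite(X_seg)) or not np.all(np.isfinite(Y)):
        raise ValueError("non-finite values in X or Y")
    if np.any(Y.var(axis=0) <= 0):
        raise ValueError("degenerate trait with zero variance")

    R_scale, S_scale = _resolved_priors(config, X_seg, Y)
    state = _initial_state(config, X_seg, Y, R_scale, S_scale)
    beta, ind, Rd, Sd, pid, mud = _run(
        X_seg, Y, config, state,
        config.n_iter, config.burn_in, config.thin, config.rng_seed,
    )
    return MTPosterior(
        beta_draws=beta, indicator_draws=ind, R_draws=Rd, Sigma_draws=Sd,
        pi_draws=pid, mu_draws=mud, segment=segment, config=config,
    )


def gibbs_sweeps(X, Y, config: MTModelConfig, state: GibbsState,
                 n_sweeps: int = 1, seed: int = 0) -> GibbsState:
    """Advance ``state`` by ``n_sweeps`` full Gibbs sweeps in place.

    Exposed for stepwise sampler validation (successive-conditional
    simulation); ``fit_segment`` is the normal entry point.
    """
    _run(X, Y, config, state, n_sweeps, 0, max(n_sweeps, 1), seed)
    return state


def sample_prior(config: MTModelConfig, n_draws: int, rng=None):
    """Independent draws of (R, Sigma, pi) from the prior, via scipy.

    Requires explicit prior scales.  Returns a dict of arrays
    ``R`` (n x 2 x 2), ``Sigma`` (n x 2 x 2), ``pi`` (n x 2).
    """
    if config.R_scale is None or config.Sigma_scale is None:
        raise ValueError("sample_prior needs explicit R_scale and Sigma_scale")
    rng = np.random.default_rng(rng)
    R = stats.invwishart.rvs(df=config.R_df, scale=config.R_scale,
                             size=n_draws, random_state=rng)
    S = stats.invwishart.rvs(df=config.Sigma_df, scale=config.Sigma_scale,
                             size=n_draws, random_state=rng)
    pi = rng.beta(config.pi_a, config.pi_b, size=(n_draws, 2))
    return {"R": np.atleast_3d(R).reshape(n_draws, 2, 2),
            "Sigma": np.atleast_3d(S).reshape(n_draws, 2, 2),
            "pi": pi}


def draw_initial_state(config: MTModelConfig, m: int, rng) -> GibbsState:
    """Draw a full sampler state from the prior (intercepts pinned at zero)."""
    prior = sample_prior(config, 1, rng)
    R = prior["R"][0]
    Sig = prior["Sigma"][0]
    pi = prior["pi"][0]
    b = rng.multivariate_normal(np.zeros(2), Sig, size=m)
    d = (rng.random((m, 2)) < pi[None, :]).astype(np.uint8)
    return GibbsState(mu=np.zeros(2), b=b, d=d,
                      R=np.ascontiguousarray(R),
                      Sigma=np.ascontiguousarray(Sig), pi=pi.copy())


def simulate_given_state(X: np.ndarray, state: GibbsState, rng) -> np.ndarray:
    """Draw Y from the model given a sampler state (mu assumed zero)."""
    n = X.shape[0]
    E = rng.multivariate_normal(np.zeros(2), state.R, size=n)
    return X @ state.beta + state.mu[None, :] + E
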