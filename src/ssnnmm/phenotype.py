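"""Whole-genome regression layer: phenotypes on completed gene contents.

    y = 1 mu + sum_j z_j alpha_j + e,    e ~ N(0, I sigma2_e),

with z_j the completed (observed + currently sampled) gene contents of the
phenotyped training individuals, centered by observed-marker means.  Marker
effects get either the ridge/RR-BLUP prior (common normal variance — model-
equivalent to GBLUP with a VanRaden G) or the BayesC-pi spike-and-slab; the
ridge mode is implemented as BayesC-pi with pi fixed at zero, so the two
share one code path and one RNG stream.
"""

from __future__ import annotations

import numpy as np

from ._kernels import alpha_sweep

__all__ = [
    "update_overall_mean",
    "update_marker_effects",
    "update_residual_variance",
    "recompute_residual",
]


def update_overall_mean(state, rng) -> None:
    """Draw mu ~ Normal(mu_old + mean(r), var_e / n); keep r current."""
    n = state.r.size
    if n == 0:
        raise ValueError("no phenotyped training individuals")
    mu_new = state.mu + state.r.mean() + np.sqrt(state.var_e / n) * rng.standard_normal()
    state.r -= mu_new - state.mu
    state.mu = mu_new


def update_marker_effects(state, rng, prior: str = "rrblup", estimate_var_alpha: bool = True) -> None:
    """One Gibbs sweep over all marker effects, plus sigma2_alpha and pi.

    Draw order: effect normals (m,), inclusion uniforms (m, only when the
    spike is active), one chi-square for sigma2_alpha (unless the common
    effect variance is held fixed), one Beta for pi (only when pi is
    estimated).  Each effect's conditional mean is stored in
    ``state.alpha_cond_mean`` for Rao-Blackwellized posterior summaries.
    """
    if prior not in ("rrblup", "bayesc_pi"):
        raise ValueError(f"unknown prior {prior!r}")
    m = state.alpha.size
    use_pi = prior == "bayesc_pi"
    pi = state.pi if use_pi else 0.0
    innov = rng.standard_normal(m)
    need_unif = use_pi and (state.estimate_pi or pi > 0.0)
    unif = rng.random(m) if need_unif else np.zeros(m)
    k_in, ssq = alpha_sweep(
        state.Z,
        state.train_rows,
        state.center,
        state.alpha,
        state.delta,
        state.r,
        state.var_e,
        state.var_alpha,
        pi,
        innov,
        unif,
        use_pi,
        state.alpha_cond_mean,
    )
    if not np.isfinite(state.alpha).all():
        raise FloatingPointError("non-finite marker-effect draw")
    if estimate_var_alpha:
        nu = state.prior_df
        state.var_alpha = (ssq + nu * state.S_alpha) / rng.chisquare(nu + k_in)
    if use_pi and state.estimate_pi:
        state.pi = rng.beta(m - k_in + 1.0, k_in + 1.0)


def update_residual_variance(state, rng) -> None:
    """sigma2_e ~ ScaledInv-chi2(nu + n, (r'r + nu S_e) / (nu + n))."""
    n = state.r.size
    nu = state.prior_df
    state.var_e = (state.r @ state.r + nu * state.S_e) / rng.chisquare(nu + n)


def recompute_residual(state) -> np.ndarray:
    """Residual vector rebuilt from scratch (audit oracle for the running r)."""
    X = state.Z[state.train_rows, :]
    return state.y - state.mu - (X @ state.alpha - state.center @ state.alpha)
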