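"""Sampling missing gene contents of non-genotyped individuals.

The full conditional of a missing cell z_ij is the product of its
pedigree-layer prior N(mu_j + u_ij, sigma2_eps_j) and, when the individual
is phenotyped and sampling conditions on phenotypes, the Gaussian phenotype
likelihood in which z_ij enters linearly with coefficient alpha_j.  Both
factors are Gaussian, so the draw is exact:

    precision P = alpha_j^2 / sigma2_e + 1 / sigma2_eps_j
    mean      = P^-1 [ alpha_j t_i / sigma2_e + (mu_j + u_ij) / sigma2_eps_j ]

with t_i the phenotype residual with marker j's own contribution added
back.  Unconditionally (or for unphenotyped individuals) the draw is from
the prior.  Given the current u_j the cells are conditionally independent
across individuals, so a row-major pass is a valid Gibbs scan.  Sampled
gene contents are continuous — never rounded to 0/1/2.

This module is the single place where the conditional is defined; a
nonlinear output layer would replace :func:`missing_fullconditional` (and
the direct Gaussian draw) with an HMC step without touching the rest of the
chain.
"""

from __future__ import annotations

import numpy as np

from ._kernels import missing_sweep

__all__ = ["missing_fullconditional", "sample_missing_genotypes"]


def missing_fullconditional(state, i: int, j: int, condition_on_y: bool) -> tuple[float, float]:
    """(mean, variance) of the full conditional of missing cell (i, j).

    ``i`` is a middle-layer row index, ``j`` a marker index.  Raises if the
    cell is observed.  Means/variances are on the raw dosage scale (the
    centering used in the phenotype regression is handled internally).
    """
    if state.obs_mask[i, j]:
        raise ValueError(f"cell ({i}, {j}) is observed; its gene content is frozen")
    mu_g = state.blocks.mu_g
    var_eps = float(state.blocks.var_eps[j])
    pm = float(mu_g[j] + state.U[state.mid_to_ped[i], j])
    t = int(state.train_of_row[i])
    if condition_on_y and t >= 0:
        aj = float(state.alpha[j])
        prec = aj * aj / state.var_e + 1.0 / var_eps
        tt = state.r[t] + aj * (state.Z[i, j] - state.center[j])
        mean_x = (aj * tt / state.var_e + (pm - state.center[j]) / var_eps) / prec
        var = 1.0 / prec
        mean = mean_x + state.center[j]
    else:
        mean, var = pm, var_eps
    if not var > 0:
        raise FloatingPointError(f"non-positive conditional variance at ({i}, {j})")
    return mean, var


def sample_missing_genotypes(state, rng, condition_on_y: bool) -> None:
    """Redraw every missing cell once; keep phenotype residuals current.

    Sweep order is by individual then marker.  Observed cells are never
    touched.  Draw order: one standard normal per missing cell, row-major.
    """
    if state.miss_rows.size == 0:
        return
    a = state.alpha
    var_eps = state.blocks.var_eps
    prec = a * a / state.var_e + 1.0 / var_eps
    invp = 1.0 / prec
    coef_t = a / state.var_e * invp
    coef_p = invp / var_eps
    innov = rng.standard_normal(state.miss_rows.size)
    missing_sweep(
        state.Z,
        state.miss_rows,
        state.miss_cols,
        state.blocks.mu_g,
        state.U,
        state.mid_to_ped,
        a,
        state.center,
        coef_t,
        coef_p,
        np.sqrt(invp),
        np.sqrt(var_eps),
        state.r,
        state.train_of_row,
        condition_on_y,
        innov,
    )
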