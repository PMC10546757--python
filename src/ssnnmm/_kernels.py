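"""Numba kernels for the per-iteration Gibbs sweeps.

Innovations (standard-normal / uniform draws) are generated by the caller
with a ``numpy.random.Generator`` and passed in as arrays, so the chain is
deterministic for a given seed and the kernels stay free of RNG state.
Per-marker constants (shrinkage factors, conditional standard deviations)
are hoisted out of the inner loops, which keeps them to fused
multiply-adds; the variance-ratio lambda of the gene-content layer is a
single scalar in fixed-heritability mode, which the main kernel exploits.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["gene_sweep", "alpha_sweep", "missing_sweep"]


@njit(cache=True)
def gene_sweep(
    U,
    Z,
    obs,
    mu_g,
    mid_row_of_ped,
    row_kind,
    indptr,
    indices,
    data,
    lam,
    lam_is_scalar,
    var_u,
    var_eps,
    sqrt_var_u,
    sqrt_var_eps,
    innov_mu,
    innov_u,
    alpha,
    center,
    r_vec,
    train_of_row,
    w_pseudo,
):
    """Single-site Gibbs pass over (mu_j, u_j) for all markers at once.

    Observed gene contents are the data of the per-marker pedigree-BLUP
    model; sampled (imputed) cells never feed back as data — they are
    redrawn from their own conditional afterwards.  For a *phenotyped*
    individual whose cell (i, j) is missing, the phenotype carries
    information about u_ij once the missing cell is marginalized out: the
    record t_i / alpha_j (the phenotype residual with marker j's own
    contribution restored, scaled back to the dosage axis) enters with
    weight ``w_pseudo[j] = alpha_j^2 var_eps_j / (var_e + alpha_j^2
    var_eps_j)`` relative to an observed dosage.  Together with the
    subsequent conditional draw of the missing cell this forms an exact
    blocked (partially collapsed) Gibbs step — the naive alternative of
    treating sampled cells as data mixes at rate ~var_eps and effectively
    never forgets its initialization when the gene-content heritability is
    near 1.  Passing ``w_pseudo = 0`` (unconditional sampling, or a null
    marker effect) reduces everything to pure pedigree BLUP on observed
    cells.

    ``row_kind[i]``: 0 = no observed data, 1 = fully observed row,
    2 = partially observed row (mixed SNP panels).  ``lam[j] =
    var_eps[j] / var_u[j]``; when ``lam_is_scalar`` all markers share
    lam[0] and the main loops stay division-free.  U (q, m) and mu_g (m,)
    are updated in place.
    """
    q, m = U.shape
    # --- marker means over observed (and pseudo) records ---
    acc = np.zeros(m)
    wsum = np.zeros(m)
    for i in range(q):
        rr = mid_row_of_ped[i]
        if rr < 0:
            continue
        t = train_of_row[rr]
        full = row_kind[i] == 1
        for j in range(m):
            if full or obs[rr, j]:
                acc[j] += Z[rr, j] - U[i, j]
                wsum[j] += 1.0
            elif t >= 0 and w_pseudo[j] > 0.0:
                # t_i / alpha_j + c_j simplifies against the stored dosage
                pz = Z[rr, j] + r_vec[t] / alpha[j]
                acc[j] += w_pseudo[j] * (pz - U[i, j])
                wsum[j] += w_pseudo[j]
    for j in range(m):
        inv_n = 1.0 / wsum[j]
        mu_g[j] = acc[j] * inv_n + sqrt_var_eps[j] * np.sqrt(inv_n) * innov_mu[j]
    # --- deviations ---
    s = np.empty(m)
    for i in range(q):
        for j in range(m):
            s[j] = 0.0
        aii = 0.0
        for ptr in range(indptr[i], indptr[i + 1]):
            k = indices[ptr]
            v = data[ptr]
            if k == i:
                aii = v
            else:
                for j in range(m):
                    s[j] += v * U[k, j]
        rr = mid_row_of_ped[i]
        kind = row_kind[i]
        t = train_of_row[rr] if rr >= 0 else -1
        if lam_is_scalar:
            la = lam[0]
            c_dat = 1.0 + la * aii
            invc = 1.0 / c_dat
            sdf_dat = np.sqrt(invc)
            inva = 1.0 / aii
            sdf_pri = np.sqrt(inva)
            if kind == 1:
                for j in range(m):
                    U[i, j] = (Z[rr, j] - mu_g[j] - la * s[j]) * invc + sdf_dat * sqrt_var_eps[
                        j
                    ] * innov_u[i, j]
            elif rr < 0 or t < 0:
                for j in range(m):
                    if kind == 2 and obs[rr, j]:
                        U[i, j] = (
                            Z[rr, j] - mu_g[j] - la * s[j]
                        ) * invc + sdf_dat * sqrt_var_eps[j] * innov_u[i, j]
                    else:
                        U[i, j] = -s[j] * inva + sdf_pri * sqrt_var_u[j] * innov_u[i, j]
            elif kind == 0:
                # fully-missing phenotyped row: every cell is a pseudo-record
                rt = r_vec[t]
                for j in range(m):
                    if w_pseudo[j] > 0.0:
                        pz = Z[rr, j] + rt / alpha[j]
                        c = w_pseudo[j] + la * aii
                        U[i, j] = (w_pseudo[j] * (pz - mu_g[j]) - la * s[j]) / c + np.sqrt(
                            var_eps[j] / c
                        ) * innov_u[i, j]
                    else:
                        U[i, j] = -s[j] * inva + sdf_pri * sqrt_var_u[j] * innov_u[i, j]
            else:
                # partially observed phenotyped row (mixed panels)
                rt = r_vec[t]
                for j in range(m):
                    if obs[rr, j]:
                        U[i, j] = (
                            Z[rr, j] - mu_g[j] - la * s[j]
                        ) * invc + sdf_dat * sqrt_var_eps[j] * innov_u[i, j]
                    elif w_pseudo[j] > 0.0:
                        pz = Z[rr, j] + rt / alpha[j]
                        c = w_pseudo[j] + la * aii
                        U[i, j] = (w_pseudo[j] * (pz - mu_g[j]) - la * s[j]) / c + np.sqrt(
                            var_eps[j] / c
                        ) * innov_u[i, j]
                    else:
                        U[i, j] = -s[j] * inva + sdf_pri * sqrt_var_u[j] * innov_u[i, j]
        else:
            inva = 1.0 / aii
            for j in range(m):
                if kind != 0 and obs[rr, j]:
                    c = 1.0 + lam[j] * aii
                    U[i, j] = (Z[rr, j] - mu_g[j] - lam[j] * s[j]) / c + np.sqrt(
                        var_eps[j] / c
                    ) * innov_u[i, j]
                elif rr >= 0 and t >= 0 and w_pseudo[j] > 0.0:
                    c = w_pseudo[j] + lam[j] * aii
                    pz = Z[rr, j] + r_vec[t] / alpha[j]
                    U[i, j] = (w_pseudo[j] * (pz - mu_g[j]) - lam[j] * s[j]) / c + np.sqrt(
                        var_eps[j] / c
                    ) * innov_u[i, j]
                else:
                    U[i, j] = -s[j] * inva + np.sqrt(var_u[j] * inva) * innov_u[i, j]


@njit(cache=True)
def alpha_sweep(
    Z, train_rows, center, alpha, delta, r, var_e, var_alpha, pi, innov, unif, use_pi, cond_mean
):
    """Scalar conjugate Gibbs updates of all marker effects.

    Covariates are the completed gene contents of the phenotyped training
    rows, centered by ``center``; the phenotype residual ``r`` is kept
    current incrementally.  With ``use_pi`` the spike-and-slab indicator is
    sampled from its marginal odds (effect integrated out); ``pi == 0``
    short-circuits to certain inclusion without consuming a uniform, which
    makes the ridge (RR-BLUP) mode an exact special case.

    ``cond_mean[j]`` receives each effect's conditional posterior mean
    (inclusion probability times the conjugate mean), the Rao-Blackwellized
    estimate the chain accumulates alongside the draws.

    Returns (number of included effects, sum of squared included effects).
    """
    n_t = train_rows.size
    m = alpha.size
    lam_a = var_e / var_alpha
    k_in = 0
    ssq = 0.0
    for j in range(m):
        a_old = alpha[j]
        cj = 0.0
        rhs = 0.0
        for t in range(n_t):
            x = Z[train_rows[t], j] - center[j]
            cj += x * x
            rhs += x * r[t]
        rhs += cj * a_old
        denom = cj + lam_a
        include = True
        p1 = 1.0
        if use_pi and pi > 0.0:
            # log Bayes factor for delta_j = 1 vs 0, effect integrated out
            logbf = 0.5 * rhs * rhs / (var_e * denom) + 0.5 * np.log(lam_a / denom)
            logodds = np.log((1.0 - pi) / pi) + logbf
            p1 = 1.0 / (1.0 + np.exp(-logodds))
            include = unif[j] < p1
        cond_mean[j] = p1 * rhs / denom
        if include:
            a_new = rhs / denom + np.sqrt(var_e / denom) * innov[j]
            delta[j] = 1.0
            k_in += 1
            ssq += a_new * a_new
        else:
            a_new = 0.0
            delta[j] = 0.0
        diff = a_new - a_old
        if diff != 0.0:
            for t in range(n_t):
                r[t] -= (Z[train_rows[t], j] - center[j]) * diff
        alpha[j] = a_new
    return k_in, ssq


@njit(cache=True)
def missing_sweep(
    Z,
    miss_rows,
    miss_cols,
    mu_g,
    U,
    mid_to_ped,
    alpha,
    center,
    coef_t,
    coef_p,
    sd_cond,
    sd_prior,
    r,
    train_of_row,
    condition_on_y,
    innov,
):
    """Redraw every missing gene-content cell from its full conditional.

    For a phenotyped row under conditional sampling the draw is
    N(coef_t[j] * t + coef_p[j] * (prior_mean - center[j]) + center[j],
    sd_cond[j]^2) with t the phenotype residual with marker j's own
    contribution restored — the precomputed coefficients encode
    precision-weighting of likelihood and pedigree prior.  Otherwise the
    draw is from the prior N(mu_j + u_ij, sd_prior[j]^2).  Cells are
    scanned row-major; the owning residual entry is corrected after each
    draw.  Cells of different individuals never interact, so the scan is a
    valid Gibbs pass regardless of individual order.
    """
    for idx in range(miss_rows.size):
        i = miss_rows[idx]
        j = miss_cols[idx]
        pm = mu_g[j] + U[mid_to_ped[i], j]
        t = train_of_row[i]
        z_old = Z[i, j]
        if condition_on_y and t >= 0:
            tt = r[t] + alpha[j] * (z_old - center[j])
            mean_x = coef_t[j] * tt + coef_p[j] * (pm - center[j])
            z_new = mean_x + sd_cond[j] * innov[idx] + center[j]
            r[t] -= alpha[j] * (z_new - z_old)
        else:
            z_new = pm + sd_prior[j] * innov[idx]
            if t >= 0:
                r[t] -= alpha[j] * (z_new - z_old)
        Z[i, j] = z_new
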