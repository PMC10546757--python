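"""Pedigree-BLUP layer: gene content of each marker as a quantitative trait.

For marker j the observed (and sampled) dosages of middle-layer individuals
follow

    z_j = 1 mu_j + W u_j + eps_j,   u_j ~ MVN(0, A sigma2_u_j),
                                    eps_j ~ N(0, I sigma2_eps_j),

with A the numerator relationship matrix over the whole pedigree and W the
0/1 incidence picking out middle-layer individuals.  The residual exists to
keep the mixed-model equations usable and to absorb genotype/pedigree
errors; with perfect data the gene-content heritability
sigma2_u / (sigma2_u + sigma2_eps) is 1, so a fixed ratio very close to 1
(default 0.999) is the standard operating mode.  In ``estimated`` mode both
variances get scaled inverse-chi-square priors and are Gibbs-sampled.

Updates are single-site Gibbs over the per-marker MME, vectorized across
markers (see :mod:`ssnnmm._kernels`); with innovations zeroed the sweep is
exactly Gauss–Seidel on the MME, which tests exploit as an oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._kernels import gene_sweep
from .data import GenotypeMatrix

__all__ = [
    "MarkerBlocks",
    "init_gene_content_state",
    "update_marker_mean_and_u",
    "update_gene_content_variances",
    "heritability_from_samples",
    "gene_content_heritability",
]


@dataclass
class MarkerBlocks:
    """Vectorized per-marker state of the gene-content layer."""

    marker_index: np.ndarray  # indices of retained markers in the input panel
    mu_g: np.ndarray  # (m,) marker means
    var_u: np.ndarray  # (m,) genetic variance of gene content
    var_eps: np.ndarray  # (m,) residual variance of gene content
    s2: np.ndarray  # (m,) observed dosage sample variance (initialization basis)
    S_u: np.ndarray  # (m,) prior scale for var_u (estimated mode)
    S_eps: np.ndarray  # (m,) prior scale for var_eps
    h2_mode: str  # 'fixed' | 'estimated'
    h2_fixed: float
    prior_df: float


def init_gene_content_state(
    geno: GenotypeMatrix,
    h2_mode: str = "fixed",
    h2_fixed: float = 0.999,
    prior_df: float = 4.0,
) -> MarkerBlocks:
    """Initialize per-marker means and variance components.

    ``mu_j`` starts at the observed marker mean; variances at
    ``h2_fixed * s2_j`` and ``(1 - h2_fixed) * s2_j`` with ``s2_j`` the
    observed dosage sample variance.  In ``fixed`` mode they stay there; in
    ``estimated`` mode the same values seed the chain and set the scaled
    inverse-chi-square prior scales (df ``prior_df``).

    Markers with fewer than two observed genotypes raise; markers that are
    monomorphic among observed genotypes are excluded with a warning.
    """
    if h2_mode not in ("fixed", "estimated"):
        raise ValueError(f"unknown h2_mode {h2_mode!r}")
    if not (0 < h2_fixed < 1):
        raise ValueError("h2_fixed must lie in (0, 1)")
    cnt = geno.observed_mask.sum(axis=0)
    if (cnt < 2).any():
        j = int(np.nonzero(cnt < 2)[0][0])
        raise ValueError(
            f"marker {geno.markers[j]!r} has {int(cnt[j])} observed genotype(s); "
            "cannot set its dosage variance"
        )
    Zobs = np.where(geno.observed_mask, geno.Z, 0.0)
    mu = Zobs.sum(axis=0) / cnt
    s2 = (np.where(geno.observed_mask, (geno.Z - mu) ** 2, 0.0)).sum(axis=0) / (cnt - 1)
    keep = s2 > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} marker(s) monomorphic among observed genotypes"
        )
    idx = np.nonzero(keep)[0]
    mu, s2 = mu[idx], s2[idx]
    var_u = h2_fixed * s2
    var_eps = (1.0 - h2_fixed) * s2
    return MarkerBlocks(
        marker_index=idx,
        mu_g=mu.copy(),
        var_u=var_u.copy(),
        var_eps=var_eps.copy(),
        s2=s2,
        S_u=var_u.copy(),
        S_eps=var_eps.copy(),
        h2_mode=h2_mode,
        h2_fixed=h2_fixed,
        prior_df=float(prior_df),
    )


def update_marker_mean_and_u(state, rng, markers=None, condition_on_y: bool = False) -> None:
    """Gibbs draw of (mu_j, u_j) for the selected markers (default: all).

    Single-site scan over the joint MME: first the mean given u, then each
    pedigree individual's deviation given everything else, sharing the
    sparse A-inverse across markers.  Observed dosages are the data; with
    ``condition_on_y`` the phenotype of an individual whose cell is missing
    additionally enters as a weighted pseudo-record (the missing cell
    marginalized out), so that together with the subsequent missing-cell
    draw the step is an exact blocked update.  Draw order per call:
    marker-mean normals (m,), then deviation normals (q, m).
    """
    b = state.blocks
    subset = markers is not None
    if subset:
        sel = np.atleast_1d(np.asarray(markers))
        mu_g = b.mu_g[sel].copy()
        var_u = np.ascontiguousarray(b.var_u[sel])
        var_eps = np.ascontiguousarray(b.var_eps[sel])
        U = np.ascontiguousarray(state.U[:, sel])
        Z = np.ascontiguousarray(state.Z[:, sel])
        obs = np.ascontiguousarray(state.obs_u8[:, sel])
        alpha = np.ascontiguousarray(state.alpha[sel])
        center = np.ascontiguousarray(state.center[sel])
    else:
        mu_g, var_u, var_eps = b.mu_g, b.var_u, b.var_eps
        U, Z = state.U, state.Z
        obs = state.obs_u8
        alpha, center = state.alpha, state.center
    q, m = U.shape
    if condition_on_y:
        w_pseudo = alpha * alpha * var_eps / (state.var_e + alpha * alpha * var_eps)
    else:
        w_pseudo = np.zeros(m)
    # in fixed mode every marker shares one variance ratio, which the kernel
    # exploits to keep the inner loops division-free
    lam_is_scalar = b.h2_mode == "fixed"
    lam = (
        np.array([(1.0 - b.h2_fixed) / b.h2_fixed])
        if lam_is_scalar
        else var_eps / var_u
    )
    innov_mu = rng.standard_normal(m)
    innov_u = rng.standard_normal((q, m))
    gene_sweep(
        U,
        Z,
        obs,
        mu_g,
        state.mid_row_of_ped,
        state.row_kind,
        state.ainv_indptr,
        state.ainv_indices,
        state.ainv_data,
        lam,
        lam_is_scalar,
        var_u,
        var_eps,
        np.sqrt(var_u),
        np.sqrt(var_eps),
        innov_mu,
        innov_u,
        alpha,
        center,
        state.r,
        state.train_of_row,
        w_pseudo,
    )
    if not np.isfinite(U).all():
        bad = int(np.nonzero(~np.isfinite(U).all(axis=0))[0][0])
        raise FloatingPointError(f"non-finite gene-content draw at marker column {bad}")
    if subset:
        state.blocks.mu_g[sel] = mu_g
        state.U[:, sel] = U


def update_gene_content_variances(state, rng) -> None:
    """Scaled inverse-chi-square draws of (var_u_j, var_eps_j), all markers.

    A no-op in fixed-heritability mode.  Draw order: one chi-square vector
    for the genetic variances, then one for the residual variances.
    """
    b = state.blocks
    if b.h2_mode == "fixed":
        return
    nu = b.prior_df
    q = state.U.shape[0]
    m = b.mu_g.size
    # u' A^-1 u per marker via the shared sparse A^-1
    AinvU = state.ainv_csr @ state.U
    quad = np.einsum("ij,ij->j", AinvU, state.U)
    b.var_u = (quad + nu * b.S_u) / rng.chisquare(nu + q, size=m)
    # residuals over observed cells only (the model's data for marker j)
    eps = np.where(
        state.obs_u8.astype(bool), state.Z - b.mu_g - state.U[state.mid_to_ped, :], 0.0
    )
    sse = np.einsum("ij,ij->j", eps, eps)
    b.var_eps = (sse + nu * b.S_eps) / rng.chisquare(nu + state.n_obs, size=m)
    if (b.var_u <= 0).any() or (b.var_eps <= 0).any():
        raise FloatingPointError("non-positive gene-content variance draw")


def heritability_from_samples(var_u_samples, var_eps_samples) -> np.ndarray:
    """Posterior-mean gene-content heritability, computed per sample then
    averaged (mean of ratios, not ratio of means)."""
    var_u_samples = np.asarray(var_u_samples, dtype=float)
    var_eps_samples = np.asarray(var_eps_samples, dtype=float)
    return np.mean(var_u_samples / (var_u_samples + var_eps_samples), axis=0)


def gene_content_heritability(summary, j: int) -> float:
    """Posterior-mean heritability of gene content for marker ``j``.

    Equals ``h2_fixed`` exactly in fixed mode; otherwise the mean of the
    per-sample variance ratios accumulated during the chain.
    """
    h2 = summary.gene_content_h2
    if h2 is None:
        raise ValueError("no gene-content heritability samples in this summary")
    return float(h2[j])
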