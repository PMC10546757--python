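"""Conventional single-step GBLUP (H matrix) and genotyped-only GBLUP.

These are the reference methods the network-based sampler is compared
against: a VanRaden genomic relationship matrix G over genotyped
individuals, blended with the pedigree submatrix A22 for invertibility,
combined into the single-step H-inverse

    H^-1 = A^-1 + [0 0; 0 G_blend^-1 - A22^-1]

on the genotyped block, and an animal-model mixed-model-equation solve.
Variance components are supplied (typically simulation truth) rather than
estimated, which isolates the method comparison from variance estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GenotypeMatrix, PhenotypeTable

__all__ = [
    "GenomicMatrix",
    "HInverse",
    "genomic_matrix",
    "h_inverse",
    "solve_single_step",
    "solve_gblup",
    "backsolve_marker_effects",
]


@dataclass
class GenomicMatrix:
    """VanRaden G over genotyped individuals, raw and blended with A22."""

    ids: tuple[str, ...]
    G_raw: np.ndarray
    G_blend: np.ndarray
    allele_freq: np.ndarray
    blend: tuple[float, float]
    M: np.ndarray  # centered dosage matrix (kept for effect backsolving)
    scale: float  # sum 2 p (1 - p)


@dataclass
class HInverse:
    """Single-step relationship inverse over all pedigree individuals."""

    ids: tuple[str, ...]
    H_inv: np.ndarray


def _check_pd(mat: np.ndarray, name: str) -> None:
    try:
        np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"{name} is not positive definite") from exc


def genomic_matrix(
    geno: GenotypeMatrix,
    blend_alpha: float = 0.95,
    blend_beta: float = 0.05,
    A22: np.ndarray | None = None,
) -> GenomicMatrix:
    """VanRaden genomic relationship matrix with A22 blending.

    ``G_raw = M M' / sum_j 2 p_j (1-p_j)`` with ``M`` the dosage matrix
    column-centered by twice the observed allele frequencies;
    ``G_blend = alpha G_raw + beta A22``.  Requires a common complete panel
    (no missing cells) — the conventional single-step constraint.
    """
    if not geno.observed_mask.all():
        raise ValueError(
            "genomic_matrix requires fully genotyped individuals on a common panel"
        )
    if abs(blend_alpha + blend_beta - 1.0) > 1e-12:
        raise ValueError("blend weights must sum to 1")
    p = geno.allele_freq
    scale = float(np.sum(2.0 * p * (1.0 - p)))
    if scale <= 0:
        raise ValueError("all markers monomorphic; G is undefined")
    M = geno.Z - 2.0 * p
    G_raw = (M @ M.T) / scale
    if blend_beta > 0:
        if A22 is None:
            raise ValueError("A22 required when blend_beta > 0")
        G_blend = blend_alpha * G_raw + blend_beta * A22
    else:
        G_blend = G_raw.copy()
    _check_pd(G_blend, "blended G")
    return GenomicMatrix(
        ids=geno.ids,
        G_raw=G_raw,
        G_blend=G_blend,
        allele_freq=p,
        blend=(blend_alpha, blend_beta),
        M=M,
        scale=scale,
    )


def h_inverse(
    A_inv: np.ndarray,
    G_blend: np.ndarray,
    A22: np.ndarray,
    genotyped_positions,
    ids: tuple[str, ...] | None = None,
) -> HInverse:
    """Assemble H^-1 = A^-1 + scatter(G_blend^-1 - A22^-1) on the genotyped block."""
    pos = np.asarray(genotyped_positions, dtype=np.int64)
    H = A_inv.copy()
    if pos.size:
        Gi = np.linalg.inv(G_blend)
        A22i = np.linalg.inv(A22)
        H[np.ix_(pos, pos)] += Gi - A22i
    if ids is None:
        ids = tuple(str(i) for i in range(A_inv.shape[0]))
    return HInverse(ids=ids, H_inv=H)


def _animal_mme(
    y: np.ndarray, train_pos: np.ndarray, K_inv: np.ndarray, lambda_ratio: float
) -> np.ndarray:
    """Solve the animal-model MME for (mu, a); returns a over all individuals.

    System: [[n, w'], [w, D + K^-1 lambda]] (mu, a)' = (1'y, W'y)' where W
    selects phenotyped individuals (one record each).
    """
    if lambda_ratio <= 0:
        raise ValueError("lambda_ratio must be positive")
    n_ind = K_inv.shape[0]
    n_t = train_pos.size
    if n_t == 0:
        raise ValueError("no phenotyped training individuals")
    C = np.zeros((n_ind + 1, n_ind + 1))
    C[0, 0] = n_t
    w = np.zeros(n_ind)
    np.add.at(w, train_pos, 1.0)
    C[0, 1:] = w
    C[1:, 0] = w
    C[1:, 1:] = np.diag(w) + K_inv * lambda_ratio
    rhs = np.zeros(n_ind + 1)
    rhs[0] = y.sum()
    np.add.at(rhs, 1 + train_pos, y)
    sol = np.linalg.solve(C, rhs)
    return sol[1:]


def solve_single_step(
    pheno: PhenotypeTable, H_inv: HInverse, lambda_ratio: float
) -> dict[str, float]:
    """SS-GBLUP breeding values for every pedigree individual.

    ``lambda_ratio = sigma2_e / sigma2_a``.  Only train-role phenotypes
    enter the equations.  Returns an id -> EBV mapping.
    """
    lookup = {iid: k for k, iid in enumerate(H_inv.ids)}
    train = pheno.train_ids()
    try:
        pos = np.array([lookup[i] for i in train], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"phenotyped id {exc.args[0]!r} not in H matrix") from None
    a = _animal_mme(pheno.y_of(train), pos, H_inv.H_inv, lambda_ratio)
    return dict(zip(H_inv.ids, a))


def solve_gblup(
    pheno: PhenotypeTable, gm: GenomicMatrix, lambda_ratio: float
) -> dict[str, float]:
    """Genotyped-only GBLUP: breeding values for all genotyped individuals
    (training individuals without genotypes are simply dropped)."""
    lookup = {iid: k for k, iid in enumerate(gm.ids)}
    train = [i for i in pheno.train_ids() if i in lookup]
    if not train:
        raise ValueError("no genotyped phenotyped training individuals")
    pos = np.array([lookup[i] for i in train], dtype=np.int64)
    K_inv = np.linalg.inv(gm.G_blend)
    a = _animal_mme(pheno.y_of(train), pos, K_inv, lambda_ratio)
    return dict(zip(gm.ids, a))


def backsolve_marker_effects(gm: GenomicMatrix, ebv: dict[str, float]) -> np.ndarray:
    """Marker effects implied by genotyped individuals' breeding values.

    alpha = M' G_blend^-1 a_g / scale — the standard GBLUP-to-SNP-effect
    backsolve, used to correlate baseline effects with sampled ones.
    """
    a_g = np.array([ebv[i] for i in gm.ids])
    return gm.M.T @ np.linalg.solve(gm.G_blend, a_g) / gm.scale
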