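"""Synthetic pedigrees, gene-dropped genotypes, QTL phenotypes and masking.

The generator emulates a livestock evaluation design: a multi-generation
pedigree with discrete generations and random pair mating, biallelic SNPs
dropped through the pedigree by Mendelian sampling from founder allele
frequencies, a trait controlled by a small fraction of the panel (QTL kept
inside the panel), and masking patterns that turn training individuals
non-genotyped either wholesale (whole rows) or cellwise (mixed SNP panels).
"""

from __future__ import annotations

import warnings

import numpy as np

from .data import GenotypeMatrix, PhenotypeTable, TrueValues
from .pedigree import UNKNOWN, Pedigree

__all__ = [
    "simulate_pedigree",
    "gene_drop",
    "simulate_phenotypes",
    "assign_roles",
    "mask_individuals",
    "mask_cells",
]


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    offspring_per_mating: int = 2,
    seed: int = 0,
) -> Pedigree:
    """Discrete-generation pedigree with random pair mating.

    Each generation, the previous generation is randomly paired without
    replacement (monogamous pairs) and every pair produces
    ``offspring_per_mating`` offspring.  Ids are ``G<gen>_<k>``; the result
    is topologically ordered by construction.
    """
    if n_founders < 2 or n_founders % 2:
        raise ValueError("n_founders must be an even number >= 2")
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    if offspring_per_mating < 1:
        raise ValueError("offspring_per_mating must be >= 1")
    rng = np.random.default_rng(seed)

    ids: list[str] = [f"G0_{k}" for k in range(n_founders)]
    sire: list[int] = [UNKNOWN] * n_founders
    dam: list[int] = [UNKNOWN] * n_founders
    gen: list[int] = [0] * n_founders
    prev = list(range(n_founders))
    for g in range(1, n_generations + 1):
        perm = rng.permutation(len(prev))
        pairs = [(prev[perm[2 * k]], prev[perm[2 * k + 1]]) for k in range(len(prev) // 2)]
        cur: list[int] = []
        k = 0
        for s, d in pairs:
            for _ in range(offspring_per_mating):
                ids.append(f"G{g}_{k}")
                sire.append(s)
                dam.append(d)
                gen.append(g)
                cur.append(len(ids) - 1)
                k += 1
        if not cur:
            raise ValueError("generation produced no offspring; increase n_founders")
        prev = cur
    return Pedigree(
        ids=tuple(ids),
        sire=np.array(sire, dtype=np.int64),
        dam=np.array(dam, dtype=np.int64),
        generation=np.array(gen, dtype=np.int64),
        ordered=True,
    )


def _drop_markers(ped: Pedigree, freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Gene-drop a set of markers; returns (n, m) dosages."""
    n, m = ped.n, freqs.size
    a1 = np.empty((n, m), dtype=np.int8)
    a2 = np.empty((n, m), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            u = rng.random((2, m))
            a1[i] = u[0] < freqs
            a2[i] = u[1] < freqs
        else:
            # one allele from each parent, picked uniformly from the parent's two
            for dest, p in ((a1, s), (a2, d)):
                if p == UNKNOWN:
                    dest[i] = rng.random(m) < freqs
                else:
                    pick = rng.random(m) < 0.5
                    dest[i] = np.where(pick, a1[p], a2[p])
    return (a1 + a2).astype(np.float64)


def gene_drop(
    ped: Pedigree,
    m: int,
    freq_low: float = 0.1,
    freq_high: float = 0.9,
    seed: int = 0,
    max_retries: int = 20,
) -> GenotypeMatrix:
    """Biallelic genotypes by Mendelian gene dropping.

    Founder allele frequencies are drawn per marker from
    ``Uniform(freq_low, freq_high)``; founders receive two independent
    Bernoulli alleles, non-founders inherit one random allele from each
    parent.  Markers that end up monomorphic across all individuals are
    redrawn (bounded retries) or dropped with a warning.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    if not (0 < freq_low <= freq_high < 1):
        raise ValueError("need 0 < freq_low <= freq_high < 1")
    if not ped.ordered:
        raise ValueError("pedigree must be topologically ordered")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(freq_low, freq_high, size=m)
    Z = _drop_markers(ped, freqs, rng)
    for _ in range(max_retries):
        mono = np.nonzero(Z.std(axis=0) == 0)[0]
        if mono.size == 0:
            break
        Z[:, mono] = _drop_markers(ped, rng.uniform(freq_low, freq_high, size=mono.size), rng)
    mono = np.nonzero(Z.std(axis=0) == 0)[0]
    keep = np.setdiff1d(np.arange(m), mono)
    if mono.size:
        warnings.warn(f"dropped {mono.size} marker(s) still monomorphic after retries")
    markers = tuple(f"M{j}" for j in range(m))
    markers = tuple(markers[j] for j in keep)
    return GenotypeMatrix(
        ids=ped.ids,
        markers=markers,
        Z=Z[:, keep],
        observed_mask=np.ones((ped.n, keep.size), dtype=bool),
    )


def simulate_phenotypes(
    geno: GenotypeMatrix,
    qtl_prop: float = 0.005,
    h2: float = 0.7,
    var_p: float = 1.0,
    seed: int = 0,
) -> tuple[PhenotypeTable, TrueValues]:
    """Trait controlled by a random subset of panel markers.

    QTL are chosen uniformly without replacement (rounded half-up count,
    at least 1); raw additive effects are standard normal, then rescaled so
    the realized variance of true breeding values equals ``h2 * var_p``
    exactly over the simulated individuals; residuals are
    ``Normal(0, (1-h2) var_p)``.  All individuals receive a phenotype; the
    train/test split is assigned separately (:func:`assign_roles`).
    """
    if not (0 < h2 < 1):
        raise ValueError("h2 must lie in (0, 1)")
    if not (0 < qtl_prop < 1):
        raise ValueError("qtl_prop must lie in (0, 1)")
    n_qtl = int(np.floor(qtl_prop * geno.m + 0.5))
    if n_qtl < 1:
        raise ValueError("qtl_prop implies fewer than one QTL")
    if not geno.observed_mask.all():
        raise ValueError("phenotype simulation requires fully observed genotypes")
    rng = np.random.default_rng(seed)
    qtl = np.sort(rng.choice(geno.m, size=n_qtl, replace=False))
    eff = rng.standard_normal(n_qtl)
    bv = geno.Z[:, qtl] @ eff
    bv = bv - bv.mean()
    sd = bv.std()  # population sd; exact-variance rescaling
    if sd == 0:
        raise ValueError("QTL are monomorphic; cannot build a trait")
    scale = np.sqrt(h2 * var_p) / sd
    eff = eff * scale
    bv = bv * scale
    resid = rng.normal(0.0, np.sqrt((1.0 - h2) * var_p), size=geno.n)
    y = bv + resid
    pheno = PhenotypeTable(geno.ids, y, tuple(["train"] * geno.n))
    truth = TrueValues(
        qtl_indices=qtl,
        qtl_effects=eff,
        ids=geno.ids,
        true_bv=bv,
        h2_target=h2,
        varp_target=var_p,
    )
    return pheno, truth


def assign_roles(pheno: PhenotypeTable, ped: Pedigree, n_test: int) -> PhenotypeTable:
    """Mark the youngest ``n_test`` individuals (final generation, id order)
    as the unphenotyped test set; everyone else trains."""
    if ped.generation is None:
        raise ValueError("pedigree has no generation field")
    last = ped.generation.max()
    youngest = [i for i, g in zip(ped.ids, ped.generation) if g == last][:n_test]
    test = set(youngest)
    role = tuple("test" if i in test else "train" for i in pheno.ids)
    return PhenotypeTable(pheno.ids, pheno.y.copy(), role)


def mask_individuals(
    geno: GenotypeMatrix,
    proportion: float,
    protected_ids=(),
    seed: int = 0,
) -> GenotypeMatrix:
    """Turn a random fraction of the (unprotected) individuals fully
    non-genotyped.  ``round(proportion * pool)`` individuals are masked; the
    input matrix is untouched."""
    if not (0 <= proportion < 1):
        raise ValueError("proportion must lie in [0, 1)")
    protected = set(protected_ids)
    pool = [i for i in geno.ids if i not in protected]
    k = int(np.floor(proportion * len(pool) + 0.5))
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(len(pool), size=k, replace=False).tolist()) if k else set()
    chosen_ids = {pool[c] for c in chosen}
    mask = geno.observed_mask.copy()
    for r, iid in enumerate(geno.ids):
        if iid in chosen_ids:
            mask[r, :] = False
    return GenotypeMatrix(geno.ids, geno.markers, geno.Z.copy(), mask)


def mask_cells(
    geno: GenotypeMatrix,
    proportion: float,
    protected_ids=(),
    seed: int = 0,
) -> GenotypeMatrix:
    """Exact-count cellwise masking over unprotected rows (mixed SNP panels).

    All currently-observed cells of unprotected rows are pooled, shuffled,
    and the first ``round(proportion * n_cells)`` are masked — an exact
    missing fraction rather than a binomial one.
    """
    if not (0 <= proportion < 1):
        raise ValueError("proportion must lie in [0, 1)")
    protected = set(protected_ids)
    rows = np.array([i not in protected for i in geno.ids])
    mask = geno.observed_mask.copy()
    cells = np.nonzero(mask & rows[:, None])
    n_cells = cells[0].size
    k = int(np.floor(proportion * n_cells + 0.5))
    if k:
        rng = np.random.default_rng(seed)
        pick = rng.permutation(n_cells)[:k]
        mask[cells[0][pick], cells[1][pick]] = False
    return GenotypeMatrix(geno.ids, geno.markers, geno.Z.copy(), mask)
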