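"""Scikit-learn style estimators over the single-step machinery.

``fit`` takes the genotype container (a :class:`~ssnnmm.data.GenotypeMatrix`
or an id-indexed DataFrame with NaN for missing dosages) as ``X``, the
phenotypes (a :class:`~ssnnmm.data.PhenotypeTable` or an id-indexed Series)
as ``y``, and the pedigree as a keyword; ``predict`` returns breeding
values for requested ids.  Parameters follow the sklearn contract
(get_params/set_params, fitted attributes with trailing underscores), so
the estimators compose with sklearn model-selection utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .baseline import genomic_matrix, h_inverse, solve_gblup, solve_single_step
from .data import GenotypeMatrix, PhenotypeTable
from .engine import RunConfig, estimate_breeding_values, run_nnmm
from .pedigree import Pedigree, numerator_inverse, numerator_matrix, submatrix, topological_order

__all__ = ["SingleStepNNMM", "SingleStepGBLUP", "GBLUP"]


def _as_genotypes(X) -> GenotypeMatrix:
    if isinstance(X, GenotypeMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        Z = X.to_numpy(dtype=float)
        mask = ~np.isnan(Z)
        return GenotypeMatrix(
            tuple(str(i) for i in X.index),
            tuple(str(c) for c in X.columns),
            np.where(mask, Z, 0.0),
            mask,
        )
    raise TypeError("X must be a GenotypeMatrix or an id-indexed DataFrame")


def _as_phenotypes(y) -> PhenotypeTable:
    if isinstance(y, PhenotypeTable):
        return y
    if isinstance(y, pd.Series):
        return PhenotypeTable(
            tuple(str(i) for i in y.index),
            y.to_numpy(dtype=float),
            tuple(["train"] * len(y)),
        )
    raise TypeError("y must be a PhenotypeTable or an id-indexed Series")


def _ordered(ped: Pedigree) -> Pedigree:
    return ped if ped.ordered else topological_order(ped)


class SingleStepNNMM(BaseEstimator):
    """Three-layer single-step evaluation fitted by Gibbs sampling.

    Parameters mirror :class:`~ssnnmm.engine.RunConfig`.  After ``fit``:

    - ``summary_`` : the full :class:`~ssnnmm.engine.PosteriorSummary`;
    - ``marker_effects_`` : posterior-mean marker effects;
    - ``ebv_`` : id -> posterior-mean breeding value for every middle-layer
      individual;
    - ``gene_content_h2_`` : per-marker gene-content heritability.
    """

    def __init__(
        self,
        chain_length: int = 2000,
        burn_in: int | None = None,
        seed: int = 0,
        h2_mode: str = "fixed",
        h2_fixed: float = 0.999,
        condition_on_y: bool = True,
        prior: str = "rrblup",
        prior_df: float = 4.0,
        h2_prior: float = 0.5,
    ):
        self.chain_length = chain_length
        self.burn_in = burn_in
        self.seed = seed
        self.h2_mode = h2_mode
        self.h2_fixed = h2_fixed
        self.condition_on_y = condition_on_y
        self.prior = prior
        self.prior_df = prior_df
        self.h2_prior = h2_prior

    def _config(self) -> RunConfig:
        return RunConfig(
            chain_length=self.chain_length,
            burn_in=self.burn_in,
            seed=self.seed,
            h2_mode=self.h2_mode,
            h2_fixed=self.h2_fixed,
            condition_on_y=self.condition_on_y,
            prior=self.prior,
            prior_df=self.prior_df,
            h2_prior=self.h2_prior,
        )

    def fit(self, X, y, pedigree: Pedigree = None):
        if pedigree is None:
            raise ValueError("pedigree is required")
        geno = _as_genotypes(X)
        pheno = _as_phenotypes(y)
        self.geno_ = geno
        self.summary_ = run_nnmm(_ordered(pedigree), geno, pheno, self._config())
        self.marker_effects_ = self.summary_.alpha_mean
        self.gene_content_h2_ = self.summary_.gene_content_h2
        self.ebv_ = dict(zip(self.summary_.mid_ids, self.summary_.ebv_mean))
        return self

    def predict(self, ids) -> np.ndarray:
        """Posterior-mean breeding values for the given ids (middle-layer
        individuals use per-sample accumulation; other fully genotyped
        individuals the marker-effect dot product)."""
        if isinstance(ids, pd.DataFrame):
            ids = [str(i) for i in ids.index]
        return estimate_breeding_values(self.summary_, self.geno_, ids)["ebv_mean"].to_numpy()


class SingleStepGBLUP(BaseEstimator):
    """Conventional H-matrix single-step GBLUP with supplied variance ratio."""

    def __init__(self, lambda_ratio: float = 3.0 / 7.0, blend_alpha: float = 0.95):
        self.lambda_ratio = lambda_ratio
        self.blend_alpha = blend_alpha

    def fit(self, X, y, pedigree: Pedigree = None):
        if pedigree is None:
            raise ValueError("pedigree is required")
        ped = _ordered(pedigree)
        geno = _as_genotypes(X)
        pheno = _as_phenotypes(y)
        gen_ids = geno.fully_observed_ids()
        nm = numerator_matrix(ped)
        nm.A_inv = numerator_inverse(ped, nm.F).A_inv
        A22 = submatrix(nm, gen_ids)
        gm = genomic_matrix(geno.subset(gen_ids), self.blend_alpha, 1 - self.blend_alpha, A22)
        Hinv = h_inverse(nm.A_inv, gm.G_blend, A22, ped.index_of(gen_ids), ids=ped.ids)
        self.ebv_ = solve_single_step(pheno, Hinv, self.lambda_ratio)
        return self

    def predict(self, ids) -> np.ndarray:
        return np.array([self.ebv_[i] for i in ids])


class GBLUP(BaseEstimator):
    """Genotyped-only GBLUP (VanRaden G, supplied variance ratio)."""

    def __init__(self, lambda_ratio: float = 3.0 / 7.0, blend_alpha: float = 0.95):
        self.lambda_ratio = lambda_ratio
        self.blend_alpha = blend_alpha

    def fit(self, X, y, pedigree: Pedigree = None):
        geno = _as_genotypes(X)
        pheno = _as_phenotypes(y)
        gen_ids = geno.fully_observed_ids()
        A22 = None
        if self.blend_alpha < 1.0:
            if pedigree is None:
                raise ValueError("pedigree is required when blending G with A22")
            ped = _ordered(pedigree)
            A22 = submatrix(numerator_matrix(ped), gen_ids)
        gm = genomic_matrix(geno.subset(gen_ids), self.blend_alpha, 1 - self.blend_alpha, A22)
        self.ebv_ = solve_gblup(pheno, gm, self.lambda_ratio)
        return self

    def predict(self, ids) -> np.ndarray:
        return np.array([self.ebv_[i] for i in ids])
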