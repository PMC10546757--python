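"""MCMC orchestration, posterior summaries, accuracy, replicate experiments.

One iteration of the chain updates, in a fixed scan order,

1. the phenotype layer (overall mean, all marker effects, the effect
   variance and spike probability where applicable, the residual variance);
2. the gene-content layer (per-marker mean and pedigree deviations, and in
   ``estimated`` mode the per-marker variance components);
3. every missing gene-content cell, from its Gaussian full conditional,
   conditionally or unconditionally on phenotypes.

The chain is deterministic given the seed; an end-of-iteration audit
recomputes the phenotype residual from scratch and aborts on desync.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, replace
from typing import Any

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from . import gene_content, latent, phenotype
from .baseline import backsolve_marker_effects, genomic_matrix, h_inverse, solve_gblup, solve_single_step
from .data import GenotypeMatrix, PhenotypeTable, TrueValues
from .gene_content import MarkerBlocks, init_gene_content_state
from .pedigree import Pedigree, numerator_inverse, numerator_matrix, submatrix
from .simulate import mask_cells, mask_individuals

logger = logging.getLogger("ssnnmm")

__all__ = [
    "RunConfig",
    "ChainState",
    "Chain",
    "PosteriorSummary",
    "run_nnmm",
    "estimate_breeding_values",
    "prediction_accuracy",
    "run_replicates",
    "ReplicateResults",
]


@dataclass(frozen=True)
class RunConfig:
    """Resolved chain configuration.

    chain_length : total MCMC iterations (default 2000).
    burn_in : discarded iterations (default chain_length // 2).
    h2_mode / h2_fixed : gene-content heritability treatment; the fixed
        default 0.999 keeps the mixed-model equations well conditioned
        while leaving gene content essentially fully heritable.
    condition_on_y : whether missing gene contents are sampled conditional
        on phenotypes (default True).
    prior : 'rrblup' (ridge, GBLUP-equivalent) or 'bayesc_pi'.
    h2_prior : trait heritability used to set the marker-effect prior scale
        var_p * h2_prior / sum_j 2 p_j (1 - p_j).
    """

    chain_length: int = 2000
    burn_in: int | None = None
    seed: int = 0
    h2_mode: str = "fixed"
    h2_fixed: float = 0.999
    condition_on_y: bool = True
    prior: str = "rrblup"
    pi_init: float = 0.5
    estimate_pi: bool = True
    prior_df: float = 4.0
    h2_prior: float = 0.5
    var_p_prior: float | None = None
    estimate_trait_variances: bool = True
    audit_tol: float = 1e-6
    save_imputed: bool = True
    progress_every: int = 0

    def resolved_burn_in(self) -> int:
        b = self.chain_length // 2 if self.burn_in is None else self.burn_in
        if not (0 <= b < self.chain_length):
            raise ValueError("need chain_length > burn_in >= 0")
        return b

    def as_dict(self) -> dict[str, Any]:
        d = self.__dict__.copy()
        d["burn_in"] = self.resolved_burn_in()
        return d


@dataclass
class ChainState:
    """All MCMC unknowns plus the frozen data views one iteration needs."""

    blocks: MarkerBlocks
    U: np.ndarray  # (q, m) gene-content deviations over the pedigree
    Z: np.ndarray  # (n_mid, m) completed gene contents
    obs_mask: np.ndarray  # (n_mid, m) frozen observed-cell mask
    obs_u8: np.ndarray  # same mask as uint8 (kernel view)
    row_kind: np.ndarray  # (q,) 0 no observed data, 1 full row, 2 partial row
    n_obs: np.ndarray  # (m,) observed cells per marker
    mid_ids: tuple[str, ...]
    mid_to_ped: np.ndarray  # (n_mid,) pedigree index of each middle row
    mid_row_of_ped: np.ndarray  # (q,) middle row of pedigree individual, or -1
    miss_rows: np.ndarray
    miss_cols: np.ndarray
    ainv_csr: sp.csr_matrix
    train_rows: np.ndarray  # middle rows with a training phenotype
    train_of_row: np.ndarray  # (n_mid,) index into r/y, or -1
    y: np.ndarray
    center: np.ndarray  # (m,) frozen centering constants (observed means)
    mu: float
    alpha: np.ndarray
    alpha_cond_mean: np.ndarray
    delta: np.ndarray
    pi: float
    var_alpha: float
    var_e: float
    r: np.ndarray
    S_alpha: float
    S_e: float
    prior_df: float
    estimate_pi: bool
    rng: np.random.Generator = None
    iteration: int = 0

    @property
    def ainv_indptr(self):
        return self.ainv_csr.indptr

    @property
    def ainv_indices(self):
        return self.ainv_csr.indices

    @property
    def ainv_data(self):
        return self.ainv_csr.data


@dataclass
class PosteriorSummary:
    """Post-burn-in posterior summaries of one chain."""

    mid_ids: tuple[str, ...]
    markers: tuple[str, ...]
    center: np.ndarray
    alpha_mean: np.ndarray
    alpha_sd: np.ndarray
    delta_mean: np.ndarray
    mu_mean: float
    mu_g_mean: np.ndarray
    ebv_mean: np.ndarray
    ebv_sd: np.ndarray
    var_e_trace: np.ndarray
    var_alpha_trace: np.ndarray
    pi_trace: np.ndarray
    gene_content_h2: np.ndarray
    imputed_mean: np.ndarray | None
    imputed_sd: np.ndarray | None
    obs_mask: np.ndarray
    n_samples: int
    config: RunConfig
    split_half_ebv_correlation: float = float("nan")

    def ebv_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": list(self.mid_ids), "ebv_mean": self.ebv_mean, "ebv_sd": self.ebv_sd}
        )

    def marker_effects_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": list(self.markers),
                "alpha_mean": self.alpha_mean,
                "alpha_sd": self.alpha_sd,
                "delta_mean": self.delta_mean,
            }
        )

    def gene_content_h2_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": list(self.markers), "h2_posterior_mean": self.gene_content_h2}
        )

    def variances_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(1, self.var_e_trace.size + 1),
                "var_e": self.var_e_trace,
                "var_alpha": self.var_alpha_trace,
                "pi": self.pi_trace,
            }
        )

    def converged(self, threshold: float = 0.99) -> bool:
        """Split-half agreement flag: EBV means from the two halves of the
        post-burn-in samples should correlate above the threshold."""
        r = self.split_half_ebv_correlation
        return bool(np.isnan(r) or r >= threshold)

    def imputed_frame(self) -> pd.DataFrame:
        """Posterior mean/SD of every sampled (missing) gene content."""
        if self.imputed_mean is None:
            raise ValueError("chain was run without imputation accumulation")
        rows, cols = np.nonzero(~self.obs_mask)
        return pd.DataFrame(
            {
                "id": [self.mid_ids[r] for r in rows],
                "marker": [self.markers[c] for c in cols],
                "z_mean": self.imputed_mean[rows, cols],
                "z_sd": self.imputed_sd[rows, cols],
            }
        )

    def plot_traces(self, path) -> None:
        """Variance-component trace plots (PNG) for convergence inspection."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 3))
        axes[0].plot(self.var_e_trace, lw=0.6)
        axes[0].set_title("residual variance")
        axes[1].plot(self.var_alpha_trace, lw=0.6)
        axes[1].set_title("marker-effect variance")
        for ax in axes:
            ax.set_xlabel("iteration")
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)

    def ebv_of(self, ids) -> np.ndarray:
        lookup = {i: k for k, i in enumerate(self.mid_ids)}
        return self.ebv_mean[[lookup[i] for i in ids]]


class Chain:
    """A single-step network chain: build state, advance, summarize.

    Instances are picklable mid-run (state includes the generator), so a
    checkpointed chain continues with draws identical to an uninterrupted
    one.
    """

    def __init__(
        self,
        ped: Pedigree,
        geno: GenotypeMatrix,
        pheno: PhenotypeTable,
        cfg: RunConfig,
        A_inv: np.ndarray | None = None,
    ) -> None:
        self.cfg = cfg
        self.burn_in = cfg.resolved_burn_in()
        self.state = _build_state(ped, geno, pheno, cfg, A_inv=A_inv)
        m = self.state.alpha.size
        n_mid = self.state.Z.shape[0]
        self.markers = tuple(geno.markers[k] for k in self.state.blocks.marker_index)
        self._acc = {
            "alpha": np.zeros(m),
            "alpha_rb": np.zeros(m),
            "alpha2": np.zeros(m),
            "delta": np.zeros(m),
            "mu": 0.0,
            "ebv": np.zeros(n_mid),
            "ebv2": np.zeros(n_mid),
            "z": np.zeros((n_mid, m)) if cfg.save_imputed else None,
            "z2": np.zeros((n_mid, m)) if cfg.save_imputed else None,
            "ebv_h1": np.zeros(n_mid),
            "ebv_h2": np.zeros(n_mid),
            "n_h1": 0,
            "n_h2": 0,
            "h2": np.zeros(m),
            "mu_g": np.zeros(m),
            "n": 0,
        }
        self._var_e_trace = np.zeros(cfg.chain_length)
        self._var_alpha_trace = np.zeros(cfg.chain_length)
        self._pi_trace = np.zeros(cfg.chain_length)

    def step(self) -> None:
        st = self.state
        cfg = self.cfg
        phenotype.update_overall_mean(st, st.rng)
        phenotype.update_marker_effects(
            st, st.rng, prior=cfg.prior, estimate_var_alpha=cfg.estimate_trait_variances
        )
        if cfg.estimate_trait_variances:
            phenotype.update_residual_variance(st, st.rng)
        gene_content.update_marker_mean_and_u(st, st.rng, condition_on_y=cfg.condition_on_y)
        gene_content.update_gene_content_variances(st, st.rng)
        latent.sample_missing_genotypes(st, st.rng, cfg.condition_on_y)
        # end-of-iteration audit: rebuild the residual from scratch and
        # refresh the running copy so incremental error cannot accumulate
        g_all = st.Z @ st.alpha - st.center @ st.alpha
        g_rb = st.Z @ st.alpha_cond_mean - st.center @ st.alpha_cond_mean
        r_true = st.y - st.mu - g_all[st.train_rows]
        drift = float(np.max(np.abs(r_true - st.r))) if st.r.size else 0.0
        if drift > cfg.audit_tol:
            raise FloatingPointError(
                f"residual bookkeeping desync {drift:.2e} at iteration {st.iteration}"
            )
        st.r = r_true
        it = st.iteration
        self._var_e_trace[it] = st.var_e
        self._var_alpha_trace[it] = st.var_alpha
        self._pi_trace[it] = st.pi
        if (it + 1) % 100 == 0:
            if not (np.isfinite(st.alpha).all() and np.isfinite(st.Z).all()):
                raise FloatingPointError(f"non-finite state at iteration {it}")
            if self.cfg.progress_every and (it + 1) % self.cfg.progress_every == 0:
                logger.info("iteration %d/%d var_e=%.4f", it + 1, cfg.chain_length, st.var_e)
        if it >= self.burn_in:
            self._accumulate(g_rb)
        st.iteration += 1

    def _accumulate(self, g: np.ndarray) -> None:
        st = self.state
        acc = self._acc
        acc["alpha"] += st.alpha
        acc["alpha_rb"] += st.alpha_cond_mean
        acc["alpha2"] += st.alpha ** 2
        acc["delta"] += st.delta
        acc["mu"] += st.mu
        acc["ebv"] += g
        acc["ebv2"] += g ** 2
        # split-half accumulation for the convergence diagnostic
        if acc["n"] < (self.cfg.chain_length - self.burn_in) // 2:
            acc["ebv_h1"] += g
            acc["n_h1"] += 1
        else:
            acc["ebv_h2"] += g
            acc["n_h2"] += 1
        if acc["z"] is not None:
            acc["z"] += st.Z
            acc["z2"] += st.Z ** 2
        b = st.blocks
        acc["mu_g"] += b.mu_g
        if b.h2_mode == "estimated":
            acc["h2"] += b.var_u / (b.var_u + b.var_eps)
        acc["n"] += 1

    def run(self) -> PosteriorSummary:
        while self.state.iteration < self.cfg.chain_length:
            self.step()
        return self.summary()

    def summary(self) -> PosteriorSummary:
        acc = self._acc
        n = acc["n"]
        if n == 0:
            raise RuntimeError("no post-burn-in samples accumulated yet")
        st = self.state
        b = st.blocks

        def _sd(s, s2):
            v = s2 / n - (s / n) ** 2
            return np.sqrt(np.clip(v, 0.0, None))

        if b.h2_mode == "fixed":
            h2 = np.full(b.mu_g.size, b.h2_fixed)
        else:
            h2 = acc["h2"] / n
        split_r = float("nan")
        if acc["n_h1"] > 1 and acc["n_h2"] > 1:
            h1 = acc["ebv_h1"] / acc["n_h1"]
            h2_ = acc["ebv_h2"] / acc["n_h2"]
            if np.std(h1) > 0 and np.std(h2_) > 0:
                split_r = float(np.corrcoef(h1, h2_)[0, 1])
        return PosteriorSummary(
            mid_ids=st.mid_ids,
            markers=self.markers,
            center=st.center.copy(),
            alpha_mean=acc["alpha_rb"] / n,
            alpha_sd=_sd(acc["alpha"], acc["alpha2"]),
            delta_mean=acc["delta"] / n,
            mu_mean=acc["mu"] / n,
            mu_g_mean=acc["mu_g"] / n,
            ebv_mean=acc["ebv"] / n,
            ebv_sd=_sd(acc["ebv"], acc["ebv2"]),
            var_e_trace=self._var_e_trace[: st.iteration].copy(),
            var_alpha_trace=self._var_alpha_trace[: st.iteration].copy(),
            pi_trace=self._pi_trace[: st.iteration].copy(),
            gene_content_h2=h2,
            imputed_mean=None if acc["z"] is None else acc["z"] / n,
            imputed_sd=None if acc["z"] is None else _sd(acc["z"], acc["z2"]),
            obs_mask=st.obs_mask,
            n_samples=n,
            config=self.cfg,
            split_half_ebv_correlation=split_r,
        )

    def checkpoint(self) -> bytes:
        return pickle.dumps(self)

    @staticmethod
    def restore(blob: bytes) -> "Chain":
        return pickle.loads(blob)


def _build_state(
    ped: Pedigree,
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    cfg: RunConfig,
    A_inv: np.ndarray | None = None,
) -> ChainState:
    if not ped.ordered:
        raise ValueError("pedigree must be topologically ordered")
    ped_index = ped.index
    for iid in geno.ids:
        if iid not in ped_index:
            raise ValueError(f"genotyped id {iid!r} not in pedigree")
    for iid in pheno.ids:
        if iid not in ped_index:
            raise ValueError(f"phenotyped id {iid!r} not in pedigree")

    blocks = init_gene_content_state(
        geno, h2_mode=cfg.h2_mode, h2_fixed=cfg.h2_fixed, prior_df=cfg.prior_df
    )
    sel = blocks.marker_index
    Zin = geno.Z[:, sel]
    mask_in = geno.observed_mask[:, sel]
    m = sel.size

    geno_row = {iid: k for k, iid in enumerate(geno.ids)}
    train_ids_all = pheno.train_ids()
    train_set = set(train_ids_all)
    genotyped = {iid for k, iid in enumerate(geno.ids) if mask_in[k].any()}
    # middle layer: genotyped individuals plus phenotyped training individuals,
    # in pedigree order; pedigree-only individuals contribute through u alone
    mid_ids = tuple(i for i in ped.ids if i in genotyped or i in train_set)
    mid_to_ped = ped.index_of(mid_ids)
    q = ped.n
    mid_row_of_ped = np.full(q, -1, dtype=np.int64)
    mid_row_of_ped[mid_to_ped] = np.arange(len(mid_ids))

    n_mid = len(mid_ids)
    Z = np.empty((n_mid, m))
    obs = np.zeros((n_mid, m), dtype=bool)
    for r, iid in enumerate(mid_ids):
        k = geno_row.get(iid)
        if k is None:
            continue
        obs[r] = mask_in[k]
        Z[r] = np.where(mask_in[k], Zin[k], 0.0)
    center = blocks.mu_g.copy()
    Z[~obs] = np.broadcast_to(center, (n_mid, m))[~obs]
    miss_rows, miss_cols = np.nonzero(~obs)
    miss_rows = miss_rows.astype(np.int64)
    miss_cols = miss_cols.astype(np.int64)
    n_obs = obs.sum(axis=0).astype(np.float64)
    row_kind = np.zeros(q, dtype=np.int8)
    row_obs = obs.sum(axis=1)
    for r in range(n_mid):
        i = mid_to_ped[r]
        if row_obs[r] == m:
            row_kind[i] = 1
        elif row_obs[r] > 0:
            row_kind[i] = 2

    if A_inv is None:
        A_inv = numerator_inverse(ped).A_inv
    ainv_csr = sp.csr_matrix(A_inv)

    train_of_row = np.full(n_mid, -1, dtype=np.int64)
    train_rows_list = [int(mid_row_of_ped[ped_index[i]]) for i in train_ids_all]
    order = np.argsort(train_rows_list)  # scan training rows in middle-layer order
    train_rows = np.array([train_rows_list[k] for k in order], dtype=np.int64)
    y = pheno.y_of(train_ids_all)[order]
    train_of_row[train_rows] = np.arange(train_rows.size)

    var_p = cfg.var_p_prior
    if var_p is None:
        var_p = float(np.var(y)) if y.size and np.var(y) > 0 else 1.0
    p = np.clip(
        np.where(obs, Z, 0.0).sum(axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1)), 1e-6, 1 - 1e-6
    )
    het = float(np.sum(2.0 * p * (1.0 - p)))
    S_alpha = cfg.h2_prior * var_p / het
    S_e = (1.0 - cfg.h2_prior) * var_p

    mu0 = float(y.mean()) if y.size else 0.0
    state = ChainState(
        blocks=blocks,
        U=np.zeros((q, m)),
        Z=Z,
        obs_mask=obs,
        obs_u8=obs.astype(np.uint8),
        row_kind=row_kind,
        n_obs=n_obs,
        mid_ids=mid_ids,
        mid_to_ped=mid_to_ped,
        mid_row_of_ped=mid_row_of_ped,
        miss_rows=miss_rows,
        miss_cols=miss_cols,
        ainv_csr=ainv_csr,
        train_rows=train_rows,
        train_of_row=train_of_row,
        y=y,
        center=center,
        mu=mu0,
        alpha=np.zeros(m),
        alpha_cond_mean=np.zeros(m),
        delta=np.ones(m),
        pi=cfg.pi_init if cfg.prior == "bayesc_pi" else 0.0,
        var_alpha=S_alpha,
        var_e=S_e,
        r=y - mu0,
        S_alpha=S_alpha,
        S_e=S_e,
        prior_df=cfg.prior_df,
        estimate_pi=cfg.estimate_pi,
        # SFC64: same Generator API as PCG64 with a faster stream, which
        # matters here — the sampler draws ~q*m normals per iteration
        rng=np.random.Generator(np.random.SFC64(cfg.seed)),
    )
    return state


def run_nnmm(
    ped: Pedigree,
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    cfg: RunConfig | None = None,
    A_inv: np.ndarray | None = None,
) -> PosteriorSummary:
    """Fit the three-layer network by Gibbs sampling; return posterior summaries."""
    return Chain(ped, geno, pheno, cfg or RunConfig(), A_inv=A_inv).run()


def estimate_breeding_values(
    summary: PosteriorSummary, geno: GenotypeMatrix, ids
) -> pd.DataFrame:
    """EBVs for the requested ids.

    Middle-layer individuals get the per-sample accumulated posterior mean
    and SD (which for non-genotyped individuals averages over the sampled
    gene contents); other individuals need a fully observed genotype row and
    get sum_j (z_ij - c_j) * alpha_mean_j with no SD.
    """
    mid = {i: k for k, i in enumerate(summary.mid_ids)}
    geno_row = {i: k for k, i in enumerate(geno.ids)}
    marker_col = {mk: k for k, mk in enumerate(geno.markers)}
    cols = np.array([marker_col[mk] for mk in summary.markers], dtype=np.int64)
    means, sds = [], []
    for iid in ids:
        if iid in mid:
            k = mid[iid]
            means.append(summary.ebv_mean[k])
            sds.append(summary.ebv_sd[k])
        elif iid in geno_row:
            row = geno_row[iid]
            if not geno.observed_mask[row, cols].all():
                raise ValueError(f"id {iid!r} lacks complete genotypes for EBV")
            z = geno.Z[row, cols]
            means.append(float((z - summary.center) @ summary.alpha_mean))
            sds.append(np.nan)
        else:
            raise ValueError(f"id {iid!r} has no usable genotype information")
    return pd.DataFrame({"id": list(ids), "ebv_mean": means, "ebv_sd": sds})


def prediction_accuracy(ebv, true_bv) -> float:
    """Pearson correlation between estimated and true breeding values."""
    ebv = np.asarray(ebv, dtype=float)
    true_bv = np.asarray(true_bv, dtype=float)
    if ebv.shape != true_bv.shape or ebv.size < 3:
        raise ValueError("need two equal-length vectors with at least 3 entries")
    if np.std(ebv) == 0 or np.std(true_bv) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(scipy.stats.pearsonr(ebv, true_bv)[0])


@dataclass
class ReplicateResults:
    """Replicate-experiment output: raw per-run rows, a Table-1-style
    mean (sd) summary, and paired t-tests between the single-step methods."""

    results: pd.DataFrame
    table: pd.DataFrame
    means: pd.DataFrame
    ttests: pd.DataFrame
    effect_correlations: pd.DataFrame


def _derived_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=tuple(key)).generate_state(1)[0] % (2**31))


def run_replicates(
    ped: Pedigree,
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    truth: TrueValues,
    cfg: RunConfig | None = None,
    scenarios=(0.3, 0.5, 0.7, 0.9),
    n_reps: int = 10,
    h2: float = 0.7,
    var_p: float = 1.0,
    seed: int = 0,
    cellwise: bool = False,
    methods=("ss_nn_gblup", "ss_gblup", "gblup"),
    qtl_prop: float | None = None,
    n_test: int | None = None,
) -> ReplicateResults:
    """The masking experiment: scenarios x replicates x methods.

    For each replicate a fresh random subset of training individuals is
    masked non-genotyped (or, with ``cellwise``, a fraction of training
    cells); the network sampler, conventional SS-GBLUP and genotyped-only
    GBLUP are fitted on identical data, and test-set accuracy (Pearson
    correlation with true breeding values) is recorded, together with the
    correlation between the two single-step methods' marker effects.
    Baselines use the simulation-truth variance ratio; the network chain
    holds its trait variances at the same values.

    When ``qtl_prop`` and ``n_test`` are given, the trait (QTL draw,
    effects and residuals) is re-simulated for every replicate index on
    the fixed genotypes — replicates then sample the trait distribution,
    not just the masking — with the same trait shared by all scenarios of
    a replicate so scenario contrasts stay paired.  Otherwise the supplied
    phenotypes/truth are fixed throughout.
    """
    from .simulate import assign_roles, simulate_phenotypes

    cfg = cfg or RunConfig()
    refresh_trait = qtl_prop is not None and n_test is not None
    nm = numerator_matrix(ped)
    nm.A_inv = numerator_inverse(ped, nm.F).A_inv
    rows = []
    eff_rows = []
    for si, prop in enumerate(scenarios):
        for rep in range(n_reps):
            mask_seed = _derived_seed(seed, si, rep, 0)
            chain_seed = _derived_seed(seed, si, rep, 1)
            if refresh_trait:
                pheno, truth = simulate_phenotypes(
                    geno, qtl_prop=qtl_prop, h2=h2, var_p=var_p,
                    seed=_derived_seed(seed, rep, 2),
                )
                pheno = assign_roles(pheno, ped, n_test)
            test_ids = pheno.test_ids()
            true_test = truth.bv_of(test_ids)
            lam = (1.0 - h2) / h2
            masker = mask_cells if cellwise else mask_individuals
            masked = masker(geno, prop, protected_ids=test_ids, seed=mask_seed)
            alpha_nn = alpha_ss = None
            if "ss_nn_gblup" in methods:
                # hold trait variances at the values the baselines receive, so
                # the comparison isolates the imputation machinery
                rep_cfg = replace(
                    cfg, seed=chain_seed, save_imputed=False,
                    estimate_trait_variances=False, h2_prior=h2, var_p_prior=var_p,
                )
                summ = run_nnmm(ped, masked, pheno, rep_cfg, A_inv=nm.A_inv)
                acc = prediction_accuracy(summ.ebv_of(test_ids), true_test)
                rows.append((prop, rep, "ss_nn_gblup", acc))
                alpha_nn = summ.alpha_mean
            gen_ids = masked.fully_observed_ids()
            if ("ss_gblup" in methods or "gblup" in methods) and gen_ids:
                A22 = submatrix(nm, gen_ids)
                gm = genomic_matrix(masked.subset(gen_ids), 0.95, 0.05, A22)
                if "ss_gblup" in methods:
                    Hinv = h_inverse(
                        nm.A_inv, gm.G_blend, A22, ped.index_of(gen_ids), ids=ped.ids
                    )
                    ebv = solve_single_step(pheno, Hinv, lam)
                    acc = prediction_accuracy([ebv[i] for i in test_ids], true_test)
                    rows.append((prop, rep, "ss_gblup", acc))
                    alpha_ss = backsolve_marker_effects(gm, ebv)
                if "gblup" in methods:
                    ebv = solve_gblup(pheno, gm, lam)
                    acc = prediction_accuracy([ebv[i] for i in test_ids], true_test)
                    rows.append((prop, rep, "gblup", acc))
            if alpha_nn is not None and alpha_ss is not None:
                # the sampler may have excluded monomorphic-observed markers
                keep = np.arange(alpha_ss.size)
                if alpha_nn.size != alpha_ss.size:
                    raise RuntimeError("marker panels diverged between methods")
                ec = float(np.corrcoef(alpha_nn, alpha_ss)[0, 1])
                eff_rows.append((prop, rep, ec))
    results = pd.DataFrame(rows, columns=["scenario", "rep", "method", "accuracy"])
    means = results.pivot_table(index="method", columns="scenario", values="accuracy", aggfunc="mean")
    sds = results.pivot_table(index="method", columns="scenario", values="accuracy", aggfunc="std")
    table = means.copy().astype(object)
    for mth in means.index:
        for sc in means.columns:
            table.loc[mth, sc] = f"{means.loc[mth, sc]:.3f} ({sds.loc[mth, sc]:.3f})"
    tt = []
    if {"ss_nn_gblup", "ss_gblup"} <= set(methods):
        for prop in scenarios:
            a = results.query("scenario == @prop and method == 'ss_nn_gblup'").sort_values("rep")[
                "accuracy"
            ]
            b = results.query("scenario == @prop and method == 'ss_gblup'").sort_values("rep")[
                "accuracy"
            ]
            if len(a) == len(b) and len(a) > 1:
                diff = a.to_numpy() - b.to_numpy()
                if np.allclose(diff, diff[0]):
                    p = 1.0 if np.allclose(diff, 0) else np.nan
                else:
                    p = float(scipy.stats.ttest_rel(a, b).pvalue)
                tt.append((prop, float(np.mean(diff)), p))
    ttests = pd.DataFrame(tt, columns=["scenario", "mean_diff", "p_value"])
    effect_correlations = pd.DataFrame(eff_rows, columns=["scenario", "rep", "effect_corr"])
    return ReplicateResults(
        results=results, table=table, means=means, ttests=ttests,
        effect_correlations=effect_correlations,
    )
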