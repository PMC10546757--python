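# Methods

## The model

`ssnnmm` performs single-step genomic evaluation by treating pedigree, gene
contents and phenotypes as three sequential layers of one hierarchical
Gaussian model, sampled jointly by MCMC.

**Gene-content layer (pedigree → dosages).** For each marker j, the dosage
(0/1/2 count of the reference allele) of the genotyped individuals is
modelled as a quantitative trait:

    z_gj = 1 mu_j + W u_j + eps_j,
    u_j   ~ MVN(0, A sigma2_uj),        eps_j ~ N(0, I sigma2_epsj),

where `A` is the numerator relationship matrix over the whole pedigree and
`W` picks out, per marker, the individuals whose dosage is observed — so
individuals genotyped on different SNP panels simply contribute different
rows per marker.  The residual exists to keep the mixed-model equations
usable and to absorb genotype/pedigree errors; the gene-content
heritability `sigma2_u / (sigma2_u + sigma2_eps)` is 1 for perfect data.
Two operating modes:

- `fixed` (default): both variances are set from the observed dosage
  variance s2_j at a fixed ratio h2 = 0.999 and never updated.  This is
  the standard treatment when data are trusted.
- `estimated`: scaled inverse-chi-square priors (df 4, scales matched to
  the fixed-mode initialization) and Gibbs updates for both components,
  yielding a per-marker posterior heritability that acts as a
  genotype/pedigree quality diagnostic.

**Phenotype layer (dosages → trait).** A whole-genome regression on the
completed (observed + sampled) gene contents of the phenotyped training
individuals:

    y = 1 mu + sum_j z_j alpha_j + e,    e ~ N(0, I sigma2_e),

with marker covariates centered by observed-marker means.  The default
prior on effects is the ridge/RR-BLUP prior (common normal variance),
which is model-equivalent to GBLUP with a VanRaden genomic relationship
matrix; BayesC-pi (spike-and-slab with estimated exclusion probability pi)
is available and the ridge mode is implemented as its pi = 0 special case,
sharing one code path and RNG stream.  sigma2_e and the common effect
variance carry scaled inverse-chi-square priors (df 4; scales from a prior
trait heritability, default 0.5, and the phenotypic variance).

**Latent layer (missing gene contents).** Non-genotyped (or partially
genotyped) phenotyped individuals keep a full row of latent gene contents.
Each missing cell has a Gaussian full conditional — the product of its
pedigree prior N(mu_j + u_ij, sigma2_eps) and, when sampling conditions on
phenotypes, the phenotype likelihood in which the cell enters linearly —
and is redrawn every iteration.  Sampled gene contents are continuous,
never rounded to 0/1/2: the model is linear in expected allele count.

## The sampler

Per iteration, in fixed scan order: (1) phenotype layer (mu, all alpha_j,
effect variance and pi where applicable, sigma2_e); (2) gene-content layer
(mu_j and u_j for every marker, then variance components in `estimated`
mode); (3) all missing cells.  All updates are single-site conjugate Gibbs
over the corresponding mixed-model equations, vectorized across markers in
numba kernels; the sparse pedigree-inverse `A^-1` (Henderson's rules with
inbreeding) is shared by all markers.  With the random innovations zeroed,
one sweep is exactly Gauss-Seidel on the MME — the test suite exploits this
to compare iterated sweeps against dense solves.

Two design points deserve emphasis because the obvious alternatives fail:

- **Observed cells only are data for u.** Treating the freshly *sampled*
  cells as records in the gene-content MME is also a valid Gibbs scheme,
  but at a fixed gene-content heritability of 0.999 the pair (u_ij, z_ij)
  of a non-genotyped individual becomes an almost deterministic feedback
  loop whose state decays toward the pedigree information at rate
  ~(1 - h2) per iteration: imputations effectively never leave their
  initialization within realistic chain lengths.  Conditioning u on
  observed dosages only, and redrawing every missing cell from its own
  conditional afterwards, mixes immediately.

- **Phenotype conditioning enters the u-update as pseudo-records.** Given
  u, the phenotype tilts a missing cell by at most ~sigma_eps, which is
  tiny by construction, so conditioning applied only at the cell level is
  inert.  Instead, when `condition_on_y` is on, the (mu_j, u_j) update
  marginalizes the missing cell analytically: a phenotyped individual with
  a missing cell contributes the record `t_i / alpha_j` (its phenotype
  residual with marker j's contribution restored, mapped back to the
  dosage axis) with weight

      w_j = alpha_j^2 sigma2_eps / (sigma2_e + alpha_j^2 sigma2_eps)

  relative to an observed dosage.  Together with the subsequent
  missing-cell draw this is an exact blocked (partially collapsed) Gibbs
  step for (mu_j, u_j, z_nj), so phenotype information reaches the
  imputation at full strength while mixing stays fast.  With
  `condition_on_y` off, imputation uses pedigree and observed genotypes
  only — the classical expected-gene-content (Gengler-type) limit, which a
  long-chain test verifies against the closed form
  `mu_j + A_ng A_gg^-1 (z_g - mu_j)`.

Posterior summaries are accumulated after burn-in (default: half the
chain).  Marker-effect posterior means are Rao-Blackwellized — the chain
stores each effect's conditional mean alongside the actual draw — which
reduces the Monte Carlo error of EBVs at no cost; posterior SDs come from
the draws.  Breeding values are accumulated per sample as
`sum_j (z_ij - c_j) alpha_j`, so EBVs of non-genotyped individuals
average over their imputation uncertainty.  An end-of-iteration audit
recomputes the phenotype residual from scratch (tolerance 1e-6) and then
replaces the running copy, so incremental error cannot accumulate.  The
chain is deterministic given its seed (generator: numpy `SFC64`, chosen
because the sampler consumes ~q*m normal draws per iteration) and is
picklable mid-run; a restored chain continues with identical draws.

## Baselines

Conventional SS-GBLUP: VanRaden `G = MM' / sum 2p(1-p)` over the fully
genotyped individuals (allele frequencies from observed genotypes, as base
frequencies are unavailable), blended `0.95 G + 0.05 A22` for
invertibility, combined into `H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1]`, and
solved through the animal-model MME.  A genotyped-only GBLUP uses the same
G.  Both solvers take the variance ratio as an input rather than
estimating it; in the method-comparison experiment all three methods —
including the network sampler, whose trait variances are then held at the
same values (`estimate_trait_variances=False`) — receive the
simulation-truth components, so the comparison isolates how each method
handles non-genotyped individuals rather than differences in variance
estimation.  Marker effects are backsolved from the baseline's genomic
EBVs (`alpha = M' G^-1 a_g / sum 2p(1-p)`) for cross-method effect
correlations.

## Synthetic data

The generator emulates a livestock evaluation design:

- **Pedigree**: discrete generations, random monogamous pair mating
  without replacement, configurable founders / generations / litter size.
- **Genotypes**: biallelic SNPs gene-dropped through the pedigree;
  founder allele frequencies Uniform(0.1, 0.9) (bounds keep markers well
  away from monomorphism, which would destabilize G); Mendelian
  inheritance of one random allele per parent; markers monomorphic across
  the population are redrawn or dropped.
- **Trait**: a random subset of panel markers acts as QTL (kept inside
  the panel); raw standard-normal effects are rescaled so the realized
  genetic variance is exactly h2 * var_p (pinning heritability exactly
  rather than in expectation, which removes replicate-to-replicate
  heritability noise); residuals N(0, (1-h2) var_p).  Defaults h2 = 0.7,
  var_p = 1.
- **Test set**: the youngest individuals (final generation, id order)
  keep their genotypes but contribute no phenotype to training.
- **Masking**: whole individuals (non-genotyped animals) or individual
  cells with an exact count (mixed SNP panels); the test set is protected.

What the generator does **not** emulate: linkage/LD along chromosomes
(markers segregate independently), mutation, selection, overlapping
generations, genotyping error.  Passing tests therefore demonstrate the
estimation machinery under an idealized neutral-pedigree architecture, not
performance under LD-driven marker-QTL association or real genotyping
noise.

## The desk-scale study

The replicate experiment (`run_replicates`, `ssnnmm replicate`,
`scripts/acceptance.py`) uses: pedigree of 800 (80 founders, 9
generations, 2 offspring per mating), 200 markers of which 20 are QTL
(qtl_prop 0.1), h2 = 0.7, var_p = 1, youngest 50 as test set, masking
scenarios 30/50/70/90% of training individuals, chains of 2000 iterations
with 1000 burn-in, and 10 replicates per scenario in the test suite (5 in
the acceptance script).  The phenotype-conditioning contrast runs as two
*paired* arms — identical masks and traits per replicate, conditioning the
only difference — with 6 replicates in the suite and 3 in the script; the
mixed-panel arm uses 3.  Pedigree and genotypes are simulated once and held fixed —
they play the role of the real genotype data an evaluation would have —
while each replicate draws a fresh trait (QTL sample, effects, residuals)
and a fresh masking pattern; the trait is shared across the scenarios of
a replicate so scenario contrasts stay paired.  Replicate-to-replicate
variation therefore reflects both trait and masking randomness, and the
paired t-test between the two single-step methods is read against that
variation.  Two sizing notes:

- The QTL *count* is scaled with the panel rather than the QTL
  *fraction* of a dense array: 20 QTL at 200 markers keeps the per-QTL
  heritability near a dense-panel polygenic architecture (~3.5% each).
  With a desk-scale panel and a dense-array QTL fraction the trait
  collapses to 2-3 loci of enormous effect, a monogenic regime in which
  single-step methods genuinely diverge and phenotype-conditioned
  imputation genuinely matters — properties of that regime, not of the
  methods.
- Pedigree 800 x 200 markers keeps one 2000-iteration chain near 20 s on
  a single CPU, which is what makes a 4-scenario x 10-replicate grid with
  three methods per replicate practical.

## Numerical choices and edge cases

- Pedigree: unknown parents are unrelated founders (no genetic groups or
  metafounders); inbreeding by the Meuwissen-Luo ancestor recursion
  (near-linear, validated against the tabular diagonal); `A^-1` by
  Henderson's rules with inbreeding, validated against dense inversion at
  1e-8.
- Markers with fewer than two observed genotypes are an error; markers
  monomorphic among observed genotypes are excluded with a warning.
- A constant covariate column (c_j = 0) degrades gracefully to a draw
  from the effect prior.
- Constant phenotypes: the prior scale falls back to 1.0 when var(y) = 0;
  effects then shrink to zero.
- Sampled gene contents are unconstrained reals; on clean simulations
  ≥99% of posterior-mean imputations fall in [-0.5, 2.5] (checked, not
  clamped).
- Correlation-based accuracy raises on constant inputs rather than
  returning NaN.

## Known limitations

- Single trait, intercept-only fixed effects.
- The gene-content layer is linear; a nonlinear dosage-phenotype map
  would need an HMC step behind `missing_fullconditional`'s interface.
- `estimated` variance mode under heavy missingness inflates sigma2_e
  (imputation uncertainty leaks into the residual); variance components
  for formal method comparisons should be supplied.
- Single-process execution; the per-marker updates are independent given
  `A^-1` and the residual vector, so a parallel backend is possible but
  not provided.
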