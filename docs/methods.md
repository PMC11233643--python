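# Methods

## Overview

`mtwas` predicts genetically regulated gene expression jointly across
tissues and tests predicted expression against complex traits. The pipeline
has four stages, all operating per gene on its cis region:

1. **Imputation.** Each gene's N-sample × K-tissue expression matrix
   usually has missing entries, because no donor contributes every tissue.
   Missing entries are filled by iterative per-column random-forest
   regression on the other columns (a missForest-style scheme). Genotypes
   are never used at this stage.
2. **Cross-tissue eQTL (ct-eQTL) selection.** Principal components of the
   imputed matrix summarize expression variation shared across tissues.
   Each qualifying PC is regressed on the cis-SNP dosages with stepwise
   selection under the extended Bayesian information criterion (EBIC);
   SNPs selected for earlier PCs are carried into later PC regressions as a
   fixed set, so each PC adds only what it newly explains.
3. **Tissue-specific eQTL (ts-eQTL) selection and effect estimation.**
   Per tissue, the same EBIC stepwise search runs on the tissue's
   expression with the ct set fixed; the union of ct and ts SNPs is then
   fit by weighted least squares that down-weights imputed samples.
4. **Association.** With individual-level data, the trait is regressed on
   predicted expression Ê = Σ_j β̂_j X_j and Z = γ̂/se(γ̂) is reported. With
   GWAS summary statistics, Z ≈ Σ_j β̂_j (σ̂_j/σ̂) z_j, where σ̂² is the
   variance of the weighted SNP sum under a reference LD panel.

## Models and formulas

**EBIC.** For a selected SNP set S (always containing the fixed set S₀):

    EBIC_λ(S) = −2 ℓ_N(β̂_S) + |S| log N + 2λ |S| log M

with M the number of cis-SNP candidates and the Gaussian profile
log-likelihood ℓ_N = −(N/2)[log(2π·RSS/N) + 1]. |S| counts the full set
including S₀; since S₀ is constant within one search this does not affect
which moves are accepted, and it makes the reported criterion value an
exact recomputation of the formula on the returned set. λ defaults to 0.5,
the canonical choice for selection consistency in high-dimensional linear
models, and is exposed on the CLI (`--lambda`).

The search is: forward additions while the best single addition lowers
EBIC; backward eliminations of non-fixed terms while the best removal
lowers EBIC; then exhaustive enumeration of all subsets of the surviving
non-fixed terms (capped at 15 terms, i.e. 2^15 fits; beyond the cap the
backward result stands and the skip is logged). Ties in EBIC break to the
lowest SNP index so runs are reproducible. Interaction and quadratic terms
are out of scope.

**PC count.** Tissue columns are standardized and the correlation matrix
eigendecomposed; PCs with eigenvalue ≥ 2.0 are used (an eigenvalue of 2
means the component explains about two tissues' worth of variance), with a
floor of one PC when none qualifies. Each PC's sign is fixed to correlate
nonnegatively with mean expression across tissues, which makes selection
traces reproducible (selection itself is sign-invariant).

**WLS weights.** For a tissue with N_obs observed and N_imp imputed
samples, observed rows get weight 1 and imputed rows weight
min(1, N_obs/N_imp) — imputed samples can never outweigh observed ones.
With N_obs ≥ N_imp the fit reduces exactly to OLS; with weight w the fit
equals OLS on a dataset where each observed row appears 1/w times, which
the tests exploit as an oracle. Singular normal equations fall back to a
logged ridge (1e−8 on the diagonal).

**Summary-statistics test.** σ̂² = Σ_{j,l} β̂_j β̂_l σ̂_j σ̂_l R_{jl} is
computed from the reference panel (per-SNP SDs σ̂_j and correlations R);
when the quadratic form is numerically non-positive a ridge of
1e−6·trace(R)/m is added and flagged. Alleles are harmonized before use: a
GWAS record whose effect allele matches the weight's ref allele has its z
negated; SNPs with incompatible alleles or missing from the panel are
dropped without renormalizing β̂, and the coverage fraction is reported.
Exact fits in the individual-level test cap |Z| at 40 with a flag.

**Post-processing.** Genes overlapping the MHC
(GRCh38 chr6:28,510,120–33,480,577, bounds inclusive) are removed before
trait testing. Bonferroni correction is applied across gene-tissue tests;
BH is used for the predictable-gene FDR. Within a tissue, gene pairs whose
predicted expressions have r² > 0.5 are pruned greedily: genes are visited
in ascending P (ties on gene id) and kept only if uncorrelated with every
gene already kept. The pairwise rule leaves the multi-gene resolution
order open; greedy-by-P is this package's declared choice.

**Effective N.** Binary-trait GWAS sample sizes enter as
4·n_case·n_control/(n_case + n_control).

## Imputation details

Columns are processed in ascending-missingness order each sweep, after a
column-mean initial fill. Per column, a 100-tree regression forest
(minimum node size 5, all K−1 donor columns considered per split while
K−1 ≤ 10, √ thereafter — missForest's regression defaults adapted to small
K) is trained on the rows observed in that column and re-predicts its
missing rows. Sweeps stop the first time the relative change over imputed
entries, Δ = Σ(curr−prev)²/Σcurr², increases, at which point the previous
sweep's values are kept (the missForest stopping rule), or at `max_iter`
(default 10). Observed entries pass through bit-exactly. Tissues with
fewer than 10 observed samples for a gene are dropped for that gene;
a single remaining tissue with missing entries is an error since there are
no donor columns. In the large simulation studies shipped with the test
suite the sweep cap is set to 3: measured Δ falls from ≈0.57 (sweep 1) to
≈0.02 by sweep 3, so later sweeps change imputed values negligibly while
dominating runtime.

## Cross-validation

Five folds, assignment stratified by each sample's observed-tissue count so
every fold retains observed test entries for every tissue. For each fold,
imputation, selection and fitting use the training folds only; held-out
samples are never imputed, and prediction R² (squared Pearson correlation,
plus its signed variant and an F-test on df (1, n−2)) is computed on the
held-out observed entries, then averaged across folds. Predictable genes
are flagged at R² > 0.01 (common criterion) and BH-FDR < 0.05 of the
F-test (stringent criterion). Two ablations are evaluated alongside:
*mtwas_tissue* (imputation but one unconstrained stepwise per tissue — no
ct/ts partition) and *single_tissue* (no imputation; observed training
samples only).

## Synthetic data

The simulator provides every input the pipeline consumes; there are no
bundled datasets. Genotypes: two haplotypes per sample, each a latent
AR(1) Gaussian (adjacent correlation `ld_rho`) thresholded at the per-SNP
minor-allele quantile — a Gaussian copula giving dosages in {0,1,2} with
tunable LD; per-SNP MAFs are uniform on `maf_range` and can be pinned to
an existing cohort's MAFs to draw an independent reference panel from the
same population. Expression: E[n,k] = Σ_{j∈ct} b_j X_nj + Σ_{j∈ts(k)}
c_jk X_nj + λ_k F_n + ε_nk, with ct effects shared by all tissues, ts
effects private to one tissue, and a per-sample shared factor F (loadings
λ_k = `shared_factor_sd`) that gives the cross-tissue correlation the
imputation step exploits. Causal effects have magnitude exactly
`ct_effect_sd`/`ts_effect_sd` with independent random signs, so the
stated SD and the per-SNP effect magnitude coincide. Missingness is MCAR
per tissue (MNAR is out of scope). Traits: Y = γ·E_k + η standardized,
optional direct genotype effects via `h2_direct`; per-SNP z-scores come
from marginal regressions and LD blocks are sample correlations of the
generating (or a reference) genotype panel. All randomness flows from the
config seed through numpy's PCG64 generator.

Default architecture: N = 500 samples, M = 30 cis-SNPs, K = 6 tissues,
3 ct-eQTLs and 2 ts-eQTLs per tissue with |effect| = 0.8, unit noise and
factor SDs, 30% missingness, ld_rho = 0.3. The CV ablation study instead
uses N = 300, M = 20, K = 4, 2 ct + 1 ts per tissue with |effect| = 0.35
and factor loading 0.8 — sized so per-tissue eQTL detection is borderline
(single-tissue t ≈ 2.7 against an EBIC acceptance threshold of t ≈ 3.1)
while PC-level detection is well powered (t ≈ 3.4); this is the regime
where pooling tissues genuinely changes what is discoverable, and the
resulting CV R² (≈0.03–0.05) matches the magnitude seen for real tissues.
The identity between the summary-statistics and individual-level tests is
exercised at γ = 0.08 (≈0.6% of trait variance, a typical TWAS effect);
the approximation error of the summary-level Z grows as √N·r³/2 in the
trait-expression correlation r, so it is a small-effect approximation by
construction.

What the simulator does *not* emulate: population structure and
relatedness, MNAR missingness (e.g. expression-dependent dropout),
sequencing/count noise, trans effects, and realistic LD block structure
beyond AR(1). Passing tests therefore demonstrate correctness of the
algorithms and calibration under the stated generative model, not
performance on real cohorts.

## Numerical choices and degenerate inputs

- Stepwise fits go through a Gram-matrix cache (intercept always included,
  never penalized); a numerically perfect fit is floored at RSS =
  1e−12·Σy² so the criterion stays finite, and the public EBIC function
  rejects RSS ≤ 0 outright.
- Rank-based inverse-normal transformation uses Blom's constant c = 3/8
  with average ranks for ties; constant vectors are rejected.
- Missing dosages are mean-filled per SNP during QC; monomorphic,
  low-MAF (< 0.05) and strand-ambiguous (A/T, C/G) SNPs are removed.
- Coordinates are 1-based inclusive everywhere (VCF convention). The cis
  window defaults to ±1 Mb around the gene body, the convention of the
  major TWAS toolkits, and is configurable.
- Constant predicted expressions yield flagged null association records
  rather than errors; zero-variance predictions score R² = 0, p = 1.

## Known limitations

- The per-column forests make imputation the runtime bottleneck
  (~100 tree fits per column per sweep); genes are independent and can be
  processed in parallel by the caller, but the library itself is
  single-threaded for reproducibility.
- EBIC selection with λ = 0.5 admits a per-regression false-selection
  probability of a few percent at typical cis-SNP counts (for a null
  regression the chance of selecting nothing is ≈ (1 − P(χ²₁ > log N +
  log M))^M, e.g. ≈ 0.94 at N = 500, M = 30); across 1 + K regressions per
  gene, occasional spurious single-SNP selections on null genes are
  expected. Imputation adds a little more: imputed entries are forest
  conditional means, so imputed rows are variance-shrunk and the expression
  PC's mixture distribution mildly overdisperses the candidate-maximum
  t-statistic (measured: null ct-stage empty rate ≈ 0.92 under 30%
  missingness vs ≈ 0.95 on complete data). Raising λ trades power for
  stringency.
- The summary-statistics test assumes the reference panel matches the GWAS
  population; no cross-ancestry adjustment is attempted.
- PEER/expression-factor estimation, genotype liftover and fine-mapping
  integration are out of scope; covariates are accepted as inputs.
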