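"""Synthetic data with a cross-tissue / tissue-specific eQTL architecture.

The generator produces everything the pipeline consumes: dosage genotypes
with tunable AR(1) linkage disequilibrium, a multi-tissue expression tensor
whose genetic component splits into effects shared by every tissue and
effects private to one tissue, MCAR missingness masks, complex traits, and
marginal GWAS z-scores with block LD reference matrices. Truth objects
record the causal index sets and coefficients so selection can be scored
exactly.

Genotype model: each of the two haplotypes is a latent AR(1) Gaussian
(correlation ``ld_rho`` between adjacent SNPs) thresholded at the per-SNP
minor-allele quantile — a Gaussian-copula construction that yields dosages
in {0, 1, 2} with adjacent-SNP correlation governed by ``ld_rho``.

Expression model for sample n, tissue k:

    E[n, k] = sum_{j in ct} b_j X[n, j] + sum_{j in ts(k)} c_{jk} X[n, j]
              + lambda_k F_n + eps[n, k]

with b shared across tissues, c private to one tissue, F a per-sample
shared factor (loadings ``shared_factor_sd``) giving the cross-tissue
correlation the imputation step exploits, and Gaussian noise ``noise_sd``.
Causal effects have magnitude exactly ``ct_effect_sd`` / ``ts_effect_sd``
with independent random signs, so their SD equals the config value while
every causal SNP carries the stated effect size. All randomness flows from
``seed`` through numpy's PCG64 generator, so output is identical across
platforms for a given config.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import ExpressionTensor, GeneRecord, GenotypeMatrix, GwasSummary, LdBlock, SnpRecord


@dataclass
class SimConfig:
    n_samples: int = 500
    n_snps: int = 30
    n_tissues: int = 6
    ld_rho: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_ct_eqtls: int = 3
    n_ts_eqtls_per_tissue: int = 2
    ct_effect_sd: float = 0.8
    ts_effect_sd: float = 0.8
    noise_sd: float = 1.0
    shared_factor_sd: float = 1.0
    missing_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        needed = self.n_ct_eqtls + self.n_ts_eqtls_per_tissue * self.n_tissues
        if needed > self.n_snps:
            raise ValueError(
                f"{needed} causal SNPs requested but only {self.n_snps} simulated")
        for name in ("noise_sd",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class EqtlTruth:
    """Ground-truth architecture for scoring selection sensitivity/precision."""

    ct_indices: list[int]
    ct_effects: np.ndarray
    ts_indices: dict[int, list[int]]  # tissue -> SNP indices
    ts_effects: dict[int, np.ndarray]
    factor_loadings: np.ndarray
    shared_factor: np.ndarray = field(repr=False, default=None)


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None,
                       maf: np.ndarray | None = None) -> GenotypeMatrix:
    """Dosages as the sum of two AR(1) Gaussian-copula haplotypes.

    Passing ``maf`` fixes the per-SNP allele frequencies (e.g. to draw an
    independent reference panel from the same population as an existing
    cohort); otherwise they are drawn uniformly from ``cfg.maf_range``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n, m, rho = cfg.n_samples, cfg.n_snps, cfg.ld_rho
    maf = rng.uniform(*cfg.maf_range, size=m) if maf is None else np.asarray(maf, float)
    thresh = stats.norm.ppf(maf)
    dosage = np.zeros((n, m))
    for _hap in range(2):
        z = np.empty((n, m))
        z[:, 0] = rng.standard_normal(n)
        innov = rng.standard_normal((n, m - 1)) if m > 1 else None
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * innov[:, j - 1]
        dosage += (z < thresh[None, :]).astype(float)
    snps = [SnpRecord(id=f"rs{j + 1}", chrom="1", pos=1000 * (j + 1),
                      ref_allele="A", alt_allele="C", maf=float(maf[j]))
            for j in range(m)]
    samples = [f"S{i + 1}" for i in range(n)]
    return GenotypeMatrix(samples=samples, snps=snps, dosages=dosage)


def _signed_effects(rng: np.random.Generator, k: int, magnitude: float) -> np.ndarray:
    return magnitude * rng.choice([-1.0, 1.0], size=k)


def simulate_expression(
    g: GenotypeMatrix, cfg: SimConfig, rng: np.random.Generator | None = None,
    gene: GeneRecord | None = None,
) -> tuple[ExpressionTensor, EqtlTruth]:
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n, m, k = g.n_samples, g.n_snps, cfg.n_tissues
    needed = cfg.n_ct_eqtls + cfg.n_ts_eqtls_per_tissue * k
    if needed > m:
        raise ValueError("requested eQTL counts exceed the number of SNPs")
    causal = rng.choice(m, size=needed, replace=False)
    ct_idx = sorted(int(i) for i in causal[: cfg.n_ct_eqtls])
    ts_idx: dict[int, list[int]] = {}
    off = cfg.n_ct_eqtls
    for t in range(k):
        ts_idx[t] = sorted(int(i) for i in
                           causal[off + t * cfg.n_ts_eqtls_per_tissue:
                                  off + (t + 1) * cfg.n_ts_eqtls_per_tissue])

    b = _signed_effects(rng, len(ct_idx), cfg.ct_effect_sd)
    ts_eff = {t: _signed_effects(rng, len(ts_idx[t]), cfg.ts_effect_sd) for t in range(k)}
    lam = np.full(k, cfg.shared_factor_sd)
    F = rng.standard_normal(n)

    X = g.dosages
    genetic_ct = X[:, ct_idx] @ b if ct_idx else np.zeros(n)
    E = np.empty((n, k))
    for t in range(k):
        genetic_ts = X[:, ts_idx[t]] @ ts_eff[t] if ts_idx[t] else np.zeros(n)
        E[:, t] = genetic_ct + genetic_ts + lam[t] * F \
            + cfg.noise_sd * rng.standard_normal(n)

    if gene is None:
        gene = GeneRecord(id="gene1", chrom="1", start=1, end=1000 * m + 1000)
    tensor = ExpressionTensor(
        gene=gene, samples=list(g.samples),
        tissues=[f"T{t + 1}" for t in range(k)],
        values=E, observed_mask=np.ones((n, k), dtype=bool))
    truth = EqtlTruth(ct_indices=ct_idx, ct_effects=b, ts_indices=ts_idx,
                      ts_effects=ts_eff, factor_loadings=lam, shared_factor=F)
    return tensor, truth


def mask_missing(e: ExpressionTensor, cfg: SimConfig,
                 rng: np.random.Generator | None = None) -> ExpressionTensor:
    """Per-tissue MCAR masking at ``cfg.missing_rate``.

    Raises if any tissue would retain fewer than 2 observed samples.
    """
    if not e.observed_mask.all():
        raise ValueError("input tensor must be fully observed")
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    mask = rng.random((e.n_samples, e.n_tissues)) >= cfg.missing_rate
    if (mask.sum(axis=0) < 2).any():
        raise ValueError("missing_rate leaves a tissue with < 2 observed samples")
    out = e.copy()
    out.observed_mask = mask
    out.values = e.values.copy()
    out.values[~mask] = np.nan
    return out


def simulate_gwas(
    g: GenotypeMatrix, e_true: ExpressionTensor, gamma: float, tissue: int,
    h2_direct: float = 0.0, seed: int = 0, block_size: int | None = None,
) -> tuple[GwasSummary, list[LdBlock], np.ndarray]:
    """Trait Y = E_tissue * gamma + eta (standardized) and its marginal
    per-SNP z-scores, plus LD blocks computed from the generating sample.

    ``h2_direct`` adds genotype effects on the trait that bypass expression,
    drawn so they explain that fraction of trait variance.
    """
    if not (0 <= h2_direct < 1):
        raise ValueError("h2_direct must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = g.n_samples
    expr = e_true.values[:, tissue]
    expr_std = (expr - expr.mean()) / expr.std()
    y = gamma * expr_std + rng.standard_normal(n)
    if h2_direct > 0:
        w = rng.standard_normal(g.n_snps)
        direct = g.dosages @ w
        direct = (direct - direct.mean()) / direct.std()
        y = y + direct * np.sqrt(h2_direct / (1 - h2_direct)) * y.std()
    y = (y - y.mean()) / y.std()

    X = g.dosages
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    r = (Xc / sd).T @ y / n  # corr(Y, X_j); y standardized
    r = np.clip(r, -0.999999, 0.999999)
    z = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)

    summ = GwasSummary(
        snp_ids=g.snp_ids,
        effect_alleles=[s.alt_allele for s in g.snps],
        other_alleles=[s.ref_allele for s in g.snps],
        z=z, n_gwas=np.full(g.n_snps, float(n)))
    blocks = ld_blocks_from_genotypes(g, block_size=block_size)
    return summ, blocks, y


def ld_blocks_from_genotypes(g: GenotypeMatrix,
                             block_size: int | None = None) -> list[LdBlock]:
    """Sample-correlation LD blocks over contiguous SNP runs."""
    m = g.n_snps
    block_size = m if block_size is None else block_size
    blocks = []
    for start in range(0, m, block_size):
        idx = list(range(start, min(start + block_size, m)))
        sub = g.dosages[:, idx]
        corr = np.corrcoef(sub, rowvar=False)
        corr = np.atleast_2d(corr)
        blocks.append(LdBlock(snp_ids=[g.snps[i].id for i in idx],
                              corr=corr, snp_sd=sub.std(axis=0, ddof=1)))
    return blocks
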