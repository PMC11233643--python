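"""Core in-memory containers shared across the pipeline.

All containers are thin dataclasses over numpy arrays with explicit sample /
SNP / tissue orderings, so every stage can be checked for alignment cheaply.
Coordinates are 1-based inclusive (VCF convention) throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class SnpRecord:
    """A single bi-allelic variant; dosages elsewhere count ``alt_allele``."""

    id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    maf: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.id}: position must be >= 1, got {self.pos}")

    @property
    def is_strand_ambiguous(self) -> bool:
        return (self.ref_allele.upper(), self.alt_allele.upper()) in AMBIGUOUS_PAIRS


@dataclass(frozen=True)
class GeneRecord:
    """Genomic footprint of a gene; start/end are 1-based inclusive."""

    id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start > end")


@dataclass
class GenotypeMatrix:
    """N samples x M SNPs dosage matrix on the 0-2 alt-allele scale.

    Missing dosages are NaN until :func:`mtwas.data_io.qc_genotypes` replaces
    them with the per-SNP mean.
    """

    samples: list[str]
    snps: list[SnpRecord]
    dosages: np.ndarray  # (N, M) float

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency from mean dosage (NaN-aware)."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = list(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[i] for i in index],
            dosages=self.dosages[:, index].copy(),
        )

    def subset_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = list(index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            snps=list(self.snps),
            dosages=self.dosages[index, :].copy(),
        )

    def with_maf(self) -> "GenotypeMatrix":
        maf = self.maf()
        snps = [replace(s, maf=float(m)) for s, m in zip(self.snps, maf)]
        return GenotypeMatrix(samples=list(self.samples), snps=snps, dosages=self.dosages.copy())


@dataclass
class ExpressionTensor:
    """Per-gene N-sample x K-tissue expression with an observed-entry mask."""

    gene: GeneRecord
    samples: list[str]
    tissues: list[str]
    values: np.ndarray  # (N, K) float
    observed_mask: np.ndarray  # (N, K) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        shape = (len(self.samples), len(self.tissues))
        if self.values.shape != shape or self.observed_mask.shape != shape:
            raise ValueError("values/mask shape does not match samples x tissues")
        if not np.all(np.isfinite(self.values[self.observed_mask])):
            raise ValueError("observed entries must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)

    def n_obs(self) -> np.ndarray:
        """Per-tissue observed sample counts (N_obs; N_imp = N - N_obs)."""
        return self.observed_mask.sum(axis=0)

    def copy(self) -> "ExpressionTensor":
        return ExpressionTensor(
            gene=self.gene,
            samples=list(self.samples),
            tissues=list(self.tissues),
            values=self.values.copy(),
            observed_mask=self.observed_mask.copy(),
        )


@dataclass
class CovariateTable:
    samples: list[str]
    names: list[str]
    values: np.ndarray  # (N, C)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.names)):
            raise ValueError("covariate shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariates contain missing values")


@dataclass
class TissueWeights:
    """Fitted per-tissue prediction model: effects of the selected eQTLs."""

    tissue: str
    snp_ids: list[str]
    beta: np.ndarray
    intercept: float
    sigma_hat: float
    classes: list[str]  # "ct" or "ts", parallel to snp_ids
    n_obs: int
    n_imp: int


@dataclass
class EqtlModel:
    """Trained model for one gene: the ct-eQTL set, per-tissue ts-eQTL sets
    and per-tissue weighted-least-squares effect estimates."""

    gene: GeneRecord
    ct_set: list[str]
    ts_sets: dict[str, list[str]]
    weights: dict[str, TissueWeights]
    pc_count: int = 0

    def predict(self, geno: GenotypeMatrix, tissue: str) -> np.ndarray:
        w = self.weights[tissue]
        if not w.snp_ids:
            return np.full(geno.n_samples, w.intercept)
        col = {s: i for i, s in enumerate(geno.snp_ids)}
        idx = [col[s] for s in w.snp_ids]
        return geno.dosages[:, idx] @ w.beta + w.intercept


@dataclass
class GwasSummary:
    """Per-SNP GWAS z-scores with effect/other alleles and sample size."""

    snp_ids: list[str]
    effect_alleles: list[str]
    other_alleles: list[str]
    z: np.ndarray
    n_gwas: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.n_gwas = np.asarray(self.n_gwas, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("GWAS z-scores must be finite")

    def lookup(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.snp_ids)}


@dataclass
class LdBlock:
    """Reference LD: SNP correlation matrix plus dosage-scale SDs."""

    snp_ids: list[str]
    corr: np.ndarray
    snp_sd: np.ndarray

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        self.snp_sd = np.asarray(self.snp_sd, dtype=float)
        m = len(self.snp_ids)
        if self.corr.shape != (m, m):
            raise ValueError("LD matrix shape mismatch")
        if not np.allclose(self.corr, self.corr.T, atol=1e-10):
            raise ValueError("LD matrix must be symmetric")


@dataclass
class GeneAssociation:
    """Gene x tissue association record (Z = gamma_hat / se)."""

    gene: str
    tissue: str
    z: float
    p: float
    p_adjusted: float = float("nan")
    prediction_r2: float = float("nan")
    n_eqtls_used: int = 0
    flags: list[str] = field(default_factory=list)
    kept_after_pruning: bool = True
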