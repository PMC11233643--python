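"""Readers, writers and preprocessing for genotype / expression / GWAS data.

Genotypes are accepted as VCF (plain or bgzipped, via cyvcf2), PLINK
bed/bim/fam, or a plain dosage TSV (rows = samples, header columns formatted
``chrom:pos:ref:alt``). Expression comes as GCT 1.2 or TSV, one file per
tissue (rows = genes, columns = samples). All coordinates are 1-based
inclusive; BED-half-open inputs must be converted by the caller.
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    CovariateTable,
    GeneRecord,
    GenotypeMatrix,
    GwasSummary,
    LdBlock,
    SnpRecord,
)

log = logging.getLogger(__name__)

PLINK_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes into a dosage matrix on the 0-2 alt-allele scale.

    Sample and SNP order follow file order. Missing genotypes become NaN
    (cleaned later by :func:`qc_genotypes`). Duplicated SNP ids are an error.
    """
    path = Path(path)
    if not path.exists() and format != "plink":
        raise FileNotFoundError(path)
    if format == "vcf":
        g = _read_vcf(path)
    elif format == "plink":
        g = _read_plink(path)
    elif format == "tsv":
        g = _read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")
    ids = g.snp_ids
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicated SNP id(s): {dup[:5]}")
    return g.with_maf()


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snps: list[SnpRecord] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if var.ALT is None or len(var.ALT) != 1:
            raise ValueError(f"non-biallelic record at {var.CHROM}:{var.POS}")
        gt = np.asarray(var.genotype.array())[:, :2].astype(float)
        gt[gt < 0] = np.nan  # missing allele calls
        cols.append(gt.sum(axis=1))
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}"
        snps.append(SnpRecord(id=vid, chrom=str(var.CHROM), pos=int(var.POS),
                              ref_allele=var.REF, alt_allele=var.ALT[0]))
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(samples=samples, snps=snps, dosages=dosages)


def _read_plink(prefix: Path) -> GenotypeMatrix:
    """Minimal PLINK 1 bed/bim/fam reader (SNP-major 2-bit encoding).

    A1 in the .bim is taken as the counted (alt) allele, so dosages match the
    VCF reader on the same data.
    """
    prefix = Path(str(prefix).removesuffix(".bed"))
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str})
    samples = [str(s) for s in fam[1]]
    n, m = len(samples), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != PLINK_BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK bed)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if len(body) != bytes_per_snp * m:
        raise ValueError(f"{prefix}.bed: truncated (expected {bytes_per_snp * m} data bytes)")
    body = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11  # (m, bytes, 4)
    codes = codes.reshape(m, -1)[:, :n]
    # 00 -> hom A1 (2), 10 -> het (1), 11 -> hom A2 (0), 01 -> missing
    dose = np.choose(codes, [2.0, np.nan, 1.0, 0.0]).T
    snps = [SnpRecord(id=str(r.id), chrom=str(r.chrom), pos=int(r.pos),
                      ref_allele=str(r.a2), alt_allele=str(r.a1))
            for r in bim.itertuples()]
    return GenotypeMatrix(samples=samples, snps=snps, dosages=dose)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    snps = []
    for col in df.columns:
        parts = str(col).split(":")
        if len(parts) != 4:
            raise ValueError(f"{path}: column {col!r} is not chrom:pos:ref:alt")
        chrom, pos, ref, alt = parts
        snps.append(SnpRecord(id=str(col), chrom=chrom, pos=int(pos),
                              ref_allele=ref, alt_allele=alt))
    return GenotypeMatrix(samples=[str(s) for s in df.index], snps=snps,
                          dosages=df.to_numpy(dtype=float))


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write hard-call genotypes as a plain VCF (dosages rounded to 0/1/2)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({s.chrom for s in g.snps})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, s in enumerate(g.snps):
            calls = []
            for d in g.dosages[:, j]:
                calls.append("./." if np.isnan(d) else gt_map[int(round(d))])
            fh.write(f"{s.chrom}\t{s.pos}\t{s.id}\t{s.ref_allele}\t{s.alt_allele}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write hard-call genotypes as a PLINK bed/bim/fam triplet."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in g.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in g.snps:
            fh.write(f"{s.chrom}\t{s.id}\t0\t{s.pos}\t{s.alt_allele}\t{s.ref_allele}\n")
    n = g.n_samples
    bytes_per_snp = (n + 3) // 4
    code_for = {2: 0b00, 1: 0b10, 0: 0b11}
    out = bytearray(PLINK_BED_MAGIC)
    for j in range(g.n_snps):
        codes = np.full(bytes_per_snp * 4, 0b01, dtype=np.uint8)  # missing pad
        for i, d in enumerate(g.dosages[:, j]):
            codes[i] = 0b01 if np.isnan(d) else code_for[int(round(d))]
        packed = (codes.reshape(-1, 4) << (np.arange(4) * 2)[None, :]).sum(axis=1)
        out.extend(packed.astype(np.uint8).tobytes())
    prefix.with_suffix(".bed").write_bytes(bytes(out))


def write_dosage_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    cols = [f"{s.chrom}:{s.pos}:{s.ref_allele}:{s.alt_allele}" for s in g.snps]
    pd.DataFrame(g.dosages, index=g.samples, columns=cols).to_csv(
        path, sep="\t", index_label="sample")


def qc_genotypes(g: GenotypeMatrix, maf_threshold: float = 0.05,
                 drop_ambiguous: bool = True,
                 whitelist: set[str] | None = None) -> GenotypeMatrix:
    """Standard variant QC: MAF filter, strand-ambiguity filter, mean-fill.

    Missing dosages are replaced by the SNP's mean observed dosage. An
    optional whitelist (e.g. a HapMap3 rsID list) restricts the SNP set.
    Idempotent: running twice equals running once.
    """
    maf = g.maf()
    keep = []
    for j, s in enumerate(g.snps):
        if whitelist is not None and s.id not in whitelist:
            continue
        if np.isnan(maf[j]) or maf[j] < maf_threshold:
            continue
        if drop_ambiguous and s.is_strand_ambiguous:
            continue
        keep.append(j)
    if not keep:
        warnings.warn("all SNPs removed by QC; returning empty matrix")
    dosages = g.dosages[:, keep].copy()
    for jj in range(dosages.shape[1]):
        col = dosages[:, jj]
        miss = np.isnan(col)
        if miss.any():
            col[miss] = np.nanmean(col)
    out = GenotypeMatrix(samples=list(g.samples),
                         snps=[g.snps[j] for j in keep], dosages=dosages)
    return out.with_maf()


def cis_window(gene: GeneRecord, g: GenotypeMatrix,
               window_bp: int = 1_000_000) -> GenotypeMatrix:
    """SNPs on the gene's chromosome within ``window_bp`` of its body.

    Retains pos in [start - window_bp, end + window_bp], bounds inclusive.
    """
    if not any(s.chrom == gene.chrom for s in g.snps):
        warnings.warn(f"chromosome {gene.chrom} absent from genotype matrix")
    lo, hi = gene.start - window_bp, gene.end + window_bp
    keep = [j for j, s in enumerate(g.snps)
            if s.chrom == gene.chrom and lo <= s.pos <= hi]
    return g.subset_snps(keep)


# ---------------------------------------------------------------------------
# expression / covariates
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> pd.DataFrame:
    """One tissue's expression as a genes x samples DataFrame (GCT 1.2 or TSV)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    # round_trip parsing keeps write -> read -> write bit-stable
    if first.startswith("#1.2"):
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0,
                         float_precision="round_trip")
        df = df.drop(columns=[c for c in ("Description",) if c in df.columns])
    else:
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CovariateTable(samples=[str(s) for s in df.index],
                          names=list(df.columns),
                          values=df.to_numpy(dtype=float))


def read_snp_whitelist(path: str | Path) -> set[str]:
    return {line.strip() for line in open(path) if line.strip()}


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def inverse_normal_transform(x: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    Maps x to Phi^{-1}((rank - c) / (N - 2c + 1)); ties get average ranks.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant vector carries no rank information")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - c) / (n - 2 * c + 1))


def residualize(y: np.ndarray, cov: CovariateTable | np.ndarray | None) -> np.ndarray:
    """Least-squares residuals of y on [1, covariates].

    Raises on a rank-deficient design, naming the collinear column(s).
    """
    y = np.asarray(y, dtype=float)
    if cov is None:
        return y - y.mean()
    if isinstance(cov, CovariateTable):
        C, names = cov.values, cov.names
    else:
        C = np.asarray(cov, dtype=float)
        names = [f"c{i}" for i in range(C.shape[1])]
    design = np.column_stack([np.ones(len(y)), C])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify the first column whose addition does not raise the rank
        bad = []
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) == np.linalg.matrix_rank(design[:, :j]):
                bad.append(names[j - 1])
        raise ValueError(f"rank-deficient covariate design; collinear column(s): {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


# ---------------------------------------------------------------------------
# GWAS summary statistics and LD blocks
# ---------------------------------------------------------------------------

def read_sumstats(path: str | Path) -> GwasSummary:
    """TSV with columns SNP, A1 (effect), A2 (other), Z, N."""
    df = pd.read_csv(path, sep="\t")
    required = {"SNP", "A1", "A2", "Z", "N"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sumstats missing column(s): {sorted(missing)}")
    return GwasSummary(snp_ids=[str(s) for s in df["SNP"]],
                       effect_alleles=[str(a) for a in df["A1"]],
                       other_alleles=[str(a) for a in df["A2"]],
                       z=df["Z"].to_numpy(float), n_gwas=df["N"].to_numpy(float))


def write_sumstats(s: GwasSummary, path: str | Path) -> None:
    pd.DataFrame({"SNP": s.snp_ids, "A1": s.effect_alleles, "A2": s.other_alleles,
                  "Z": s.z, "N": s.n_gwas}).to_csv(path, sep="\t", index=False)


def write_ld_blocks(blocks: list[LdBlock], outdir: str | Path) -> None:
    """One matrix TSV per block plus an index TSV mapping SNPs to blocks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for b_i, blk in enumerate(blocks):
        pd.DataFrame(blk.corr, index=blk.snp_ids, columns=blk.snp_ids).to_csv(
            outdir / f"block_{b_i:04d}.tsv", sep="\t", index_label="snp")
        for sid, sd in zip(blk.snp_ids, blk.snp_sd):
            rows.append({"snp": sid, "block": b_i, "sd": sd})
    pd.DataFrame(rows).to_csv(outdir / "index.tsv", sep="\t", index=False)


def read_ld_blocks(indir: str | Path) -> list[LdBlock]:
    indir = Path(indir)
    index = pd.read_csv(indir / "index.tsv", sep="\t")
    blocks = []
    for b_i, grp in index.groupby("block", sort=True):
        mat = pd.read_csv(indir / f"block_{b_i:04d}.tsv", sep="\t", index_col=0)
        blocks.append(LdBlock(snp_ids=[str(s) for s in grp["snp"]],
                              corr=mat.to_numpy(float),
                              snp_sd=grp["sd"].to_numpy(float)))
    return blocks


def intersect_samples(g: GenotypeMatrix, sample_sets: list[list[str]]) -> list[str]:
    """Samples present in the genotypes and every expression set; samples
    lacking genotypes are dropped with a logged count."""
    geno = set(g.samples)
    union_expr: set[str] = set()
    for s in sample_sets:
        union_expr |= set(s)
    dropped = len(union_expr - geno)
    if dropped:
        log.info("dropping %d expression samples without genotypes", dropped)
    kept = [s for s in g.samples if s in union_expr]
    return kept
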