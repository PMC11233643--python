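"""Gene-trait association from individual-level data or GWAS summary stats.

Individual-level route: regress the (standardized) trait on the
(standardized) genetically predicted expression E_hat = sum_j beta_j X_j and
report Z = gamma_hat / se(gamma_hat).

Summary-statistics route: with per-SNP GWAS z-scores z_j, trained weights
beta_j, reference per-SNP SDs sigma_j and a reference LD correlation matrix
R, the gene-level score is

    Z = sum_j beta_j (sigma_j / sigma) z_j,
    sigma^2 = sum_{j,l} beta_j beta_l sigma_j sigma_l R_{jl},

i.e. the variance of the predicted expression under the LD reference.
Alleles are harmonized before use: a flip of effect/other alleles negates
z_j together with the weight orientation, leaving Z invariant.

Post-processing utilities: MHC-region masking (GRCh38), Bonferroni / BH
adjustment, greedy pruning of correlated predicted expressions, effective
sample size for binary traits, and held-out prediction metrics.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import GeneAssociation, GwasSummary, LdBlock

log = logging.getLogger(__name__)

MHC_GRCH38 = ("6", 28_510_120, 33_480_577)  # 6p21.3, inclusive
Z_CAP = 40.0


def zscore_individual(y: np.ndarray, e_hat: np.ndarray) -> tuple[float, float, list[str]]:
    """Slope and z-score of the trait on predicted expression.

    Both vectors are standardized internally; se uses N - 2 df. A constant
    prediction yields a flagged null record; an exact fit caps |z| at 40.
    Returns (gamma_hat, z, flags).
    """
    y = np.asarray(y, float)
    e_hat = np.asarray(e_hat, float)
    n = len(y)
    if n < 3 or len(e_hat) != n:
        raise ValueError("need aligned vectors of length >= 3")
    if e_hat.std() == 0:
        return float("nan"), float("nan"), ["constant_prediction"]
    ys = (y - y.mean()) / y.std()
    es = (e_hat - e_hat.mean()) / e_hat.std()
    r = float(np.clip(ys @ es / n, -1.0, 1.0))
    gamma = r  # slope of standardized-on-standardized regression
    if 1.0 - r**2 < 1e-14:
        return gamma, float(np.sign(r) * Z_CAP), ["exact_fit"]
    z = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    return gamma, float(z), []


def harmonize_weights(
    snp_ids: list[str], beta: np.ndarray, ref_alleles: list[str],
    alt_alleles: list[str], gwas: GwasSummary,
) -> tuple[list[str], np.ndarray, np.ndarray, float]:
    """Align trained weights with GWAS alleles.

    Weights are trained on the alt-allele dosage scale; a GWAS record whose
    effect allele equals the weight's ref allele has its z negated. SNPs
    absent from the GWAS (or with incompatible alleles) are dropped; the
    coverage fraction is returned and logged.
    """
    lut = gwas.lookup()
    keep_ids, keep_beta, keep_z = [], [], []
    for sid, b, ref, alt in zip(snp_ids, beta, ref_alleles, alt_alleles):
        i = lut.get(sid)
        if i is None:
            continue
        ea, oa = gwas.effect_alleles[i].upper(), gwas.other_alleles[i].upper()
        if (ea, oa) == (alt.upper(), ref.upper()):
            keep_z.append(gwas.z[i])
        elif (ea, oa) == (ref.upper(), alt.upper()):
            keep_z.append(-gwas.z[i])
        else:
            continue
        keep_ids.append(sid)
        keep_beta.append(b)
    coverage = len(keep_ids) / len(snp_ids) if snp_ids else 0.0
    if coverage < 1.0:
        log.info("sumstats coverage %.2f (%d/%d SNPs)", coverage,
                 len(keep_ids), len(snp_ids))
    return keep_ids, np.asarray(keep_beta, float), np.asarray(keep_z, float), coverage


def zscore_sumstats(
    snp_ids: list[str], beta: np.ndarray, z: np.ndarray, ld: LdBlock,
    ridge_scale: float = 1e-6,
) -> tuple[float, list[str]]:
    """Gene-level Z from harmonized weights, GWAS z-scores and reference LD.

    ``sigma_hat`` is the SD of the weighted SNP sum under the LD reference;
    a small ridge (ridge_scale * trace(R)/m) keeps the quadratic form
    positive. Returns (Z, flags).
    """
    beta = np.asarray(beta, float)
    z = np.asarray(z, float)
    lut = {s: i for i, s in enumerate(ld.snp_ids)}
    idx = [lut[s] for s in snp_ids if s in lut]
    if len(idx) < len(snp_ids):
        keep = [k for k, s in enumerate(snp_ids) if s in lut]
        beta, z = beta[keep], z[keep]
    if len(idx) == 0:
        return float("nan"), ["no_snps_in_ld"]
    R = ld.corr[np.ix_(idx, idx)]
    m = R.shape[0]
    sd = ld.snp_sd[idx]
    w = beta * sd
    var = float(w @ R @ w)
    flags: list[str] = []
    if var <= 1e-12 * float(w @ w):
        # near-singular LD: regularize the quadratic form to keep it positive
        Rr = R + np.eye(m) * (ridge_scale * np.trace(R) / m)
        var = float(w @ Rr @ w)
        flags.append("ridge_regularized")
        if var <= 1e-12:
            return float("nan"), ["degenerate_variance"]
    sigma = np.sqrt(var)
    return float(np.sum(beta * sd / sigma * z)), flags


def mask_mhc(records: list, build: str = "GRCh38") -> list:
    """Drop records overlapping the MHC (chr6:28,510,120-33,480,577, GRCh38).

    Records need ``chrom``, ``start``, ``end`` attributes; single-position
    records may use ``pos`` for both bounds.
    """
    if build != "GRCh38":
        raise ValueError(f"unknown genome build: {build}")
    chrom, lo, hi = MHC_GRCH38
    out = []
    for r in records:
        c = str(getattr(r, "chrom")).removeprefix("chr")
        start = getattr(r, "start", None)
        end = getattr(r, "end", None)
        if start is None:
            start = end = getattr(r, "pos")
        if c == chrom and start <= hi and end >= lo:
            continue
        out.append(r)
    return out


def adjust_pvalues(p: np.ndarray, method: str = "bonferroni") -> np.ndarray:
    p = np.asarray(p, float)
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown method: {method}")


def prune_correlated_genes(
    assoc: list[GeneAssociation], predicted: dict[str, np.ndarray],
    r2_threshold: float = 0.5,
) -> list[GeneAssociation]:
    """Greedy within-tissue pruning of genes with correlated predictions.

    Genes are visited in ascending P (ties break on gene id); a gene is kept
    iff its predicted expression has r^2 <= threshold with every gene kept
    so far. Constant predictions count as r^2 = 0 and are flagged. Each
    record's ``kept_after_pruning`` is set; the kept subset is returned.
    """
    order = sorted(assoc, key=lambda a: (a.p, a.gene))
    kept: list[GeneAssociation] = []
    for a in order:
        x = predicted[a.gene]
        ok = True
        for b in kept:
            y = predicted[b.gene]
            if x.std() == 0 or y.std() == 0:
                if "constant_prediction" not in a.flags and x.std() == 0:
                    a.flags.append("constant_prediction")
                continue
            r = np.corrcoef(x, y)[0, 1]
            if r**2 > r2_threshold:
                ok = False
                break
        a.kept_after_pruning = ok
        if ok:
            kept.append(a)
    return kept


def effective_n(n_case: int, n_control: int) -> float:
    """Effective sample size of a binary GWAS: 4 n1 n0 / (n1 + n0)."""
    if n_case <= 0 or n_control <= 0:
        raise ValueError("case and control counts must be positive")
    return 4.0 * n_case * n_control / (n_case + n_control)


@dataclass
class PredictionMetrics:
    r2: float
    signed_r2: float
    f_pvalue: float
    flags: list[str]


def evaluate_prediction(y_true: np.ndarray, y_pred: np.ndarray) -> PredictionMetrics:
    """Held-out prediction accuracy: squared Pearson correlation, its signed
    variant, and the F-test p-value on (1, n-2) degrees of freedom.

    The common predictable-gene criterion is r2 > 0.01; the stringent one
    applies BH FDR to the F-test p across genes (done by the caller).
    """
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    n = len(y_true)
    if n < 4:
        raise ValueError("need n >= 4")
    if y_pred.std() == 0 or y_true.std() == 0:
        return PredictionMetrics(0.0, 0.0, 1.0, ["zero_variance"])
    r = float(np.corrcoef(y_true, y_pred)[0, 1])
    r2 = r**2
    flags = ["predictable_common"] if r2 > 0.01 else []
    if 1.0 - r2 < 1e-14:
        return PredictionMetrics(1.0, float(np.sign(r)), 0.0, flags + ["exact_fit"])
    fstat = r2 * (n - 2) / (1.0 - r2)
    p = float(stats.f.sf(fstat, 1, n - 2))
    return PredictionMetrics(r2, float(np.sign(r) * r2), p, flags)


def p_from_z(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))
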