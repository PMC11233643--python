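import numpy as np
import pytest

from mtwas.types import ExpressionTensor, GeneRecord, GenotypeMatrix, SnpRecord


def make_genotypes(dosages, chrom="1", start_pos=1000, step=1000,
                   ref="A", alt="C", ids=None) -> GenotypeMatrix:
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snps = [SnpRecord(id=ids[j] if ids else f"rs{j + 1}", chrom=chrom,
                      pos=start_pos + j * step, ref_allele=ref, alt_allele=alt)
            for j in range(m)]
    return GenotypeMatrix(samples=[f"S{i + 1}" for i in range(n)],
                          snps=snps, dosages=dosages)


def make_tensor(values, mask=None, gene=None) -> ExpressionTensor:
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    if mask is None:
        mask = np.isfinite(values)
    if gene is None:
        gene = GeneRecord(id="geneX", chrom="1", start=1, end=10_000_000)
    return ExpressionTensor(gene=gene, samples=[f"S{i + 1}" for i in range(n)],
                            tissues=[f"T{t + 1}" for t in range(k)],
                            values=values, observed_mask=np.asarray(mask, bool))


def f1_score(selected, truth) -> float:
    selected, truth = set(selected), set(truth)
    if not selected and not truth:
        return 1.0
    tp = len(selected & truth)
    return 2.0 * tp / (len(selected) + len(truth))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
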