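import numpy as np
import pytest

from rfgrs import GenotypeMatrix, PhenotypeTable, SummaryStats, VariantInfo


def make_genotypes(counts, chrom="1", spacing=1000, start=1000,
                   ids=None) -> GenotypeMatrix:
    """GenotypeMatrix from a literal count matrix; positions evenly spaced."""
    counts = np.asarray(counts, dtype=np.int8)
    n, m = counts.shape
    snps = []
    for j in range(m):
        col = counts[:, j]
        obs = col[col != -9]
        maf = float(obs.mean() / 2) if obs.size else 0.0
        maf = min(maf, 0.5)
        snps.append(VariantInfo(
            id=(ids[j] if ids else f"rs{j+1}"), chrom=chrom,
            pos=start + j * spacing, ref_allele="A", alt_allele="G", maf=maf))
    return GenotypeMatrix(samples=[f"s{i+1}" for i in range(n)],
                          snps=snps, counts=counts)


def make_stats(ids, p, beta=None, allele="G") -> SummaryStats:
    ids = list(ids)
    p = np.asarray(p, float)
    return SummaryStats(
        ids=np.asarray(ids, object),
        effect_allele=np.asarray([allele] * len(ids), object),
        beta=np.zeros(len(ids)) if beta is None else np.asarray(beta, float),
        p=p)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_cohort(rng):
    """150 samples x 40 SNPs with a real signal in the first 4 SNPs."""
    import rfgrs

    spec = rfgrs.LDBlockSpec.uniform_blocks(40, block_size=8, rho=0.5,
                                            maf_range=(0.1, 0.5))
    G = rfgrs.simulate_genotypes(150, spec, seed=101)
    eta = (G.counts[:, :4].astype(float) @ np.array([0.9, -0.8, 0.7, 0.9]))
    eta -= eta.mean()
    y = (rng.random(150) < 1 / (1 + np.exp(-eta))).astype(np.int8)
    if y.min() == y.max():  # pragma: no cover - seed chosen to avoid this
        y[0] = 1 - y[0]
    return G, PhenotypeTable(samples=G.samples, y=y)
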