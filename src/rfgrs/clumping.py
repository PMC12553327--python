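"""Greedy LD clumping and p-value thresholding (the "C" and "T" steps).

Clumping repeatedly takes the most significant unassigned SNP as an index
SNP and discards every unassigned SNP within ``window_bp`` base pairs whose
genotype r-squared with it exceeds ``r2_cutoff``; discarded SNPs never seed
their own clump. Thresholding keeps SNPs with p strictly below the cutoff.
Both operate on association results aligned with target-training genotypes —
LD is always computed from the training samples, never test samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GenotypeMatrix, SummaryStats


@dataclass(frozen=True)
class ClumpParams:
    """Clumping/thresholding hyperparameters.

    ``r2_cutoff`` in (0, 1]: neighbors with r^2 strictly above it are removed.
    ``window_bp``: inclusive base-pair distance within which LD is considered
    (250 kb default, the standard clumping convention). ``p_threshold`` in
    (0, 1]: strict upper bound for the thresholding step.
    """

    r2_cutoff: float = 0.5
    window_bp: int = 250_000
    p_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_cutoff <= 1.0):
            raise ValueError(f"r2_cutoff must be in (0, 1], got {self.r2_cutoff}")
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError(f"p_threshold must be in (0, 1], got {self.p_threshold}")
        if self.window_bp < 0:
            raise ValueError("window_bp must be non-negative")


def pairwise_r2(G: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of the genotype count vectors of SNPs i, j.

    Invariant to allele orientation (x vs 2-x). Monomorphic SNPs have no
    defined correlation and raise.
    """
    xi = G.counts[:, i].astype(np.float64)
    xj = G.counts[:, j].astype(np.float64)
    if xi.std() == 0.0 or xj.std() == 0.0:
        raise ValueError("pairwise r2 undefined for a monomorphic SNP")
    r = np.corrcoef(xi, xj)[0, 1]
    return float(r * r)


def clump(stats: SummaryStats, G: GenotypeMatrix, params: ClumpParams,
          ) -> list[str]:
    """Greedy LD clumping of ``stats`` against the genotypes in ``G``.

    Returns the index SNPs in p-ascending order; ties in p are broken by
    (chrom, pos, id). SNPs absent from ``G`` are an error; an empty ``stats``
    yields an empty list.
    """
    if len(stats) == 0:
        return []
    gidx = {s.id: j for j, s in enumerate(G.snps)}
    unknown = [i for i in stats.ids.tolist() if i not in gidx]
    if unknown:
        raise ValueError(f"clump: stats SNP(s) not in genotypes: {unknown[:5]}")

    ids = stats.ids.tolist()
    cols = np.asarray([gidx[i] for i in ids], dtype=np.intp)
    chroms = np.asarray([G.snps[c].chrom for c in cols], dtype=object)
    pos = np.asarray([G.snps[c].pos for c in cols], dtype=np.int64)

    order = sorted(range(len(ids)),
                   key=lambda k: (stats.p[k], chroms[k], pos[k], ids[k]))

    # standardized genotype columns for vectorized r^2 against an index SNP
    X = G.counts[:, cols].astype(np.float64)
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    nonzero = sd > 0
    X[:, nonzero] /= sd[nonzero]
    n = X.shape[0]

    assigned = np.zeros(len(ids), dtype=bool)
    retained: list[str] = []
    for k in order:
        if assigned[k]:
            continue
        assigned[k] = True
        retained.append(ids[k])
        cand = np.flatnonzero(
            ~assigned
            & (chroms == chroms[k])
            & (np.abs(pos - pos[k]) <= params.window_bp))
        if cand.size == 0:
            continue
        if not nonzero[k]:
            continue  # monomorphic index SNP is uncorrelated with everything
        usable = cand[nonzero[cand]]
        if usable.size:
            r = X[:, usable].T @ X[:, k] / n
            assigned[usable[r * r > params.r2_cutoff]] = True
    return retained


def threshold(stats: SummaryStats, p_threshold: float) -> list[str]:
    """SNP ids with p strictly below ``p_threshold``, in input order."""
    keep = stats.p < p_threshold
    return [i for i, k in zip(stats.ids.tolist(), keep) if k]
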