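"""Synthetic genotypes and phenotypes for the five simulation scenarios.

Genotypes are biallelic minor-allele counts with blockwise linkage
disequilibrium (LD): within each block a latent standard-normal AR(1) process
with adjacent correlation ``rho`` is thresholded at the Hardy-Weinberg
quantiles of a per-SNP MAF drawn uniformly from ``maf_range``. This stands in
for real chromosome-scale genotype data, giving clumping genuine LD structure
to remove while staying fully seeded.

Binary phenotypes follow logistic models over 100 causal SNPs under five
genetic architectures:

1. additive main effects,
2. two-way SNP-SNP interactions (100 pairs between causal SNPs 1-50 and
   51-100),
3. 50 main effects plus 100 two-way interactions,
4. 30 three-way interactions, one SNP from each of three disjoint groups of
   33 causal SNPs,
5. quadratic main effects (5a: any MAF; 5b: causal SNPs restricted to
   MAF > 0.3).

Effect sizes are Normal(mu, 0.1) log odds ratios; exactly half of the main
(and quadratic) effects are negated so ~50% of causal effects are protective.
A base population can share ``q`` of the 100 causal SNPs with the target
population, carrying identical effect sizes on the shared SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .io_formats import GenotypeMatrix, VariantInfo

SCENARIOS = ("1", "2", "3", "4", "5a", "5b")

#: Named (mu_main, mu_int) log-odds-ratio presets.
EFFECT_PRESETS: dict[str, tuple[float, float]] = {
    "small": (log(1.1), log(1.6)),
    "moderate": (log(1.5), log(2.0)),
}


class ConfigError(ValueError):
    """Infeasible or out-of-range simulation configuration."""


@dataclass(frozen=True)
class LDBlockSpec:
    """Blockwise-LD genotype layout.

    ``rho`` is the latent adjacent-SNP correlation within a block (AR(1));
    between blocks SNPs are independent. Positions are block-contiguous with
    ``bp_spacing`` base pairs between adjacent SNPs.
    """

    block_sizes: tuple[int, ...]
    rho: float = 0.6
    maf_range: tuple[float, float] = (0.01, 0.5)
    bp_spacing: int = 5_000
    chrom: str = "21"

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ConfigError(f"rho must be in [0, 1), got {self.rho}")
        lo, hi = self.maf_range
        if not (0.01 - 1e-12 <= lo <= hi <= 0.5 + 1e-12):
            raise ConfigError(f"maf_range {self.maf_range} outside [0.01, 0.5]")
        if any(b < 1 for b in self.block_sizes):
            raise ConfigError("block sizes must be positive")

    @property
    def n_snps(self) -> int:
        return int(sum(self.block_sizes))

    @classmethod
    def uniform_blocks(cls, n_snps: int, block_size: int = 10, **kw) -> "LDBlockSpec":
        """n_snps split into equal blocks (last block absorbs the remainder)."""
        n_full, rem = divmod(n_snps, block_size)
        sizes = [block_size] * n_full
        if rem:
            if sizes:
                sizes[-1] += rem
            else:
                sizes = [rem]
        return cls(block_sizes=tuple(sizes), **kw)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one base/target simulation.

    Desk-scale defaults: 1000 SNPs, 1000 target and 2000 base samples, 100
    causal SNPs all shared (q=100), moderate effect sizes. ``sd`` is the
    standard deviation of the effect-size distribution.
    """

    n_target: int = 1000
    n_base: int = 2000
    n_snps: int = 1000
    n_causal: int = 100
    q: int = 100
    mu_main: float = log(1.5)
    mu_int: float = log(2.0)
    sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q > self.n_causal:
            raise ConfigError(f"q={self.q} exceeds n_causal={self.n_causal}")
        if self.n_snps < self.n_causal:
            raise ConfigError("n_snps must be >= n_causal")
        if self.q not in (100, 70, 50, 30):
            import logging
            logging.getLogger("rfgrs").warning(
                "q=%d is outside the standard overlap grid {100, 70, 50, 30}",
                self.q)


@dataclass(frozen=True)
class EffectModel:
    """A scenario's causal architecture over SNP column indices.

    ``main_terms``: (snp, beta) linear terms; ``pair_terms``:
    (snp_l, snp_m, beta) products; ``triple_terms``: three-way products;
    ``quad_terms``: (snp, beta) applied to the squared count. ``causal_ids``
    lists the 100 causal column indices in draw order.
    """

    scenario: str
    causal_ids: tuple[int, ...]
    beta0: float = 0.0
    main_terms: tuple[tuple[int, float], ...] = ()
    pair_terms: tuple[tuple[int, int, float], ...] = ()
    triple_terms: tuple[tuple[int, int, int, float], ...] = ()
    quad_terms: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}")

    def linear_predictor(self, counts: np.ndarray) -> np.ndarray:
        """eta_i = beta0 + sum of the model's terms over genotype counts."""
        x = np.asarray(counts, dtype=np.float64)
        eta = np.full(x.shape[0], self.beta0, dtype=np.float64)
        for snp, b in self.main_terms:
            eta += b * x[:, snp]
        for l, m, b in self.pair_terms:
            eta += b * x[:, l] * x[:, m]
        for l, m, n, b in self.triple_terms:
            eta += b * x[:, l] * x[:, m] * x[:, n]
        for snp, b in self.quad_terms:
            eta += b * x[:, snp] ** 2
        return eta


# ---------------------------------------------------------------------------
# Genotype simulation
# ---------------------------------------------------------------------------

def simulate_genotypes(n: int, spec: LDBlockSpec, seed: int) -> GenotypeMatrix:
    """Draw n samples of blockwise-LD genotypes under ``spec``.

    Per block, a latent AR(1) Gaussian vector is thresholded per SNP at the
    quantiles implied by Hardy-Weinberg genotype frequencies (1-f)^2 and
    (1-f)^2 + 2f(1-f) for a MAF f drawn uniformly from ``maf_range``.
    Deterministic given (spec, seed).
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E02]))
    m = spec.n_snps
    mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)

    # latent AR(1) within blocks
    z = np.empty((n, m), dtype=np.float64)
    innov = rng.standard_normal((n, m))
    col = 0
    scale = np.sqrt(1.0 - spec.rho ** 2)
    for size in spec.block_sizes:
        z[:, col] = innov[:, col]
        for j in range(col + 1, col + size):
            z[:, j] = spec.rho * z[:, j - 1] + scale * innov[:, j]
        col += size

    # Hardy-Weinberg thresholds on the latent scale
    p0 = (1.0 - mafs) ** 2
    p01 = p0 + 2.0 * mafs * (1.0 - mafs)
    t0 = norm.ppf(p0)
    t1 = norm.ppf(p01)
    counts = np.zeros((n, m), dtype=np.int8)
    counts[z >= t0] = 1
    counts[z >= t1] = 2

    snps = []
    pos = 1
    col = 0
    for size in spec.block_sizes:
        for j in range(col, col + size):
            obs_maf = min(float(counts[:, j].mean() / 2.0), 0.5)
            snps.append(VariantInfo(
                id=f"snp{j+1}", chrom=spec.chrom, pos=pos,
                ref_allele="A", alt_allele="G", maf=obs_maf))
            pos += spec.bp_spacing
        col += size
    samples = [f"ind{i+1}" for i in range(n)]
    return GenotypeMatrix(samples=samples, snps=snps, counts=counts)


# ---------------------------------------------------------------------------
# Effect models
# ---------------------------------------------------------------------------

def _signed_main_betas(rng: np.random.Generator, k: int, mu: float, sd: float,
                       ) -> np.ndarray:
    """k betas ~ Normal(mu, sd), exactly half negated (randomly placed)."""
    betas = rng.normal(mu, sd, size=k)
    neg = rng.choice(k, size=k // 2, replace=False)
    betas[neg] *= -1.0
    return betas


def draw_effects(scenario: str, config: SimConfig, seed: int,
                 snp_mafs: Sequence[float] | None = None) -> EffectModel:
    """Draw a causal architecture for ``scenario``.

    Causal SNPs are drawn uniformly without replacement from all columns
    (scenario 5b: only from columns with MAF > 0.3, requiring ``snp_mafs``).
    Main and quadratic effects are Normal(mu_main, sd) with exactly half
    negated; interaction effects are Normal(mu_int, sd), unflipped.
    """
    if scenario not in SCENARIOS:
        raise ConfigError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xEFFE]))
    k = config.n_causal

    if scenario == "5b":
        if snp_mafs is None:
            raise ConfigError("scenario 5b requires per-SNP MAFs")
        pool = np.flatnonzero(np.asarray(snp_mafs) > 0.3)
        if pool.size < k:
            raise ConfigError(
                f"scenario 5b needs >= {k} SNPs with MAF > 0.3, found {pool.size}")
    else:
        pool = np.arange(config.n_snps)
    causal = rng.choice(pool, size=k, replace=False)
    return _draw_terms(scenario, tuple(int(c) for c in causal), config, rng)


def _draw_terms(scenario: str, causal: tuple[int, ...], config: SimConfig,
                rng: np.random.Generator) -> EffectModel:
    """Attach effect terms to an already-chosen causal SNP list."""
    k = len(causal)
    mu_m, mu_i, sd = config.mu_main, config.mu_int, config.sd

    if scenario == "1":
        betas = _signed_main_betas(rng, k, mu_m, sd)
        return EffectModel(scenario, causal,
                           main_terms=tuple(zip(causal, betas.tolist())))
    if scenario in ("5a", "5b"):
        betas = _signed_main_betas(rng, k, mu_m, sd)
        return EffectModel(scenario, causal,
                           quad_terms=tuple(zip(causal, betas.tolist())))
    if scenario == "2":
        pairs = _draw_pairs(rng, causal, n_pairs=100)
        betas = rng.normal(mu_i, sd, size=len(pairs))
        return EffectModel(scenario, causal, pair_terms=tuple(
            (l, m, float(b)) for (l, m), b in zip(pairs, betas)))
    if scenario == "3":
        main_betas = _signed_main_betas(rng, 50, mu_m, sd)
        main = tuple(zip(causal[:50], main_betas.tolist()))
        pairs = _draw_pairs(rng, causal, n_pairs=100)
        betas = rng.normal(mu_i, sd, size=len(pairs))
        return EffectModel(scenario, causal, main_terms=main, pair_terms=tuple(
            (l, m, float(b)) for (l, m), b in zip(pairs, betas)))
    if scenario == "4":
        triples = _draw_triples(rng, causal, n_triples=30)
        betas = rng.normal(mu_i, sd, size=len(triples))
        return EffectModel(scenario, causal, triple_terms=tuple(
            (l, m, n, float(b)) for (l, m, n), b in zip(triples, betas)))
    raise ConfigError(f"unknown scenario {scenario!r}")


def _draw_pairs(rng: np.random.Generator, causal: tuple[int, ...], n_pairs: int,
                ) -> list[tuple[int, int]]:
    """n_pairs distinct pairs: left from causal SNPs 1-50, right from 51-100."""
    flat = rng.choice(50 * 50, size=n_pairs, replace=False)
    return [(causal[f // 50], causal[50 + f % 50]) for f in sorted(flat.tolist())]


def _draw_triples(rng: np.random.Generator, causal: tuple[int, ...],
                  n_triples: int) -> list[tuple[int, int, int]]:
    """n_triples distinct triples, one SNP from each disjoint group of 33.

    Groups are causal positions 1-33, 34-66 and 67-99; the 100th causal SNP
    is carried but inert.
    """
    flat = rng.choice(33 ** 3, size=n_triples, replace=False)
    out = []
    for f in sorted(flat.tolist()):
        l, rem = divmod(int(f), 33 * 33)
        m, n = divmod(rem, 33)
        out.append((causal[l], causal[33 + m], causal[66 + n]))
    return out


def make_base_target(scenario: str, config: SimConfig, seed: int,
                     snp_mafs: Sequence[float] | None = None,
                     ) -> tuple[EffectModel, EffectModel]:
    """Draw paired (target, base) effect models sharing q causal SNPs.

    The q shared SNPs keep identical effect sizes and term structure in both
    models; each population's 100-q unique causal SNPs are fresh draws,
    disjoint from each other and from the shared set. Terms whose member SNPs
    are all shared carry the same beta in both models; terms touching a
    replaced SNP get freshly drawn effects (same distribution).
    """
    target = draw_effects(scenario, config, seed, snp_mafs=snp_mafs)
    k = config.n_causal
    if config.q == k:
        return target, target

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBA5E]))
    shared_pos = set(rng.choice(k, size=config.q, replace=False).tolist())

    if scenario == "5b":
        if snp_mafs is None:
            raise ConfigError("scenario 5b requires per-SNP MAFs")
        pool = np.flatnonzero(np.asarray(snp_mafs) > 0.3)
    else:
        pool = np.arange(config.n_snps)
    taken = set(target.causal_ids)
    avail = np.asarray([c for c in pool.tolist() if c not in taken])
    n_unique = k - config.q
    if avail.size < n_unique:
        raise ConfigError(
            f"not enough SNPs for disjoint base causal set "
            f"(need {n_unique}, have {avail.size})")
    fresh = rng.choice(avail, size=n_unique, replace=False)

    # substitute the non-shared causal SNPs by position, keep the term graph
    base_causal = list(target.causal_ids)
    it = iter(fresh.tolist())
    for pos in range(k):
        if pos not in shared_pos:
            base_causal[pos] = int(next(it))
    subst = dict(zip(target.causal_ids, base_causal))
    shared = {target.causal_ids[p] for p in shared_pos}

    def remap(terms, redraw_mu, signed):
        """Keep betas of all-shared terms; redraw betas of touched terms."""
        touched = [t for t in terms if not all(s in shared for s in t[:-1])]
        if signed and touched:
            new_betas = _signed_main_betas(rng, len(touched), redraw_mu, config.sd)
        else:
            new_betas = rng.normal(redraw_mu, config.sd, size=len(touched))
        redrawn = iter(new_betas.tolist())
        out = []
        for t in terms:
            snps = tuple(subst[s] for s in t[:-1])
            beta = t[-1] if all(s in shared for s in t[:-1]) else float(next(redrawn))
            out.append(snps + (beta,))
        return tuple(out)

    base = EffectModel(
        scenario=scenario, causal_ids=tuple(base_causal), beta0=target.beta0,
        main_terms=remap(target.main_terms, config.mu_main, signed=True),
        pair_terms=remap(target.pair_terms, config.mu_int, signed=False),
        triple_terms=remap(target.triple_terms, config.mu_int, signed=False),
        quad_terms=remap(target.quad_terms, config.mu_main, signed=True),
    )
    return target, base


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotype(G: GenotypeMatrix, em: EffectModel, seed: int) -> np.ndarray:
    """y_i ~ Bernoulli(expit(eta_i)) under the effect model. Seeded."""
    touched = [s for s, _ in em.main_terms]
    touched += [s for t in em.pair_terms for s in t[:2]]
    touched += [s for t in em.triple_terms for s in t[:3]]
    touched += [s for s, _ in em.quad_terms]
    if touched and max(touched) >= G.n_snps:
        raise ConfigError("effect model references SNP columns outside G")
    eta = em.linear_predictor(G.counts)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFE50]))
    return (rng.random(eta.shape[0]) < expit(eta)).astype(np.int8)


def draw_target_indices(pool_size: int, n_target: int, seed: int,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Randomly split a genotyped pool into target and base individuals.

    Mirrors drawing the target cohort from a larger genotype pool and
    treating everyone left over as the base cohort. Returns disjoint,
    exhaustive (target, base) index arrays.
    """
    if not (0 < n_target < pool_size):
        raise ConfigError("need 0 < n_target < pool_size")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD0A1]))
    perm = rng.permutation(pool_size)
    return np.sort(perm[:n_target]), np.sort(perm[n_target:])


def calibrate_intercept(G: GenotypeMatrix, em: EffectModel) -> EffectModel:
    """Return a copy of ``em`` with beta0 set to -mean(eta) on ``G``.

    Centers the linear predictor so cohort prevalence sits near 0.5. The
    scenarios' raw models carry no intercept; with a synthetic uniform MAF
    spectrum their interaction terms (all-positive-mean effects) would
    otherwise drive prevalence toward 1 and leave one outcome class nearly
    empty.
    """
    from dataclasses import replace
    eta = em.linear_predictor(G.counts) - em.beta0
    return replace(em, beta0=float(-np.mean(eta)))
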