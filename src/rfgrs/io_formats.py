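"""Genotype, phenotype and summary-statistic containers and file formats.

The pipeline works on three in-memory objects:

* :class:`GenotypeMatrix` — samples x SNPs minor-allele counts (0/1/2, with a
  ``MISSING`` sentinel for no-calls), plus per-SNP metadata.
* :class:`PhenotypeTable` — binary outcome and optional numeric covariates.
* :class:`SummaryStats` — per-SNP association results (effect allele, log-odds
  beta, p-value and the derived z-value), either read from an external GWAS
  ("base data") or produced by a marginal scan of the target training split.

Supported on-disk formats: PLINK 1 binary (bed/bim/fam, SNP-major), VCF 4.x
with GT fields, and header-carrying TSV for summary statistics, phenotypes and
scores. Coordinates are 1-based as in BIM/VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("rfgrs")

#: Sentinel for a missing genotype call.
MISSING: int = -9


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ConsistencyError(FormatError):
    """Mutually inconsistent inputs (dimension or identifier mismatch)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantInfo:
    """Per-SNP metadata.

    ``alt_allele`` is the counted (minor) allele after orientation;
    ``ref_allele`` is the other allele. ``pos`` is a 1-based base-pair
    coordinate and ``maf`` the minor-allele frequency in [0, 0.5] computed
    from non-missing calls.
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.id}: pos must be >= 1, got {self.pos}")
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(f"SNP {self.id}: maf {self.maf} outside [0, 0.5]")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele count matrix.

    ``counts[i, m]`` is the number of copies of the minor allele of SNP ``m``
    carried by sample ``i`` (0, 1 or 2), or :data:`MISSING`.
    """

    samples: list[str]
    snps: list[VariantInfo]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        if self.counts.ndim != 2:
            raise ConsistencyError("counts must be a 2-D matrix")
        n, m = self.counts.shape
        if len(self.samples) != n:
            raise ConsistencyError(
                f"{len(self.samples)} samples but {n} matrix rows")
        if len(self.snps) != m:
            raise ConsistencyError(f"{len(self.snps)} SNPs but {m} matrix columns")
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ConsistencyError("SNP identifiers are not unique")
        valid = np.isin(self.counts, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.counts[~valid])
            raise ConsistencyError(f"invalid genotype codes {bad.tolist()}")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def subset_snps(self, ids: Sequence[str]) -> "GenotypeMatrix":
        """Restrict to ``ids`` (in the given order)."""
        index = {s.id: j for j, s in enumerate(self.snps)}
        try:
            cols = [index[i] for i in ids]
        except KeyError as exc:
            raise ConsistencyError(f"unknown SNP id {exc.args[0]!r}") from None
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[j] for j in cols],
            counts=self.counts[:, cols].copy(),
        )

    def subset_samples(self, rows: Sequence[int]) -> "GenotypeMatrix":
        rows = np.asarray(rows, dtype=np.intp)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in rows],
            snps=list(self.snps),
            counts=self.counts[rows].copy(),
        )

    def has_missing(self) -> bool:
        return bool((self.counts == MISSING).any())


@dataclass
class PhenotypeTable:
    """Binary outcome y (0 control / 1 case) plus numeric covariates Z."""

    samples: list[str]
    y: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.y.ndim != 1 or len(self.samples) != self.y.shape[0]:
            raise ConsistencyError("y must be 1-D and match the sample list")
        if not np.isin(self.y, (0, 1)).all():
            raise ConsistencyError("y must be coded 0/1")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=np.float64)
            if self.covariates.ndim != 2 or self.covariates.shape[0] != self.y.shape[0]:
                raise ConsistencyError("covariates must be n_samples x p")
            if self.covariates.shape[1] == 0:
                self.covariates = None

    @property
    def n_samples(self) -> int:
        return self.y.shape[0]

    def subset_samples(self, rows: Sequence[int]) -> "PhenotypeTable":
        rows = np.asarray(rows, dtype=np.intp)
        return PhenotypeTable(
            samples=[self.samples[i] for i in rows],
            y=self.y[rows].copy(),
            covariates=None if self.covariates is None else self.covariates[rows].copy(),
            covariate_names=list(self.covariate_names),
        )


@dataclass
class SummaryStats:
    """Per-SNP marginal association results.

    ``beta`` is the log-odds effect of ``effect_allele``; ``p`` a two-sided
    p-value in (0, 1]. ``z = |Phi^-1(p/2)|`` is derivable and computed lazily.
    ``flag`` marks SNPs whose fit was degenerate (monomorphic, separated).
    """

    ids: np.ndarray
    effect_allele: np.ndarray
    beta: np.ndarray
    p: np.ndarray
    se: np.ndarray | None = None
    z: np.ndarray | None = None
    flag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.effect_allele = np.asarray(self.effect_allele, dtype=object)
        self.beta = np.asarray(self.beta, dtype=np.float64)
        self.p = np.asarray(self.p, dtype=np.float64)
        n = self.ids.shape[0]
        for name in ("effect_allele", "beta", "p"):
            if getattr(self, name).shape != (n,):
                raise ConsistencyError(f"SummaryStats field {name} length mismatch")
        if len(set(self.ids.tolist())) != n:
            raise ConsistencyError("SummaryStats ids are not unique")
        if n and (np.min(self.p) <= 0 or np.max(self.p) > 1):
            raise ConsistencyError("p-values must lie in (0, 1]")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=np.float64)
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=np.float64)
        if self.flag is None:
            self.flag = np.zeros(n, dtype=bool)
        else:
            self.flag = np.asarray(self.flag, dtype=bool)

    def __len__(self) -> int:
        return self.ids.shape[0]

    def zvalues(self) -> np.ndarray:
        """z = |Phi^-1(p/2)|, computed on demand and cached."""
        if self.z is None:
            from .association import p_to_z
            self.z = p_to_z(self.p)
        return self.z

    def subset(self, ids: Sequence[str]) -> "SummaryStats":
        index = {i: j for j, i in enumerate(self.ids.tolist())}
        rows = np.asarray([index[i] for i in ids], dtype=np.intp)
        return SummaryStats(
            ids=self.ids[rows],
            effect_allele=self.effect_allele[rows],
            beta=self.beta[rows],
            p=self.p[rows],
            se=None if self.se is None else self.se[rows],
            z=None if self.z is None else self.z[rows],
            flag=self.flag[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "snp": self.ids,
            "effect_allele": self.effect_allele,
            "beta": self.beta,
            "p": self.p,
        }
        if self.se is not None:
            data["se"] = self.se
        data["z"] = self.zvalues()
        data["flag"] = self.flag.astype(int)
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Minor-allele orientation
# ---------------------------------------------------------------------------

def _orient_minor(counts: np.ndarray, a1: list[str], a2: list[str],
                  ids: list[str], chroms: list[str], pos: list[int],
                  ) -> tuple[np.ndarray, list[VariantInfo]]:
    """Flip columns so counts refer to the minor allele; compute MAF.

    ``counts`` arrives on the A1-count scale with MISSING sentinels. Columns
    whose A1 frequency exceeds 0.5 are flipped (x -> 2 - x) and the allele
    labels swapped.
    """
    counts = counts.astype(np.int8, copy=True)
    snps: list[VariantInfo] = []
    for j in range(counts.shape[1]):
        col = counts[:, j]
        obs = col[col != MISSING]
        freq = float(obs.mean() / 2.0) if obs.size else 0.0
        counted, other = a1[j], a2[j]
        if freq > 0.5:
            mask = col != MISSING
            col[mask] = 2 - col[mask]
            counts[:, j] = col
            freq = 1.0 - freq
            counted, other = a2[j], a1[j]
        snps.append(VariantInfo(id=ids[j], chrom=chroms[j], pos=pos[j],
                                ref_allele=other, alt_allele=counted, maf=freq))
    return counts, snps


# ---------------------------------------------------------------------------
# PLINK 1 binary
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b"
# 2-bit codes in a SNP-major .bed: 00 hom A1, 01 missing, 10 het, 11 hom A2.
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 binary fileset ``prefix``.bed/.bim/.fam.

    Counts are oriented to the minor allele and MAF is computed from the
    non-missing entries.
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    for path in (bed_path, bim_path, fam_path):
        if not path.exists():
            raise FormatError(f"missing PLINK file {path}")

    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype=str)
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    n, m = len(fam), len(bim)

    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: not a PLINK 1 .bed file (bad magic)")
    if raw[2] != 0x01:
        raise FormatError(f"{bed_path}: only SNP-major .bed files are supported")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise ConsistencyError(
            f"{bed_path}: {len(raw)} bytes, expected {expected} for "
            f"{n} samples x {m} SNPs")

    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack 2-bit fields, sample-within-byte little-endian
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    counts = _BED_DECODE[codes].T  # n x m, A1-count scale

    counts, snps = _orient_minor(
        counts, bim["a1"].tolist(), bim["a2"].tolist(), bim["id"].tolist(),
        bim["chrom"].tolist(), bim["pos"].astype(int).tolist())
    return GenotypeMatrix(samples=fam["iid"].tolist(), snps=snps, counts=counts)


def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a GenotypeMatrix as a PLINK 1 SNP-major bed/bim/fam fileset.

    The counted (minor) allele is written as A1, so a read-back round-trips.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = G.counts.shape

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in G.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in G.snps:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.alt_allele}\t{v.ref_allele}\n")

    bytes_per_snp = (n + 3) // 4
    out = bytearray(_BED_MAGIC + b"\x01")
    enc = np.zeros(bytes_per_snp * 4, dtype=np.uint8)
    for j in range(m):
        enc[:] = 0
        for i in range(n):
            enc[i] = _BED_ENCODE[int(G.counts[i, j])]
        packed = (enc.reshape(bytes_per_snp, 4)
                  << (np.arange(4, dtype=np.uint8) * 2)).sum(axis=1).astype(np.uint8)
        out.extend(packed.tobytes())
    prefix.with_suffix(".bed").write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF with GT fields into a GenotypeMatrix.

    Biallelic records only; multi-allelic records are skipped with a warning.
    Half/no-calls become :data:`MISSING`. Counts are oriented to the minor
    allele after reading the ALT-count scale.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    ids: list[str] = []
    chroms: list[str] = []
    pos: list[int] = []
    a1: list[str] = []
    a2: list[str] = []
    saw_gt = False
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("read_vcf: skipping multi-allelic record %s at %s:%d",
                           rec.ID or ".", rec.CHROM, rec.POS)
            continue
        gts = rec.gt_types  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown (gts012)
        if gts is None:
            continue
        saw_gt = True
        col = np.asarray(gts, dtype=np.int8)
        col[col == 3] = MISSING
        cols.append(col)
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        chroms.append(str(rec.CHROM))
        pos.append(int(rec.POS))
        a1.append(str(rec.ALT[0]))
        a2.append(str(rec.REF))
    vcf.close()
    if not saw_gt:
        raise FormatError(f"{path}: no GT genotypes found")
    counts = np.stack(cols, axis=1) if cols else np.zeros((len(samples), 0), np.int8)
    counts, snps = _orient_minor(counts, a1, a2, ids, chroms, pos)
    return GenotypeMatrix(samples=samples, snps=snps, counts=counts)


# ---------------------------------------------------------------------------
# TSV formats
# ---------------------------------------------------------------------------

DEFAULT_SUMSTATS_COLUMNS: Mapping[str, str] = {
    "id": "snp", "effect_allele": "effect_allele", "beta": "beta", "p": "p",
}


def read_summary_stats(path: str | Path,
                       column_map: Mapping[str, str] | None = None,
                       ) -> SummaryStats:
    """Read GWAS summary statistics from a delimited text file with header.

    ``column_map`` maps the roles ``id``/``effect_allele``/``beta``/``p`` to
    column names in the file. Rows with p outside (0, 1] are dropped and the
    drop count logged.
    """
    colmap = dict(DEFAULT_SUMSTATS_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; have {list(df.columns)}")
    p = pd.to_numeric(df[colmap["p"]], errors="coerce")
    keep = (p > 0) & (p <= 1)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("read_summary_stats: dropped %d row(s) with p outside (0, 1]",
                       dropped)
    df = df.loc[keep]
    stats = SummaryStats(
        ids=df[colmap["id"]].astype(str).to_numpy(dtype=object),
        effect_allele=df[colmap["effect_allele"]].astype(str).to_numpy(dtype=object),
        beta=pd.to_numeric(df[colmap["beta"]]).to_numpy(dtype=np.float64),
        p=p.loc[keep].to_numpy(dtype=np.float64),
    )
    stats.n_dropped = dropped  # type: ignore[attr-defined]
    return stats


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    stats.to_frame().to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path, sample_ids: Sequence[str] | None = None,
                    ) -> PhenotypeTable:
    """Read a phenotype/covariate TSV keyed by sample id.

    Columns: ``sample``, ``y``, then any number of numeric covariates. When
    ``sample_ids`` is given, rows are aligned to that order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    for col in ("sample", "y"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if sample_ids is not None:
        df = df.set_index("sample").reindex(list(sample_ids))
        if df["y"].isna().any():
            absent = [s for s in sample_ids if s not in set(df.index[df["y"].notna()])]
            raise ConsistencyError(f"{path}: no phenotype for sample(s) {absent[:5]}")
        df = df.reset_index()
    cov_cols = [c for c in df.columns if c not in ("sample", "y")]
    return PhenotypeTable(
        samples=df["sample"].tolist(),
        y=df["y"].astype(int).to_numpy(),
        covariates=df[cov_cols].to_numpy(dtype=np.float64) if cov_cols else None,
        covariate_names=cov_cols,
    )


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    data = {"sample": pheno.samples, "y": pheno.y}
    if pheno.covariates is not None:
        names = pheno.covariate_names or [
            f"cov{i+1}" for i in range(pheno.covariates.shape[1])]
        for k, name in enumerate(names):
            data[name] = pheno.covariates[:, k]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def write_scores(samples: Sequence[str], scores: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"sample": list(samples), "grs": np.asarray(scores, float)}
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization and imputation
# ---------------------------------------------------------------------------

def harmonize(target: GenotypeMatrix, base: SummaryStats,
              ) -> tuple[GenotypeMatrix, SummaryStats]:
    """Align base summary statistics with target genotypes by SNP id.

    The intersection is taken on id in the target's column order. Where the
    base effect allele equals the target's non-counted (major) allele, beta is
    negated so that it refers to the counted minor allele; SNPs whose effect
    allele matches neither target allele are dropped and counted. Idempotent.
    """
    if target.n_snps == 0 or len(base) == 0:
        raise ConsistencyError("harmonize: empty input")
    base_idx = {i: j for j, i in enumerate(base.ids.tolist())}

    keep_ids: list[str] = []
    rows: list[int] = []
    signs: list[float] = []
    n_allele_dropped = 0
    for v in target.snps:
        j = base_idx.get(v.id)
        if j is None:
            continue
        ea = base.effect_allele[j]
        if ea == v.alt_allele:
            sign = 1.0
        elif ea == v.ref_allele:
            sign = -1.0
        else:
            n_allele_dropped += 1
            continue
        keep_ids.append(v.id)
        rows.append(j)
        signs.append(sign)
    if n_allele_dropped:
        logger.warning("harmonize: dropped %d SNP(s) with unmatchable alleles",
                       n_allele_dropped)
    if not keep_ids:
        raise ConsistencyError("harmonize: empty intersection between base and target")

    rows_a = np.asarray(rows, dtype=np.intp)
    signs_a = np.asarray(signs, dtype=np.float64)
    target_out = target.subset_snps(keep_ids)
    allele = [v.alt_allele for v in target_out.snps]
    stats_out = SummaryStats(
        ids=np.asarray(keep_ids, dtype=object),
        effect_allele=np.asarray(allele, dtype=object),
        beta=base.beta[rows_a] * signs_a,
        p=base.p[rows_a],
        se=None if base.se is None else base.se[rows_a],
        flag=base.flag[rows_a],
    )
    return target_out, stats_out


def impute_mode(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace MISSING entries with the per-SNP modal genotype count.

    Downstream modules (forests treat genotypes as complete 3-level factors)
    require completeness; callers apply this explicitly.
    """
    counts = G.counts.copy()
    for j in range(counts.shape[1]):
        col = counts[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            mode = 0
        else:
            mode = int(np.bincount(obs, minlength=3).argmax())
        col[miss] = mode
        counts[:, j] = col
    return replace(G, counts=counts)
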