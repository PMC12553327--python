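"""Trained genetic risk scorers and their hyperparameter grid search.

Method roster:

* ``ctRF`` — forest on SNPs selected by LD clumping *and* p-value
  thresholding, both tuned jointly with the forest hyperparameters.
* ``cRF``  — tunes only the clumping cutoff (p-threshold fixed at 1).
* ``tRF``  — tunes only the p-value threshold (no clumping).
* ``oRF``  — forest on all SNPs, no filtering.
* ``wRF``  — forest on all SNPs with association-weighted split-candidate
  sampling (weights from min-max-normalized z-values).
* ``oCT``  — the classic additive clumping + thresholding score
  GRS_i = sum_m beta_m x_im over retained SNPs.

Association p-values come either from the target training split (``Tonly``)
or from external base summary statistics (``BT``). Every candidate grid point
is scored by the Nagelkerke R^2 of the outcome regressed on the candidate
GRS; for forest methods the candidate GRS is the out-of-bag probability, so
tuning never sees resubstitution predictions. The winning point is refit on
the full training split.

The effective ctRF grid is the cross of (r2 cutoffs + a no-clumping point)
with (p thresholds + 1), making it a strict superset of the cRF and tRF
grids: ctRF's best training objective can therefore never fall below either
ablation's on the same data and seed.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .association import marginal_scan, p_to_z, z_to_weights
from .clumping import ClumpParams, clump, threshold
from .forest import (Forest, ForestConfig, SchemaError, fit_forest, load_forest,
                     oob_proba, predict_proba, save_forest)
from .io_formats import GenotypeMatrix, PhenotypeTable, SummaryStats, harmonize

logger = logging.getLogger("rfgrs")

RF_METHODS = ("ctRF", "cRF", "tRF", "wRF", "oRF")
ALL_METHODS = RF_METHODS + ("oCT",)
MODES = ("Tonly", "BT")

#: mtry rules resolved against the retained feature count M.
MTRY_RULES = {
    "sqrt": lambda m: math.ceil(math.sqrt(m)),
    "m10": lambda m: max(1, math.ceil(m / 10)),
    "m3": lambda m: max(1, math.ceil(m / 3)),
}


@dataclass(frozen=True)
class HyperGrid:
    """Grid-search space for the scorers.

    ``mtrys`` entries are either integers or the rules "sqrt", "m10", "m3"
    (ceil of sqrt(M), M/10, M/3 for M retained features).
    """

    r2_cutoffs: tuple[float, ...] = (0.1, 0.2, 0.5, 0.8)
    p_thresholds: tuple[float, ...] = (1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)
    ntrees: tuple[int, ...] = (500,)
    mtrys: tuple = ("sqrt", "m10", "m3")
    min_node_sizes: tuple[int, ...] = (1, 5, 10)
    window_bp: int = 250_000

    def __post_init__(self) -> None:
        for name in ("r2_cutoffs", "p_thresholds", "ntrees", "mtrys",
                     "min_node_sizes"):
            if not getattr(self, name):
                raise ValueError(f"HyperGrid.{name} must be non-empty")

    @classmethod
    def desk(cls) -> "HyperGrid":
        """Reduced grid for desk-scale experiments (ntree 200)."""
        return cls(r2_cutoffs=(0.1, 0.5), p_thresholds=(0.05, 1.0),
                   ntrees=(200,), mtrys=("sqrt",), min_node_sizes=(5,))


@dataclass
class GrsModel:
    """A trained genetic risk scorer.

    RF methods carry a fitted :class:`Forest`; oCT carries per-SNP additive
    weights (the marginal betas of the retained SNPs). ``objective`` is the
    training Nagelkerke R^2 that selected the hyperparameters.
    """

    method: str
    mode: str
    hyperparams: dict
    snp_ids: list[str]
    forest: Forest | None = None
    additive_weights: np.ndarray | None = None
    objective: float = float("nan")
    grid_log: list[dict] = field(default_factory=list)


def _resolve_mtry(rule, m: int) -> int:
    if isinstance(rule, str):
        return min(MTRY_RULES[rule](m), m)
    return min(int(rule), m)


def _stable_seed(master: int, *parts) -> int:
    """Deterministic 31-bit seed from the master seed and context tokens.

    Independent of method name and grid iteration order, so a grid point
    shared between two methods produces the identical forest.
    """
    token = repr((int(master),) + tuple(parts)).encode()
    return zlib.crc32(token) & 0x7FFFFFFF


def source_pvalues(mode: str, base: SummaryStats | None,
                   G_train: GenotypeMatrix, pheno_train: PhenotypeTable,
                   ) -> tuple[GenotypeMatrix, SummaryStats]:
    """Association statistics for SNP selection, per sourcing mode.

    ``Tonly``: marginal scan of the training split. ``BT``: base summary
    statistics harmonized to the training SNP set (betas oriented to the
    target minor alleles, p-values untouched). Returns the (possibly
    restricted) genotype matrix alongside the aligned statistics.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if mode == "BT":
        if base is None:
            raise ValueError("BT mode requires base summary statistics")
        return harmonize(G_train, base)
    return G_train, marginal_scan(G_train, pheno_train)


def _iter_select_grid(method: str, grid: HyperGrid):
    """(r2_cutoff | None, p_threshold) pairs for the SNP-selection search."""
    if method == "ctRF":
        r2s = list(grid.r2_cutoffs) + [None]
        ps = list(grid.p_thresholds)
        if 1.0 not in ps:
            ps = ps + [1.0]
    elif method == "cRF":
        r2s, ps = list(grid.r2_cutoffs), [1.0]
    elif method == "tRF":
        r2s, ps = [None], list(grid.p_thresholds)
    elif method in ("oRF", "wRF"):
        r2s, ps = [None], [1.0]
    elif method == "oCT":
        r2s, ps = list(grid.r2_cutoffs), list(grid.p_thresholds)
    else:
        raise ValueError(f"unknown method {method!r}")
    for r2 in r2s:
        for p in ps:
            yield r2, p


def _select_snps(stats: SummaryStats, G: GenotypeMatrix,
                 r2_cutoff: float | None, p_threshold: float,
                 window_bp: int) -> list[str]:
    """Clump (if enabled) then threshold; returns retained SNP ids."""
    if r2_cutoff is not None:
        params = ClumpParams(r2_cutoff=r2_cutoff, window_bp=window_bp,
                             p_threshold=p_threshold)
        ids = clump(stats, G, params)
        sub = stats.subset(ids)
        return threshold(sub, p_threshold)
    return threshold(stats, p_threshold)


def train_rf_grs(method: str, mode: str, G_train: GenotypeMatrix,
                 pheno_train: PhenotypeTable, base: SummaryStats | None,
                 grid: HyperGrid, seed: int) -> GrsModel:
    """Grid-search and fit one of the forest-based scorers.

    Every grid point fits a bootstrap forest, takes its OOB probabilities as
    the candidate GRS, and scores them by training Nagelkerke R^2 (samples
    never out of bag are dropped from the objective). Ties are broken toward
    fewer retained SNPs, then smaller ntree, then grid order. The winner is
    refit on the full training split with a fresh seed stream.
    """
    from .evaluation import nagelkerke_r2

    if method not in RF_METHODS:
        raise ValueError(f"method must be one of {RF_METHODS}, got {method!r}")
    if method == "oRF":
        G_sel, stats = G_train, None
    else:
        G_sel, stats = source_pvalues(mode, base, G_train, pheno_train)

    weights_all = None
    if method == "wRF":
        weights_all = z_to_weights(p_to_z(stats.p))

    y = pheno_train.y
    cov = pheno_train.covariates
    best = None  # (objective, n_retained, ntree, order) minimizing tuple
    best_state = None
    order = 0
    grid_log: list[dict] = []
    n_skipped = 0
    for r2, p in _iter_select_grid(method, grid):
        if method == "oRF" or method == "wRF":
            retained = G_sel.snp_ids
        else:
            retained = _select_snps(stats, G_sel, r2, p, grid.window_bp)
        if len(retained) == 0:
            logger.warning("grid point (r2=%s, p=%s) retained no SNPs; skipped",
                           r2, p)
            n_skipped += 1
            continue
        G_fit = G_sel if len(retained) == G_sel.n_snps else G_sel.subset_snps(retained)
        sw = None
        if weights_all is not None:
            widx = {i: k for k, i in enumerate(G_sel.snp_ids)}
            sw = weights_all[[widx[i] for i in retained]]
        n_cov = 0 if cov is None else cov.shape[1]
        n_feat = len(retained) + n_cov
        for ntree in grid.ntrees:
            for mtry_rule in grid.mtrys:
                mtry = _resolve_mtry(mtry_rule, n_feat)
                for mns in grid.min_node_sizes:
                    fseed = _stable_seed(seed, tuple(retained), ntree, mtry,
                                         mns, method == "wRF")
                    cfg = ForestConfig(ntree=ntree, mtry=mtry,
                                       min_node_size=mns, split_weights=sw,
                                       bootstrap=True, seed=fseed)
                    f = fit_forest(G_fit, pheno_train, cfg)
                    oob = oob_proba(f)
                    ok = ~np.isnan(oob)
                    if ok.sum() < 2 or y[ok].min() == y[ok].max():
                        n_skipped += 1
                        continue
                    obj = nagelkerke_r2(y[ok], oob[ok],
                                        None if cov is None else cov[ok])
                    key = (-obj, len(retained), ntree, order)
                    point = {"r2_cutoff": r2, "p_threshold": p, "ntree": ntree,
                             "mtry": mtry, "min_node_size": mns,
                             "n_snps": len(retained), "objective": obj}
                    grid_log.append(point)
                    if best is None or key < best:
                        best = key
                        best_state = (point, retained, sw)
                    order += 1
    if best_state is None:
        raise ValueError("all grid points were skipped; nothing to fit")

    point, retained, sw = best_state
    G_fit = G_sel.subset_snps(retained)
    refit_seed = _stable_seed(seed, "refit", tuple(retained), point["ntree"],
                              point["mtry"], point["min_node_size"],
                              method == "wRF")
    cfg = ForestConfig(ntree=point["ntree"], mtry=point["mtry"],
                       min_node_size=point["min_node_size"], split_weights=sw,
                       bootstrap=True, seed=refit_seed)
    forest = fit_forest(G_fit, pheno_train, cfg)
    return GrsModel(method=method, mode=mode,
                    hyperparams={k: point[k] for k in
                                 ("r2_cutoff", "p_threshold", "ntree", "mtry",
                                  "min_node_size")},
                    snp_ids=list(retained), forest=forest,
                    objective=point["objective"], grid_log=grid_log)


def train_oct(mode: str, G_train: GenotypeMatrix, pheno_train: PhenotypeTable,
              base: SummaryStats | None, grid: HyperGrid, seed: int = 0,
              ) -> GrsModel:
    """The classic additive clumping + thresholding baseline.

    Per (r2_cutoff, p_threshold) grid point the score is the beta-weighted
    minor-allele count sum over retained SNPs; the point maximizing training
    Nagelkerke R^2 wins. Deterministic — ``seed`` is accepted for interface
    symmetry only.
    """
    from .evaluation import nagelkerke_r2

    G_sel, stats = source_pvalues(mode, base, G_train, pheno_train)
    y = pheno_train.y
    cov = pheno_train.covariates
    sidx = {i: k for k, i in enumerate(G_sel.snp_ids)}
    best = None
    best_state = None
    order = 0
    grid_log: list[dict] = []
    for r2, p in _iter_select_grid("oCT", grid):
        retained = _select_snps(stats, G_sel, r2, p, grid.window_bp)
        if not retained:
            logger.warning("oCT grid point (r2=%s, p=%s) retained no SNPs; skipped",
                           r2, p)
            continue
        betas = stats.subset(retained).beta
        cols = [sidx[i] for i in retained]
        score = G_sel.counts[:, cols].astype(np.float64) @ betas
        obj = nagelkerke_r2(y, score, cov)
        point = {"r2_cutoff": r2, "p_threshold": p, "n_snps": len(retained),
                 "objective": obj}
        grid_log.append(point)
        key = (-obj, len(retained), order)
        if best is None or key < best:
            best = key
            best_state = (point, retained, betas)
        order += 1
    if best_state is None:
        raise ValueError("all oCT grid points were skipped; nothing to fit")
    point, retained, betas = best_state
    return GrsModel(method="oCT", mode=mode,
                    hyperparams={"r2_cutoff": point["r2_cutoff"],
                                 "p_threshold": point["p_threshold"]},
                    snp_ids=list(retained), additive_weights=betas,
                    objective=point["objective"], grid_log=grid_log)


def train_grs(method: str, mode: str, G_train: GenotypeMatrix,
              pheno_train: PhenotypeTable, base: SummaryStats | None,
              grid: HyperGrid, seed: int) -> GrsModel:
    """Dispatch to the RF trainer or the additive baseline."""
    if method == "oCT":
        return train_oct(mode, G_train, pheno_train, base, grid, seed)
    return train_rf_grs(method, mode, G_train, pheno_train, base, grid, seed)


def predict_grs(model: GrsModel, G_new: GenotypeMatrix,
                covariates: np.ndarray | None = None) -> np.ndarray:
    """Score new samples: forest disease probability or additive sum."""
    if model.forest is not None:
        return predict_proba(model.forest, G_new, covariates)
    if model.additive_weights is None:
        raise ValueError("model carries neither a forest nor additive weights")
    missing = [s for s in model.snp_ids if s not in set(G_new.snp_ids)]
    if missing:
        raise SchemaError(f"genotypes lack retained SNP(s): {missing[:5]}")
    G_sub = G_new.subset_snps(model.snp_ids)
    return G_sub.counts.astype(np.float64) @ model.additive_weights


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def save_model(model: GrsModel, path: str | Path) -> None:
    """Persist a GrsModel; forests go to a sibling ``<path>.forest.npz``."""
    import json

    path = Path(path)
    payload = {
        "format": "rfgrs-model",
        "version": 1,
        "method": model.method,
        "mode": model.mode,
        "hyperparams": model.hyperparams,
        "snp_ids": model.snp_ids,
        "objective": model.objective,
        "additive_weights": (model.additive_weights.tolist()
                             if model.additive_weights is not None else None),
        "has_forest": model.forest is not None,
    }
    path.write_text(json.dumps(payload, indent=1))
    if model.forest is not None:
        save_forest(model.forest, path.with_suffix(path.suffix + ".forest.npz"))


def load_model(path: str | Path) -> GrsModel:
    import json

    path = Path(path)
    payload = json.loads(path.read_text())
    if payload.get("format") != "rfgrs-model":
        raise ValueError(f"{path}: not a serialized GRS model")
    forest = None
    if payload["has_forest"]:
        forest = load_forest(path.with_suffix(path.suffix + ".forest.npz"))
    aw = payload["additive_weights"]
    return GrsModel(
        method=payload["method"], mode=payload["mode"],
        hyperparams=payload["hyperparams"], snp_ids=list(payload["snp_ids"]),
        forest=forest,
        additive_weights=None if aw is None else np.asarray(aw, float),
        objective=payload["objective"])
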