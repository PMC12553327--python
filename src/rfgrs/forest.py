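"""Probability-machine random forest over 3-level categorical SNP features.

Each tree is grown on a bootstrap sample with Gini-impurity splits. SNP
genotypes (0/1/2 minor-allele counts) are treated as 3-level categorical
features and split by the best of the three one-category-vs-rest partitions
{0}|{1,2}, {1}|{0,2}, {2}|{0,1} — which spans every binary partition of a
3-level factor. Numeric covariate features are split at the best midpoint
threshold.

At every node ``mtry`` candidate features are sampled without replacement,
either uniformly or proportionally to per-feature split weights (features
with weight 0 are never sampled). Weighted sampling uses exponential-race
keys: feature f draws key ``-log(U_f)/w_f`` and the ``mtry`` smallest keys
win, which is equivalent to sequential weighted draws with renormalization.

Prediction is a probability machine: terminal nodes store the in-bag disease
proportion, and the forest's disease-probability estimate for a sample is the
average terminal proportion over all trees. Out-of-bag (OOB) probabilities —
the same average restricted to trees whose bootstrap excluded the sample —
serve as internal validation for hyperparameter tuning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .io_formats import GenotypeMatrix, PhenotypeTable

SERIAL_FORMAT_VERSION = 1


class SchemaError(ValueError):
    """Prediction-time features do not match the fitted forest."""


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters.

    ``mtry`` = None means ceil(sqrt(n_features)). ``min_node_size`` is the
    minimum number of in-bag samples a node must hold for a split to be
    attempted. ``split_weights``, when given, is a per-SNP weight vector in
    [0, 1] aligned with the genotype matrix's SNP order; covariate features
    receive the maximum SNP weight so they stay samplable.
    """

    ntree: int = 500
    mtry: int | None = None
    min_node_size: int = 1
    split_weights: np.ndarray | None = None
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass
class Tree:
    """Flat array representation of one decision tree.

    ``feature[k] == -1`` marks a terminal node, whose ``leaf_prop[k]`` is the
    in-bag disease proportion and ``leaf_n[k]`` the in-bag sample count. For
    an internal node, ``split_val`` is the left-going category code
    (categorical feature) or the strict upper threshold for the left branch
    (numeric feature: x < split_val goes left).
    """

    feature: np.ndarray
    split_val: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_prop: np.ndarray
    leaf_n: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.feature.shape[0]


@dataclass
class Forest:
    """A fitted probability-machine forest."""

    trees: list[Tree]
    snp_ids: list[str]
    covariate_names: list[str]
    is_categorical: np.ndarray
    config: ForestConfig
    inbag: np.ndarray | None  # ntree x n in-bag multiplicities, None if unavailable
    _train_X: np.ndarray | None = field(default=None, repr=False)

    @property
    def ntree(self) -> int:
        return len(self.trees)

    @property
    def n_features(self) -> int:
        return self.is_categorical.shape[0]


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _grow_tree(X, y, inbag, is_cat, weights, mtry, min_node, seed,
               feature, split_val, left, right, leaf_prop, leaf_n):  # pragma: no cover
    np.random.seed(seed)
    n_feat = X.shape[1]
    idx = inbag.copy()
    n_in = idx.shape[0]

    # DFS stack of (node, start, end) over segments of idx
    cap = 4 * n_in + 4
    st_node = np.empty(cap, np.int64)
    st_lo = np.empty(cap, np.int64)
    st_hi = np.empty(cap, np.int64)
    top = 0
    st_node[0] = 0
    st_lo[0] = 0
    st_hi[0] = n_in
    top = 1
    n_nodes = 1

    keys = np.empty(n_feat, np.float64)
    buf = np.empty(n_in, np.int64)

    while top > 0:
        top -= 1
        node = st_node[top]
        lo = st_lo[top]
        hi = st_hi[top]
        nn = hi - lo
        pos = 0
        for t in range(lo, hi):
            pos += y[idx[t]]
        prop = pos / nn

        make_leaf = (pos == 0 or pos == nn or nn < min_node or nn < 2)
        best_gain = 0.0
        best_feat = -1
        best_val = 0.0
        best_is_cat = False

        if not make_leaf:
            # sample candidate features by exponential race over weights
            navail = 0
            for f in range(n_feat):
                w = weights[f]
                if w > 0.0:
                    u = np.random.random()
                    keys[f] = -math.log(u) / w
                    navail += 1
                else:
                    keys[f] = np.inf
            m_eff = mtry if mtry < navail else navail
            if m_eff <= 0:
                make_leaf = True
            else:
                kth = np.partition(keys, m_eff - 1)[m_eff - 1]
                parent_imp = 2.0 * prop * (1.0 - prop)
                taken = 0
                for f in range(n_feat):
                    if taken >= m_eff or keys[f] > kth:
                        continue
                    taken += 1
                    if is_cat[f]:
                        # class counts per genotype category
                        cn0 = 0; cn1 = 0; cn2 = 0
                        cp0 = 0; cp1 = 0; cp2 = 0
                        for t in range(lo, hi):
                            v = X[idx[t], f]
                            lab = y[idx[t]]
                            if v == 0.0:
                                cn0 += 1; cp0 += lab
                            elif v == 1.0:
                                cn1 += 1; cp1 += lab
                            else:
                                cn2 += 1; cp2 += lab
                        for part in range(3):
                            if part == 0:
                                nl = cn0; pl = cp0
                            elif part == 1:
                                nl = cn1; pl = cp1
                            else:
                                nl = cn2; pl = cp2
                            nr = nn - nl
                            if nl == 0 or nr == 0:
                                continue
                            pr = pos - pl
                            fl = pl / nl
                            fr = pr / nr
                            child = (nl * 2.0 * fl * (1.0 - fl)
                                     + nr * 2.0 * fr * (1.0 - fr)) / nn
                            gain = parent_imp - child
                            if gain > best_gain:
                                best_gain = gain
                                best_feat = f
                                best_val = float(part)
                                best_is_cat = True
                    else:
                        # numeric: best midpoint threshold
                        vals = np.empty(nn, np.float64)
                        labs = np.empty(nn, np.int64)
                        for t in range(nn):
                            vals[t] = X[idx[lo + t], f]
                            labs[t] = y[idx[lo + t]]
                        order = np.argsort(vals, kind="mergesort")
                        nl = 0
                        pl = 0
                        for t in range(nn - 1):
                            o = order[t]
                            nl += 1
                            pl += labs[o]
                            v_here = vals[o]
                            v_next = vals[order[t + 1]]
                            if v_next == v_here:
                                continue
                            nr = nn - nl
                            pr = pos - pl
                            fl = pl / nl
                            fr = pr / nr
                            child = (nl * 2.0 * fl * (1.0 - fl)
                                     + nr * 2.0 * fr * (1.0 - fr)) / nn
                            gain = parent_imp - child
                            if gain > best_gain:
                                best_gain = gain
                                best_feat = f
                                best_val = 0.5 * (v_here + v_next)
                                best_is_cat = False
                if best_feat < 0:
                    make_leaf = True

        if make_leaf:
            feature[node] = -1
            split_val[node] = 0.0
            left[node] = -1
            right[node] = -1
            leaf_prop[node] = prop
            leaf_n[node] = nn
            continue

        # stable partition of idx[lo:hi] into left then right
        nl = 0
        for t in range(lo, hi):
            v = X[idx[t], best_feat]
            go_left = (v == best_val) if best_is_cat else (v < best_val)
            if go_left:
                buf[nl] = idx[t]
                nl += 1
        nr = 0
        for t in range(lo, hi):
            v = X[idx[t], best_feat]
            go_left = (v == best_val) if best_is_cat else (v < best_val)
            if not go_left:
                buf[nl + nr] = idx[t]
                nr += 1
        for t in range(nn):
            idx[lo + t] = buf[t]

        lchild = n_nodes
        rchild = n_nodes + 1
        n_nodes += 2
        feature[node] = best_feat
        split_val[node] = best_val
        left[node] = lchild
        right[node] = rchild
        leaf_prop[node] = prop
        leaf_n[node] = nn
        # push right first so left is processed next (stable node numbering)
        st_node[top] = rchild; st_lo[top] = lo + nl; st_hi[top] = hi; top += 1
        st_node[top] = lchild; st_lo[top] = lo; st_hi[top] = lo + nl; top += 1

    return n_nodes


@njit(cache=True)
def _traverse(feature, split_val, left, right, leaf_prop, is_cat, X, rows, out):  # pragma: no cover
    for r in range(rows.shape[0]):
        i = rows[r]
        node = 0
        while feature[node] >= 0:
            f = feature[node]
            v = X[i, f]
            if is_cat[f]:
                node = left[node] if v == split_val[node] else right[node]
            else:
                node = left[node] if v < split_val[node] else right[node]
        out[r] = leaf_prop[node]


# ---------------------------------------------------------------------------
# Fitting and prediction
# ---------------------------------------------------------------------------

def _design_matrix(G: GenotypeMatrix, covariates: np.ndarray | None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Stack SNP counts and covariates into one feature matrix."""
    X = G.counts.astype(np.float64)
    is_cat = np.ones(G.n_snps, dtype=np.bool_)
    if covariates is not None and covariates.shape[1] > 0:
        X = np.column_stack([X, covariates.astype(np.float64)])
        is_cat = np.concatenate([is_cat, np.zeros(covariates.shape[1], np.bool_)])
    return np.ascontiguousarray(X), is_cat


def resolve_mtry(mtry: int | None, n_features: int) -> int:
    return int(math.ceil(math.sqrt(n_features))) if mtry is None else int(mtry)


def fit_forest(G: GenotypeMatrix, pheno: PhenotypeTable, config: ForestConfig,
               ) -> Forest:
    """Grow a probability-machine forest on complete genotypes.

    Deterministic given (data, config.seed). An all-one-class outcome yields
    a degenerate but valid forest of single-terminal trees.
    """
    if G.has_missing():
        raise ValueError("fit_forest requires complete genotypes")
    if G.n_samples != pheno.n_samples:
        raise ValueError("genotype/phenotype sample count mismatch")
    X, is_cat = _design_matrix(G, pheno.covariates)
    n, n_feat = X.shape
    mtry = resolve_mtry(config.mtry, n_feat)
    if mtry > n_feat:
        raise ValueError(f"mtry={mtry} exceeds {n_feat} features")

    if config.split_weights is not None:
        sw = np.asarray(config.split_weights, dtype=np.float64)
        if sw.shape != (G.n_snps,):
            raise ValueError("split_weights must align with the SNP list")
        if (sw < 0).any() or not np.isfinite(sw).all():
            raise ValueError("split_weights must be finite and non-negative")
        cov_w = float(sw.max()) if sw.size else 1.0
        weights = np.concatenate([sw, np.full(n_feat - G.n_snps, cov_w)])
    else:
        weights = np.ones(n_feat, dtype=np.float64)

    y = np.ascontiguousarray(pheno.y, dtype=np.int64)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF0E5]))
    tree_seeds = rng.integers(0, 2**31 - 1, size=config.ntree, dtype=np.int64)

    max_nodes = 2 * n + 1
    trees: list[Tree] = []
    inbag_mult = np.zeros((config.ntree, n), dtype=np.int32)
    feat = np.empty(max_nodes, np.int64)
    sval = np.empty(max_nodes, np.float64)
    lft = np.empty(max_nodes, np.int64)
    rgt = np.empty(max_nodes, np.int64)
    prop = np.empty(max_nodes, np.float64)
    lfn = np.empty(max_nodes, np.int64)
    for t in range(config.ntree):
        if config.bootstrap:
            inbag = rng.integers(0, n, size=n).astype(np.int64)
        else:
            inbag = np.arange(n, dtype=np.int64)
        np.add.at(inbag_mult[t], inbag, 1)
        n_nodes = _grow_tree(X, y, inbag, is_cat, weights, mtry,
                             config.min_node_size, int(tree_seeds[t]) % (2**32),
                             feat, sval, lft, rgt, prop, lfn)
        trees.append(Tree(
            feature=feat[:n_nodes].copy(), split_val=sval[:n_nodes].copy(),
            left=lft[:n_nodes].copy(), right=rgt[:n_nodes].copy(),
            leaf_prop=prop[:n_nodes].copy(), leaf_n=lfn[:n_nodes].copy()))

    return Forest(
        trees=trees, snp_ids=G.snp_ids,
        covariate_names=list(pheno.covariate_names) if pheno.covariates is not None else [],
        is_categorical=is_cat, config=config,
        inbag=inbag_mult if config.bootstrap else None,
        _train_X=X,
    )


def _check_schema(f: Forest, G_new: GenotypeMatrix,
                  covariates: np.ndarray | None) -> np.ndarray:
    missing = [s for s in f.snp_ids if s not in set(G_new.snp_ids)]
    if missing:
        raise SchemaError(f"genotypes lack fitted SNP(s): {missing[:5]}")
    G_sub = G_new.subset_snps(f.snp_ids)
    if G_sub.has_missing():
        raise ValueError("prediction requires complete genotypes")
    n_cov = f.n_features - len(f.snp_ids)
    if n_cov:
        if covariates is None or covariates.shape[1] != n_cov:
            raise SchemaError(f"forest was fitted with {n_cov} covariate(s)")
        X = np.column_stack([G_sub.counts.astype(np.float64), covariates])
    else:
        X = G_sub.counts.astype(np.float64)
    return np.ascontiguousarray(X)


def predict_proba(f: Forest, G_new: GenotypeMatrix,
                  covariates: np.ndarray | None = None) -> np.ndarray:
    """Disease-probability estimates: average terminal proportion over trees."""
    X = _check_schema(f, G_new, covariates)
    n = X.shape[0]
    rows = np.arange(n, dtype=np.int64)
    acc = np.zeros(n, dtype=np.float64)
    out = np.empty(n, dtype=np.float64)
    for tr in f.trees:
        _traverse(tr.feature, tr.split_val, tr.left, tr.right, tr.leaf_prop,
                  f.is_categorical, X, rows, out)
        acc += out
    return acc / f.ntree


def oob_proba(f: Forest) -> np.ndarray:
    """Out-of-bag probability per training sample (NaN where never OOB)."""
    if f.inbag is None or f._train_X is None:
        raise ValueError("oob_proba requires a bootstrap forest with training data")
    n = f._train_X.shape[0]
    acc = np.zeros(n, dtype=np.float64)
    cnt = np.zeros(n, dtype=np.int64)
    out_buf = np.empty(n, dtype=np.float64)
    for t, tr in enumerate(f.trees):
        rows = np.flatnonzero(f.inbag[t] == 0).astype(np.int64)
        if rows.size == 0:
            continue
        _traverse(tr.feature, tr.split_val, tr.left, tr.right, tr.leaf_prop,
                  f.is_categorical, f._train_X, rows, out_buf[:rows.size])
        acc[rows] += out_buf[:rows.size]
        cnt[rows] += 1
    with np.errstate(invalid="ignore"):
        res = acc / cnt
    res[cnt == 0] = np.nan
    return res


# ---------------------------------------------------------------------------
# Serialization (versioned, self-describing npz)
# ---------------------------------------------------------------------------

def save_forest(f: Forest, path: str | Path) -> None:
    """Serialize to an npz archive with a JSON metadata header.

    Trees are concatenated with per-tree node offsets. In-bag sets and the
    training matrix are not stored; a reloaded forest predicts identically
    but cannot produce OOB estimates.
    """
    offsets = np.cumsum([0] + [t.n_nodes for t in f.trees])
    meta = {
        "format": "rfgrs-forest",
        "version": SERIAL_FORMAT_VERSION,
        "snp_ids": f.snp_ids,
        "covariate_names": f.covariate_names,
        "config": {
            "ntree": f.config.ntree,
            "mtry": f.config.mtry,
            "min_node_size": f.config.min_node_size,
            "bootstrap": f.config.bootstrap,
            "seed": f.config.seed,
            "weighted": f.config.split_weights is not None,
        },
    }
    np.savez_compressed(
        Path(path),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        offsets=offsets,
        feature=np.concatenate([t.feature for t in f.trees]),
        split_val=np.concatenate([t.split_val for t in f.trees]),
        left=np.concatenate([t.left for t in f.trees]),
        right=np.concatenate([t.right for t in f.trees]),
        leaf_prop=np.concatenate([t.leaf_prop for t in f.trees]),
        leaf_n=np.concatenate([t.leaf_n for t in f.trees]),
        is_categorical=f.is_categorical,
        split_weights=(np.asarray(f.config.split_weights, np.float64)
                       if f.config.split_weights is not None else np.empty(0)),
    )


def load_forest(path: str | Path) -> Forest:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        if meta.get("format") != "rfgrs-forest":
            raise ValueError(f"{path}: not a serialized forest")
        if meta.get("version") != SERIAL_FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported forest format version")
        offsets = z["offsets"]
        trees = []
        for k in range(offsets.shape[0] - 1):
            a, b = int(offsets[k]), int(offsets[k + 1])
            trees.append(Tree(
                feature=z["feature"][a:b], split_val=z["split_val"][a:b],
                left=z["left"][a:b], right=z["right"][a:b],
                leaf_prop=z["leaf_prop"][a:b], leaf_n=z["leaf_n"][a:b]))
        cfg_d = meta["config"]
        sw = z["split_weights"]
        config = ForestConfig(
            ntree=cfg_d["ntree"], mtry=cfg_d["mtry"],
            min_node_size=cfg_d["min_node_size"],
            split_weights=sw if sw.size else None,
            bootstrap=cfg_d["bootstrap"], seed=cfg_d["seed"])
        return Forest(
            trees=trees, snp_ids=list(meta["snp_ids"]),
            covariate_names=list(meta["covariate_names"]),
            is_categorical=z["is_categorical"].astype(np.bool_),
            config=config, inbag=None, _train_X=None)
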