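"""Marginal SNP association scans and association-based split weights.

``marginal_scan`` fits, per SNP m, the logistic regression

    logit P(y_i = 1) = alpha + beta * x_im + gamma' Z_i

by maximum likelihood and reports the Wald two-sided p-value of beta (using
the observed-information standard error). When no covariates are present the
scan runs as a single Newton-Raphson vectorized across all SNPs; with
covariates each SNP is fit through statsmodels.

``p_to_z`` and ``z_to_weights`` implement the association-weighted split
sampling transform: z_m = |Phi^-1(p_m / 2)| followed by min-max normalization
to [0, 1], so the most significant SNP gets weight 1 and the least gets 0.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.special import expit
from scipy.stats import chi2, norm

from .io_formats import GenotypeMatrix, PhenotypeTable, SummaryStats

logger = logging.getLogger("rfgrs")

_MAX_ABS_BETA = 15.0  # |log-odds| beyond this signals separation
_NEWTON_TOL = 1e-8
_NEWTON_MAXITER = 50


def marginal_scan(G: GenotypeMatrix, pheno: PhenotypeTable) -> SummaryStats:
    """Per-SNP marginal logistic Wald scan.

    Monomorphic SNPs and SNPs whose fit fails to converge (complete
    separation) are reported with beta=0, p=1 and flagged; the scan never
    aborts. Effect alleles are the counted minor alleles.
    """
    if G.has_missing():
        raise ValueError("marginal_scan requires complete genotypes "
                         "(apply impute_mode first)")
    y = np.asarray(pheno.y, dtype=np.float64)
    if y.min() == y.max():
        raise ValueError("marginal_scan requires both outcome classes")
    if G.n_samples != pheno.n_samples:
        raise ValueError("genotype/phenotype sample count mismatch")

    X = G.counts.astype(np.float64)
    mono = X.min(axis=0) == X.max(axis=0)

    if pheno.covariates is None:
        # chunk columns to bound the n x m work arrays
        chunk = max(1, int(2e7) // max(X.shape[0], 1))
        parts = [_scan_vectorized(X[:, j:j + chunk], y)
                 for j in range(0, X.shape[1], chunk)]
        beta = np.concatenate([p[0] for p in parts])
        se = np.concatenate([p[1] for p in parts])
        flag = np.concatenate([p[2] for p in parts])
    else:
        beta, se, flag = _scan_with_covariates(X, y, pheno.covariates)

    flag |= mono
    beta[flag] = 0.0
    se[flag] = np.nan
    wald = np.zeros_like(beta)
    ok = ~flag
    wald[ok] = (beta[ok] / se[ok]) ** 2
    p = np.ones_like(beta)
    p[ok] = chi2.sf(wald[ok], df=1)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    n_flagged = int(flag.sum())
    if n_flagged:
        logger.warning("marginal_scan: %d SNP(s) flagged (monomorphic or "
                       "non-converged); reported with beta=0, p=1", n_flagged)
    return SummaryStats(
        ids=np.asarray(G.snp_ids, dtype=object),
        effect_allele=np.asarray([v.alt_allele for v in G.snps], dtype=object),
        beta=beta, p=p, se=se, flag=flag,
    )


def _scan_vectorized(X: np.ndarray, y: np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Newton-Raphson for logit(y) ~ 1 + x, run jointly over all SNP columns."""
    n, m = X.shape
    a = np.full(m, float(np.log(y.mean() / (1 - y.mean()))))
    b = np.zeros(m)
    converged = np.zeros(m, dtype=bool)
    X2 = X * X
    for _ in range(_NEWTON_MAXITER):
        eta = a[None, :] + X * b[None, :]
        mu = expit(eta)
        w = mu * (1.0 - mu)
        r = y[:, None] - mu
        g0 = r.sum(axis=0)
        g1 = (X * r).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (X * w).sum(axis=0)
        h11 = (X2 * w).sum(axis=0)
        det = h00 * h11 - h01 * h01
        bad = det <= 1e-12
        det[bad] = 1.0
        da = (h11 * g0 - h01 * g1) / det
        db = (h00 * g1 - h01 * g0) / det
        da[bad] = 0.0
        db[bad] = 0.0
        step = np.maximum(np.abs(da), np.abs(db))
        a += da
        b += db
        newly = step < _NEWTON_TOL
        converged |= newly
        if converged.all():
            break
    # observed-information SE of beta: sqrt(h00 / det) at the optimum
    eta = a[None, :] + X * b[None, :]
    mu = expit(eta)
    w = mu * (1.0 - mu)
    h00 = w.sum(axis=0)
    h01 = (X * w).sum(axis=0)
    h11 = (X2 * w).sum(axis=0)
    det = h00 * h11 - h01 * h01
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(det > 0, h00 / np.maximum(det, 1e-300), np.inf))
    flag = (~converged) | (np.abs(b) > _MAX_ABS_BETA) | ~np.isfinite(se)
    return b, se, flag


def _scan_with_covariates(X: np.ndarray, y: np.ndarray, Z: np.ndarray,
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP statsmodels logistic fits adjusting for covariates Z."""
    import statsmodels.api as sm

    n, m = X.shape
    beta = np.zeros(m)
    se = np.full(m, np.nan)
    flag = np.zeros(m, dtype=bool)
    base = np.column_stack([np.ones(n), np.zeros(n), Z])
    for j in range(m):
        base[:, 1] = X[:, j]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, base).fit(disp=0, maxiter=100)
            if (not res.mle_retvals.get("converged", False)
                    or abs(res.params[1]) > _MAX_ABS_BETA):
                flag[j] = True
            else:
                beta[j] = res.params[1]
                se[j] = res.bse[1]
        except Exception:
            flag[j] = True
    return beta, se, flag


def p_to_z(p) -> np.ndarray | float:
    """z = |Phi^-1(p/2)| for two-sided p-values in (0, 1]."""
    arr = np.asarray(p, dtype=np.float64)
    if arr.size and (np.min(arr) <= 0 or np.max(arr) > 1):
        raise ValueError("p-values must lie in (0, 1]")
    z = norm.isf(arr / 2.0)
    z = np.abs(z)
    return float(z) if np.isscalar(p) else z


def z_to_weights(z, weight_floor: float = 0.0) -> np.ndarray:
    """Min-max normalize z-values to split-selection weights in [0, 1].

    w_m = (z_m - z_min) / (z_max - z_min); a degenerate (constant) z vector
    yields uniform weights of 1. With the default floor of 0 the minimum-z SNP
    can never be drawn as a split candidate; ``weight_floor`` > 0 keeps every
    SNP samplable.
    """
    z = np.asarray(z, dtype=np.float64)
    if z.size == 0:
        raise ValueError("empty z vector")
    if not np.isfinite(z).all() or (z < 0).any():
        raise ValueError("z-values must be finite and non-negative")
    zmin, zmax = float(z.min()), float(z.max())
    if zmax == zmin:
        return np.ones_like(z)
    w = (z - zmin) / (zmax - zmin)
    if weight_floor > 0:
        w = np.maximum(w, weight_floor)
    return w
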