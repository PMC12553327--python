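"""Predictive-performance metrics and the simulation replication driver.

Nagelkerke R^2 (NR2) rescales the Cox-Snell pseudo-R^2 of the logistic
regression of the outcome on the GRS so its maximum is 1:

    NR2 = [1 - (L0 / L1)^(2/n)] / [1 - L0^(2/n)]

with L0, L1 the maximized null and full likelihoods. AUC is the Mann-Whitney
probability that a random case outscores a random control (ties count 1/2).

``run_experiment`` reproduces the simulation protocol end to end: per
replication it simulates paired base/target cohorts under a scenario, scans
the base cohort for summary statistics, splits the target 80/20, trains each
requested (method, mode) scorer on the training split and reports test-set
NR2 and AUC. Seed streams are derived per replication and per method, so
adding or removing a method never perturbs another method's numbers.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_formats import GenotypeMatrix, PhenotypeTable, SummaryStats
from . import synthetic_data as sd
from .association import marginal_scan
from .grs_pipeline import HyperGrid, predict_grs, train_grs

logger = logging.getLogger("rfgrs")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _fit_logit_ll(y: np.ndarray, X: np.ndarray | None) -> float:
    """Maximized Bernoulli log-likelihood of logit(y) ~ 1 (+ X columns).

    Under complete separation the likelihood is capped by clipping fitted
    probabilities at the convergence tolerance.
    """
    import statsmodels.api as sm

    n = y.shape[0]
    if X is None or X.shape[1] == 0:
        pbar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
        return float(y.sum() * np.log(pbar) + (n - y.sum()) * np.log(1 - pbar))
    design = np.column_stack([np.ones(n), X])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            mu = res.predict(design)
        except Exception:
            logger.warning("nagelkerke_r2: separation detected; "
                           "likelihood capped at the convergence tolerance")
            res = sm.Logit(y, design).fit_regularized(disp=0, alpha=1e-8,
                                                      maxiter=500)
            mu = expit(design @ res.params)
    mu = np.clip(mu, 1e-10, 1 - 1e-10)
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def nagelkerke_r2(y, score, covariates=None, null_mode: str = "marginal",
                  ) -> float:
    """Nagelkerke pseudo-R^2 of the outcome regressed on a risk score.

    ``null_mode="marginal"``: full model is intercept + score, null is
    intercept only. ``null_mode="incremental"``: covariates enter both
    models, so the value measures the score's increment over covariates.
    A constant score carries no information and returns exactly 0.
    """
    y = np.asarray(y, dtype=np.float64)
    score = np.asarray(score, dtype=np.float64)
    if y.min() == y.max():
        raise ValueError("nagelkerke_r2 requires both outcome classes")
    if not np.isfinite(score).all():
        raise ValueError("scores must be finite")
    if null_mode not in ("marginal", "incremental"):
        raise ValueError(f"unknown null_mode {null_mode!r}")
    n = y.shape[0]

    if score.min() == score.max():
        return 0.0
    cov = None
    if null_mode == "incremental" and covariates is not None:
        cov = np.asarray(covariates, dtype=np.float64)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[1] == 0:
            cov = None

    full = np.column_stack([score] + ([cov] if cov is not None else []))
    ll_full = _fit_logit_ll(y, full)
    ll_null = _fit_logit_ll(y, cov)
    cs = 1.0 - np.exp((2.0 / n) * (ll_null - ll_full))
    denom = 1.0 - np.exp((2.0 / n) * ll_null)
    if denom <= 0:
        return 0.0
    return float(np.clip(cs / denom, 0.0, 1.0))


def auc(y, score) -> float:
    """Mann-Whitney AUC; ties between a case and a control count 1/2."""
    y = np.asarray(y)
    score = np.asarray(score, dtype=np.float64)
    if y.min() == y.max():
        raise ValueError("auc requires both outcome classes")
    from sklearn.metrics import roc_auc_score
    return float(roc_auc_score(y, score))


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Class-agnostic random 80/20 train/test assignment."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    @classmethod
    def make(cls, n: int, seed: int, train_frac: float = 0.8) -> "SplitPlan":
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5711]))
        perm = rng.permutation(n)
        n_train = int(round(train_frac * n))
        return cls(train_idx=np.sort(perm[:n_train]),
                   test_idx=np.sort(perm[n_train:]), seed=seed)

    def __post_init__(self) -> None:
        overlap = np.intersect1d(self.train_idx, self.test_idx)
        if overlap.size:
            raise ValueError("train/test assignments overlap")


def kfold_indices(n: int, y: np.ndarray, k: int, seed: int,
                  ) -> list[tuple[np.ndarray, np.ndarray]]:
    """k disjoint, exhaustive folds; re-drawn stratified if a fold lacks a class."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF01D]))
    perm = rng.permutation(n)
    folds = [np.sort(perm[i::k]) for i in range(k)]
    y = np.asarray(y)

    def degenerate(fds):
        for f in fds:
            mask = np.ones(n, dtype=bool)
            mask[f] = False
            if y[f].min() == y[f].max() or y[mask].min() == y[mask].max():
                return True
        return False

    if degenerate(folds):
        logger.warning("kfold: random folds missed an outcome class; "
                       "re-drawing stratified folds")
        folds = [[] for _ in range(k)]
        for cls_val in np.unique(y):
            members = rng.permutation(np.flatnonzero(y == cls_val))
            for i, m in enumerate(members):
                folds[i % k].append(m)
        folds = [np.sort(np.asarray(f, dtype=np.intp)) for f in folds]
    out = []
    for f in folds:
        mask = np.ones(n, dtype=bool)
        mask[f] = False
        out.append((np.flatnonzero(mask), f))
    return out


def crossval_nr2(G: GenotypeMatrix, pheno: PhenotypeTable, method: str,
                 mode: str, base: SummaryStats | None, grid: HyperGrid,
                 seed: int, k: int = 5, null_mode: str = "marginal",
                 ) -> tuple[float, list[float]]:
    """5-fold cross-validated test NR2 (mean and per-fold values)."""
    n = G.n_samples
    if n < 50:
        raise ValueError("crossval_nr2 requires n >= 50")
    per_fold = []
    for fold, (tr, te) in enumerate(kfold_indices(n, pheno.y, k, seed)):
        model = train_grs(method, mode, G.subset_samples(tr),
                          pheno.subset_samples(tr), base, grid,
                          _stream_seed(seed, "cv", fold))
        cov_te = None if pheno.covariates is None else pheno.covariates[te]
        scores = predict_grs(model, G.subset_samples(te), cov_te)
        per_fold.append(nagelkerke_r2(pheno.y[te], scores, cov_te,
                                      null_mode=null_mode))
    return float(np.mean(per_fold)), per_fold


# ---------------------------------------------------------------------------
# Replication driver
# ---------------------------------------------------------------------------

def _stream_seed(master: int, *parts) -> int:
    token = repr((int(master),) + tuple(parts)).encode()
    return zlib.crc32(token) & 0x7FFFFFFF


def run_experiment(scenarios, methods, modes, reps: int, config: sd.SimConfig,
                   seed: int, grid: HyperGrid | None = None,
                   ld_spec: sd.LDBlockSpec | None = None,
                   center_intercept: bool = True) -> pd.DataFrame:
    """Run the full simulation protocol and tabulate test NR2/AUC.

    Per (scenario, replication): simulate target and base genotypes, draw
    paired effect models sharing ``config.q`` causal SNPs, simulate both
    phenotypes (with the intercept centered so prevalence sits near 0.5 when
    ``center_intercept``), compute base summary statistics by a marginal scan
    of the base cohort, split the target 80/20 and train/score every
    (method, mode). Failures are recorded and the run continues.
    """
    if grid is None:
        grid = HyperGrid.desk()
    if ld_spec is None:
        ld_spec = sd.LDBlockSpec.uniform_blocks(config.n_snps)
    if isinstance(scenarios, str):
        scenarios = [scenarios]
    if isinstance(methods, str):
        methods = [methods]
    if isinstance(modes, str):
        modes = [modes]

    rows = []
    n_failures = 0
    for scenario in scenarios:
        for rep in range(reps):
            try:
                rows_rep, rep_failures = _run_replication(
                    scenario, rep, methods, modes, config, seed, grid,
                    ld_spec, center_intercept)
            except Exception as exc:
                logger.warning("replication %s rep %d failed during data "
                               "generation: %s", scenario, rep, exc)
                rows_rep = [{"scenario": scenario, "method": m, "mode": mo,
                             "rep": rep, "nr2": np.nan, "auc": np.nan,
                             "error": str(exc)}
                            for m in methods for mo in modes]
                rep_failures = len(rows_rep)
            n_failures += rep_failures
            rows.extend(rows_rep)
    if n_failures:
        logger.warning("run_experiment: %d replication failure(s)", n_failures)
    df = pd.DataFrame(rows)
    df.attrs["n_failures"] = n_failures
    return df


def _run_replication(scenario, rep, methods, modes, config, seed, grid,
                     ld_spec, center_intercept) -> tuple[list[dict], int]:
    """Simulate one replication and train/score every (method, mode)."""
    G_t = sd.simulate_genotypes(config.n_target, ld_spec,
                                _stream_seed(seed, scenario, rep, "gt"))
    G_b = sd.simulate_genotypes(config.n_base, ld_spec,
                                _stream_seed(seed, scenario, rep, "gb"))
    mafs = [v.maf for v in G_t.snps]
    em_t, em_b = sd.make_base_target(
        scenario, config, _stream_seed(seed, scenario, rep, "fx"),
        snp_mafs=mafs)
    if center_intercept:
        em_t = sd.calibrate_intercept(G_t, em_t)
        em_b = sd.calibrate_intercept(G_b, em_b)
    y_t = sd.simulate_phenotype(G_t, em_t,
                                _stream_seed(seed, scenario, rep, "yt"))
    y_b = sd.simulate_phenotype(G_b, em_b,
                                _stream_seed(seed, scenario, rep, "yb"))
    pheno_t = PhenotypeTable(samples=G_t.samples, y=y_t)
    pheno_b = PhenotypeTable(samples=G_b.samples, y=y_b)

    base_stats = None
    if "BT" in modes:
        base_stats = marginal_scan(G_b, pheno_b)

    plan = SplitPlan.make(config.n_target,
                          _stream_seed(seed, scenario, rep, "split"))
    G_tr = G_t.subset_samples(plan.train_idx)
    G_te = G_t.subset_samples(plan.test_idx)
    ph_tr = pheno_t.subset_samples(plan.train_idx)
    y_te = pheno_t.y[plan.test_idx]
    assert not np.intersect1d(plan.train_idx, plan.test_idx).size

    rows: list[dict] = []
    n_failures = 0
    for method in methods:
        for mode in modes:
            mseed = _stream_seed(seed, scenario, rep, method, mode)
            try:
                model = train_grs(method, mode, G_tr, ph_tr,
                                  base_stats if mode == "BT" else None,
                                  grid, mseed)
                scores = predict_grs(model, G_te)
                rows.append({
                    "scenario": scenario, "method": method,
                    "mode": mode, "rep": rep,
                    "nr2": nagelkerke_r2(y_te, scores),
                    "auc": auc(y_te, scores),
                    "n_snps": len(model.snp_ids),
                    "objective": model.objective,
                    **{f"hp_{k}": v for k, v in model.hyperparams.items()},
                })
            except Exception as exc:  # keep the run going
                n_failures += 1
                logger.warning("replication failed (%s/%s/%s rep %d): %s",
                               scenario, method, mode, rep, exc)
                rows.append({"scenario": scenario, "method": method,
                             "mode": mode, "rep": rep,
                             "nr2": np.nan, "auc": np.nan,
                             "error": str(exc)})
    return rows, n_failures


def summarize_experiment(df: pd.DataFrame) -> pd.DataFrame:
    """Mean/median/IQR of test NR2 and AUC per (scenario, method, mode)."""
    def iqr(x):
        return float(np.subtract(*np.percentile(x.dropna(), [75, 25])))

    return (df.groupby(["scenario", "method", "mode"])
            .agg(nr2_mean=("nr2", "mean"), nr2_median=("nr2", "median"),
                 nr2_iqr=("nr2", iqr), auc_mean=("auc", "mean"),
                 n_reps=("rep", "count"))
            .reset_index())


def plot_experiment(df: pd.DataFrame, path=None):
    """NR2 boxplots, one panel per scenario, methods on the x-axis."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scenarios = sorted(df["scenario"].unique())
    fig, axes = plt.subplots(1, len(scenarios),
                             figsize=(4 * len(scenarios), 4), squeeze=False)
    for ax, scenario in zip(axes[0], scenarios):
        sub = df[df["scenario"] == scenario]
        labels, data = [], []
        for (method, mode), grp in sub.groupby(["method", "mode"]):
            labels.append(f"{method}\n{mode}")
            data.append(grp["nr2"].dropna().to_numpy())
        ax.boxplot(data, tick_labels=labels)
        ax.set_title(f"Scenario {scenario}")
        ax.set_ylabel("test NR2")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
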