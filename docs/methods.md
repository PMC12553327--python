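# Methods

## The probability-machine forest GRS

For individual *i* with minor-allele counts `x_i ∈ {0,1,2}^M` and covariates
`Z_i`, the genetic risk score is the forest-estimated disease probability.
Each of `ntree` trees is grown on a bootstrap sample (n draws with
replacement; bootstrap size equals the training-set size, the conventional
default). Terminal nodes store the in-bag disease proportion (cases / total
in the node). A new individual is routed down every tree and the terminal
proportions are averaged; this probability-machine estimate avoids the
degenerate 0/1 scores that majority voting produces when the true risk is
extreme.

SNP features are 3-level categorical. Candidate splits are the three
one-category-vs-rest partitions {0}|{1,2}, {1}|{0,2}, {2}|{0,1}, which span
all binary partitions of a 3-level factor, so no mode of inheritance
(additive/dominant/recessive) is imposed. Numeric covariates split at the
best midpoint threshold. The split criterion is Gini impurity decrease, the
standard classification default; ties between equal-gain splits break toward
the lowest feature index, then the lowest partition index, making tree
growth fully deterministic given the seed.

At each node, `mtry` candidate features are drawn without replacement.
Weighted candidate sampling (for wRF) uses exponential-race keys: feature
*f* with weight `w_f > 0` draws `key_f = −log(U_f)/w_f` and the `mtry`
smallest keys win. This is distributionally identical to sequential
probability-proportional-to-weight draws with renormalization; a feature's
inclusion probability is increasing in its weight, and zero-weight features
are never drawn. With uniform weights the scheme reduces exactly to uniform
sampling without replacement (the unweighted path runs through the same
code, so the equivalence is bitwise).

Out-of-bag (OOB) probabilities — averages over only the trees whose
bootstrap excluded the sample — serve as internal validation. Samples that
are in-bag for every tree are undefined and excluded from tuning statistics.

## SNP preselection and tuning (ctRF and friends)

Clumping is the greedy PLINK-style procedure: repeatedly take the most
significant unassigned SNP as an index SNP and discard unassigned SNPs
within `window_bp` base pairs whose genotype r² (squared Pearson correlation
of count vectors) exceeds the cutoff. Discarded SNPs never seed their own
clump. Ties in p break by (chromosome, position, id). LD is always computed
on the target *training* genotypes; test samples never touch scanning,
clumping, tuning or fitting. The window defaults to 250 kb, the common
convention in C+T pipelines. Thresholding keeps SNPs with p strictly below
the cutoff.

The grid search scores every (r² cutoff, p threshold, ntree, mtry, minimum
node size) combination by the NR2 of the outcome regressed on the OOB GRS in
the training split, and refits the winner on the full training split with a
fresh seed stream (the tuning-time forest is discarded). Ties break toward
fewer retained SNPs, then smaller ntree, then grid order. Default grid:
r² ∈ {0.1, 0.2, 0.5, 0.8}, p ∈ {1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1},
ntree 500, mtry ∈ {⌈√M⌉, ⌈M/10⌉, ⌈M/3⌉}, minimum node size ∈ {1, 5, 10} —
declared conventions; the `desk()` preset (r² ∈ {0.1, 0.5}, p ∈ {0.05, 1},
ntree 200, ⌈√M⌉, node size 5) is used for the replication experiments so
they run in minutes on one CPU.

Design choice: ctRF's effective grid is the cross of (r² cutoffs ∪
{no clumping}) × (p thresholds ∪ {1}). This makes it a strict superset of
the cRF grid (p fixed at 1) and the tRF grid (clumping off), so ctRF's best
training objective provably cannot fall below either ablation's. To make
that dominance exact rather than merely expected, the forest seed at a grid
point is derived (by CRC) from the master seed, the retained SNP set and the
forest hyperparameters — not from the method name — so a grid point shared
by two methods yields the bitwise-identical forest.

wRF applies no clumping or thresholding: association weighting is the
alternative to filtering. Its weights are `w_m = (z_m − z_min)/(z_max −
z_min)` with `z_m = |Φ⁻¹(p_m/2)|`; the printed form of this normalization is
min–max, the only reading that keeps weights in [0, 1]. The minimum-z SNP
gets weight exactly 0 and is never a split candidate; a `weight_floor`
option (default 0) avoids total exclusion if desired. Covariates are not
association-weighted; they receive the maximum SNP weight so they stay
samplable — a declared convention, as weighting is defined for SNPs only.

`mtry` counts all features (retained SNPs plus covariates).

## Association scans and p-value sourcing

The marginal scan fits `logit P(y=1) = α + β x_m + γ'Z` per SNP by maximum
likelihood and reports the two-sided Wald p-value using the
observed-information standard error (no small-sample correction).
Monomorphic SNPs and fits that fail to converge (complete separation,
|β| > 15 on the log-odds scale) are flagged and reported with β = 0, p = 1;
the scan never aborts. Without covariates the scan runs as one
Newton–Raphson vectorized across SNP columns (tolerance 1e-8, 50 iterations,
column-chunked to bound memory); with covariates each SNP goes through
statsmodels. The two paths agree with a generic GLM fit to 1e-6, which the
test suite checks.

In BT mode, base summary statistics are harmonized to the target by SNP id:
betas are negated when the base effect allele equals the target's major
allele, and SNPs whose effect allele matches neither target allele are
dropped and counted. Strand-ambiguous (A/T, C/G) SNPs are matched by id
only, with no strand-flip inference — id matching is the declared merge
convention. p-values pass through untouched. In Tonly mode the statistics
come from a marginal scan of the training split only.

## The simulation engine

Genotypes: per LD block, a latent standard-normal AR(1) vector with adjacent
correlation `rho` (default 0.6, blocks of 10 SNPs, 5 kb spacing) is
thresholded per SNP at the Hardy–Weinberg quantiles `(1−f)²` and
`(1−f)² + 2f(1−f)` for a MAF `f` drawn uniformly from `maf_range` (default
0.01–0.5). Genotype frequencies are therefore HWE-consistent by
construction, and clumping has real LD structure to remove. This latent
Gaussian stand-in reproduces blockwise correlation but not the empirical
LD-decay or allele-frequency spectrum of real chromosome data: passing tests
demonstrate the methods' behavior under controlled LD, not performance on
any particular cohort.

Phenotypes follow logistic models over 100 causal SNPs: (1) additive main
effects; (2) 100 two-way interaction pairs linking causal SNPs 1–50 with
51–100; (3) 50 main effects plus 100 pairs; (4) 30 three-way terms, one SNP
from each of three disjoint groups of 33 (the 100th causal SNP is carried
but inert); (5) quadratic effects, either unrestricted (5a) or with causal
SNPs drawn only from MAF > 0.3 (5b). Effect sizes are Normal(μ, 0.1) log
odds ratios, with named presets (log 1.1, log 1.6) and (log 1.5, log 2) for
the (main, interaction) means. Exactly half of the main-effect (and, for
consistency, quadratic-effect) βs are negated; interaction βs are left
unflipped, as sign flipping is specified for main effects only. Causal SNPs
may fall in the same LD block; no constraint is imposed.

Base/target pairing: the base population reuses the target's causal-term
graph with the `100 − q` non-shared causal SNPs substituted by fresh draws
(disjoint from the target's set); terms whose member SNPs are all shared
keep identical βs, terms touching a substituted SNP are redrawn from the
same distribution. Base summary statistics are produced by a marginal scan
of the simulated base cohort — individual-level base data never reach the
GRS analysis.

Intercept: the raw models have no intercept term. With the synthetic
uniform-MAF spectrum, the all-positive-mean interaction terms would push
prevalence toward 1 and leave one outcome class nearly empty, so
`calibrate_intercept` sets β₀ = −mean(η) on the simulated cohort
(prevalence ≈ 0.5) and the experiment driver applies it by default. β₀
remains configurable.

Everything — genotypes, effects, phenotypes, splits, forests — is
reproducible bit for bit from (config, seed). Per-replication and per-method
seeds are derived from the master seed by hashing context tokens, so every
method sees identical data within a replication and removing a method never
changes another's numbers.

## Evaluation

NR2 = [1 − (L0/L1)^(2/n)] / [1 − L0^(2/n)] with L0, L1 the maximized null
and full likelihoods of `logit(y) ~ GRS (+ covariates)`. With
`null_mode="marginal"` (the default for simulations, which carry no
covariates) the null is intercept-only; with `"incremental"` covariates
enter both models and the value measures the score's increment. A constant
score returns exactly 0; under separation the likelihood is capped by
clipping fitted probabilities at 1e-10. AUC is the Mann–Whitney statistic
with ties counted 1/2.

The replication driver partitions the target 80/20 (class-agnostic random
split), trains every requested (method, mode) on the training split and
reports test-set NR2 and AUC; 5-fold cross-validation (random folds,
stratified re-draw if a fold misses a class, logged) is available for
real-data-style analyses. Desk-scale experiment defaults are 10
replications, 1000 SNPs, 1000 target and 2000 base samples with 200-tree
forests; paper-scale settings (10,330 SNPs, 10,654 base samples, 100
replications, 500 trees) are supported through the same configuration
objects.

## Known limitations

* The simulator has no population structure, admixture, or quantitative
  traits, and genotypes are complete by construction; real-data missingness
  is handled by explicit modal imputation (`impute_mode`), since the forest
  treats genotypes as complete 3-level factors.
* Regression forests for continuous outcomes are out of scope.
* Variable-importance measures are deliberately absent: the probability
  machine targets calibrated risk prediction, not causal SNP discovery.
* Published additive comparators (LDpred, lassosum, penalized logistic
  regression, stacked/PCA C+T) are not re-implemented; `oCT` is the additive
  reference point.
* Forest prediction is exact but in-memory; the serialized model format
  (versioned npz plus JSON) stores trees, not training data, so a reloaded
  model predicts identically but cannot produce OOB estimates.
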