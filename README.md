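# rfgrs — random-forest genetic risk scores with tuned clumping and thresholding

`rfgrs` builds genetic risk scores (GRS) for binary traits from SNP
genotypes. Instead of the usual weighted allele-count sum, the score is the
disease probability estimated by a *probability-machine* random forest: each
tree's terminal node stores its in-bag disease proportion, and an
individual's GRS is the average of those proportions across the forest,

    GRS_i = P̂(y_i = 1 | x_i, Z_i) = (1/ntree) Σ_t prop_t(x_i, Z_i),

where `x_im ∈ {0, 1, 2}` is the minor-allele count at SNP m (treated as a
3-level categorical feature) and `Z_i` are optional covariates. Because a
forest captures non-additive structure, this GRS can outperform additive
scores when the genetic architecture involves SNP–SNP interactions or other
nonlinearities.

The package is aimed at statistical geneticists who want to experiment with
forest-based polygenic prediction and at method developers who need a fully
seeded simulation harness for comparing GRS constructions.

## Methods implemented

* **ctRF** — the headline method: SNPs are preselected by greedy LD clumping
  (squared genotype correlation `r²` against a cutoff within a base-pair
  window) and p-value thresholding, and *both* filters are tuned jointly with
  the forest hyperparameters (`ntree`, `mtry`, minimum node size) by grid
  search, maximizing the Nagelkerke R² (NR2) of the outcome regressed on the
  out-of-bag GRS in the training data.
* **cRF / tRF / oRF** — ablations tuning only the clumping cutoff, only the
  p-value threshold, or applying no filtering at all.
* **wRF** — no filtering; instead each SNP's chance of being drawn among the
  `mtry` split candidates is proportional to its min-max-normalized
  association z-value, `z_m = |Φ⁻¹(p_m / 2)|`,
  `w_m = (z_m − z_min)/(z_max − z_min)`.
* **oCT** — the classic additive clumping + thresholding baseline,
  `GRS_i = Σ_m β̂_m x_im` over retained SNPs.

Association p-values can come from the target training split (**Tonly**) or
from external GWAS summary statistics, harmonized by SNP id and effect
allele (**BT**). A simulation engine generates blockwise-LD genotypes and
binary phenotypes under five architectures (additive, two-way and three-way
epistatic, mixed, quadratic), with base and target populations sharing a
configurable number `q` of the 100 causal SNPs.

## Worked example

```python
import rfgrs

# simulate a target cohort under two-way SNP-SNP interactions
config = rfgrs.SimConfig()                        # 1000 SNPs, 1000 samples
spec   = rfgrs.LDBlockSpec.uniform_blocks(1000)
G      = rfgrs.simulate_genotypes(1000, spec, seed=1)
em     = rfgrs.calibrate_intercept(G, rfgrs.draw_effects("2", config, seed=2))
y      = rfgrs.simulate_phenotype(G, em, seed=3)
pheno  = rfgrs.PhenotypeTable(G.samples, y)

plan = rfgrs.SplitPlan.make(1000, seed=11)        # 800 train / 200 test
G_tr, ph_tr = G.subset_samples(plan.train_idx), pheno.subset_samples(plan.train_idx)
G_te = G.subset_samples(plan.test_idx)

grid  = rfgrs.HyperGrid.desk()                    # 200-tree desk-scale grid
model = rfgrs.train_rf_grs("ctRF", "Tonly", G_tr, ph_tr, None, grid, seed=42)
print(model.hyperparams, len(model.snp_ids))
scores = rfgrs.predict_grs(model, G_te)
print(round(rfgrs.nagelkerke_r2(y[plan.test_idx], scores), 3))
```

This prints the tuned hyperparameters, the retained SNP count, and the
test-set NR2:

```
{'r2_cutoff': 0.1, 'p_threshold': 0.05, 'ntree': 200, 'mtry': 9, 'min_node_size': 5} 70
0.409
```

i.e. clumping at r² > 0.1 plus thresholding at p < 0.05 kept 70 of 1000
SNPs, and the resulting forest explains ≈ 41% (Nagelkerke-scaled) of the
outcome variation in held-out samples — versus 0.211 for the additive `oCT`
baseline on the same split (`rfgrs.train_oct(...)`).

The same workflow is available from the shell:

```bash
rfgrs simulate --scenario 2 --seed 1 --out data/
rfgrs train --method ctRF --geno data/target --pheno data/target_pheno.tsv \
            --seed 42 --out model.json
rfgrs predict --model model.json --geno data/target --out scores.tsv
rfgrs experiment --scenario 2 --method ctRF --method oCT --reps 10 \
                 --seed 1 --out results/
```

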