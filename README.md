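# metss — metabolomic severity scores for lung-function outcomes

`metss` builds and validates a **metabolomic severity score (metSS)**: a
weighted sum of blood-metabolite features that predicts a continuous
clinical outcome such as post-bronchodilator FEV₁ (liters) or CT lung
density (g/L) in cohorts of ever-smokers with or at risk of COPD.  It is
aimed at researchers who have sample × metabolite intensity tables from two
cohorts (training and validation) plus clinical covariates, and who want a
reproducible, fully tested pipeline from raw intensities to a validated
score and pathway interpretation.

## The model

The score is built in two penalized stages on the training cohort:

1. **Ridge initialization.** A ridge regression of the outcome *y* on the
   harmonized metabolite design *X* (penalty chosen by 10-fold CV) gives
   coefficients β̂ʳ; penalty factors are wⱼ = 1/|β̂ʳⱼ| (capped at 10⁶).
2. **Adaptive LASSO.** Coordinate descent minimizes

   (1/2n) Σᵢ ωᵢ (yᵢ − β₀ − xᵢᵀβ)² + λ Σⱼ wⱼ |βⱼ|

   over a descending λ path anchored at λ_max; 10-fold CV picks the λ with
   the lowest mean out-of-fold MSE ("λ-min" rule).  Optional observation
   weights ωᵢ support the extreme-quintile sensitivity analysis (bottom and
   top outcome quintiles up-weighted ×5).

The metSS is the resulting linear predictor, metSSᵢ = β₀ + Σⱼ βⱼ xᵢⱼ, applied
unchanged to a validation cohort whose design was built with the training
recipe.  Performance is summarized by Wherry-adjusted R² = 1 − (1−R²)(n−1)/(n−p−1)
and MSE for three OLS models — clinical covariates only, metSS only, and
metSS + covariates — with a partial F-test for the combined-vs-covariates
comparison.  Selected metabolites are tested for KEGG-style pathway
over-representation (upper-tail hypergeometric, Benjamini–Hochberg FDR) with
a topology-based pathway impact (betweenness or out-degree centrality share).

Preprocessing follows untargeted-metabolomics practice: within-batch median
normalization; subject QC on median metabolite z-scores (> 3 SD removed);
per-metabolite missingness tiers (< 20 % → kNN-imputed (k = 10) on the
natural-log scale, 20–80 % → present/absent indicator, > 80 % → dropped);
and cross-cohort harmonization keeping only metabolites with concordant
handling in both cohorts.

A synthetic-data module generates paired cohorts with known ground truth —
block-correlated log-normal intensities, left-censored missingness spanning
the three tiers, batch effects, technical noise, cohort covariate shifts —
so the whole pipeline is testable without any data download.

## Worked example

```python
from metss import (SynthConfig, generate_cohort_pair, AdaptiveLasso,
                   build_metss, apply_metss, eval_models, expand_covariates,
                   predicted_vs_observed)
from metss import preprocess as pp

cfg = SynthConfig(n_train=300, n_valid=250, p_metabolites=120, n_blocks=12,
                  n_true_effects=10, effect_sd=0.4, seed=42)
train, valid, truth = generate_cohort_pair(cfg)

plan = pp.harmonize(pp.categorize_missingness(train.abundance),
                    pp.categorize_missingness(valid.abundance))
design_tr = pp.make_design(train.abundance, plan=plan)
design_va = pp.make_design(valid.abundance, recipe=design_tr.recipe)

model = AdaptiveLasso(train.clinical["fev1"].to_numpy(),
                      design_tr.design.to_numpy(),
                      feature_names=design_tr.feature_names)
fit = model.fit_cv(folds=10, seed=42)          # 53 features selected
score = build_metss(fit)

covs = ["sex", "age", "height_cm", "race", "bmi",
        "smoking_status", "pack_years", "site"]
ev = eval_models(valid.clinical["fev1"].to_numpy(),
                 apply_metss(score, design_va.design),
                 expand_covariates(valid.clinical, covs))
print(ev.summary())
```

prints (validation cohort):

```
Linear-model evaluation (Wherry-adjusted R^2, MSE)
==================================================
model                     adj R2 (%)         MSE  predictors
covariates_only                  9.8      2.5867           9
metss_only                      37.2      1.8622           1
metss_plus_covariates           44.3      1.5923          10
partial F (combined vs covariates): F = 149.24, p = 5.47e-27
```

The metSS alone explains 37 % of held-out outcome variance versus 10 % for
clinical covariates, and adding it to the covariates raises adjusted R² from
9.8 % to 44.3 % (partial F p ≈ 10⁻²⁷).  The observed-on-predicted regression
slope is 0.89 — the characteristic shrinkage bias in which extreme outcomes
are under/over-predicted — and 9 of the 10 planted true metabolites are
recovered.

The same run is available from the shell:

```bash
metss all --config config.yaml          # synth → preprocess → fit → score → evaluate
metss all --config config.yaml --swap --extreme-weight 5   # sensitivity analyses
```

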