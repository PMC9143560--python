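# Methods

## Statistical model

The severity score is the linear predictor of a two-stage penalized
regression fit on a training cohort.

**Stage 1 — ridge initialization.** With observation weights ω (mean-
normalized internally) and internally standardized columns (weighted mean 0,
weighted SD 1), ridge minimizes Σωᵢ(yᵢ − β₀ − xᵢᵀβ)² + λᵣ‖β‖², intercept
unpenalized, solved in closed form from one SVD of the weighted standardized
design (stable for p > n when λᵣ > 0).  λᵣ is chosen by K-fold CV over a
log-spaced grid 10⁻²…10⁴ (13 points) on the same fold partition as stage 2;
one SVD per fold serves the whole grid.  Penalty factors are
wⱼ = min(1/|β̂ʳⱼ|, 10⁶), taken from the *standardized*-scale ridge
coefficients so that they compare feature importance rather than raw units.
The cap keeps weights finite while effectively excluding near-zero-signal
features.

**Stage 2 — weighted LASSO with penalty factors.** The objective is
(1/2n) Σωᵢ(yᵢ − β₀ − xᵢᵀβ)² + λ Σ wⱼ|βⱼ| on standardized columns, with
coefficients reported on the input (log-abundance / indicator) scale.
Cyclic coordinate descent soft-thresholds each coordinate at λwⱼ, with
active-set refinement between full sweeps and warm starts along a
100-point log-spaced λ path from λ_max down to 10⁻⁴λ_max, where
λ_max = maxⱼ |⟨xⱼ, y − ȳ⟩_ω|/(n wⱼ) over features with finite positive wⱼ.
λ is chosen at the minimum mean out-of-fold MSE (the "λ-min" rule, not
one-SE).  Binary indicator columns are standardized like continuous ones
(flag to disable).  Plain LASSO is the same solver with all wⱼ = 1.

**Evaluation.** Three OLS models (covariates only / metSS only / both) in
each cohort; adjusted R² by the Wherry form 1 − (1−R²)(n−1)/(n−p−1) — the
adjustment mainstream regression output reports; an (n−p)-denominator
variant is selectable and recorded in output metadata.  MSE is RSS/n.  The
combined model is compared with covariates-only by a partial F-test.
Validation MSE/R² come from the metSS-only OLS *refit* in the validation
cohort (not raw score residuals), matching the linear-model framing of the
evaluation; the raw-score calibration is captured separately by the
observed-on-predicted slope.

## Numerical choices

* Convergence: fold fits run at a sweep tolerance of 1e-4 on the maximum
  coefficient update, with deviance-based early stopping (stop when
  in-sample R² > 0.99 or its fractional improvement per λ step falls below
  1e-5) — the truncated dense end of the path is the overfitting region the
  CV minimum never reaches, and λ values not reached by every fold are
  excluded from the minimum.  The final full-data fit runs from λ_max down
  to the chosen λ at tolerance 1e-8 and must pass a KKT check at 1e-6
  (max over features of the subgradient residual); otherwise a
  ConvergenceError carrying the violation is raised.
* λ_max is inflated by a relative 1e-9 so the soft-threshold comparison at
  the path anchor is robust to last-ulp rounding and every penalized
  coefficient is exactly zero there.
* Observation weights are normalized to mean 1, making the solution path
  invariant to rescaling all weights by a positive constant.
* Constant columns get unit SD in standardization and are never selected.
* The coordinate-descent kernels are numba-compiled; the first call in a
  session pays a one-time JIT cost.

## Preprocessing

Order of operations: within-batch median normalization → subject QC →
missingness tiering → harmonization → per-feature handling (continuous:
natural log, then kNN imputation on the log scale; indicator: observed/not).

* Batch normalization divides each metabolite by its within-batch median of
  observed values; a metabolite entirely missing in a batch stays missing
  (the tiering step handles it).  Each cohort is normalized within itself.
* Subject QC: per-metabolite z-scores (population SD, a fixed convention
  stated for reproducibility), per-subject median z, subjects more than
  3 SD from the cohort mean of medians removed.
* Tiers: missing fraction < 0.20 → impute; within the closed interval
  [0.20, 0.80] → present/absent indicator; > 0.80 → drop.  The boundary
  values belong to the indicator band.
* Harmonization keeps metabolites concordantly continuous or concordantly
  indicator in both cohorts; discordant or dropped-in-either metabolites are
  excluded.
* kNN imputation (k = 10) is delegated to scikit-learn's KNNImputer:
  distances are Euclidean over features observed in both samples, scaled by
  the shared-feature count (the nan-Euclidean scaling has the identical
  neighbour ranking), donors must have the target feature observed,
  unweighted mean of the k nearest (all available if fewer).  Imputation
  runs on log-scale values because raw-intensity distances would be
  dominated by high-abundance metabolites; the alternative order (impute,
  then log) was the main genuinely open choice and is noted here.
  Nonpositive values reaching the log step are treated as missing (logged).
* Cohort comparison: pooled-variance t-tests for continuous variables
  (Welch via a flag — the choice of variance pooling was open), chi-squared
  with continuity correction for 2×2 tables, plain chi-squared otherwise,
  Fisher's exact when a 2×2 expected count is below 5.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, not
mass-spectrometry physics: latent log-abundances are standard normal with
equicorrelated blocks (default 40 blocks of ~19 metabolites, ρ = 0.5);
observed intensity is exp(μⱼ + latent + technical noise (SD 0.25) + additive
log-scale batch shift (SD 0.3, 4 batches/cohort)); missingness is
left-censoring below a per-metabolite abundance quantile drawn from tier
shares (defaults 75 % low-missing, 20 % dichotomized band, 5 % droppable) —
the dominant mechanism in untargeted metabolomics and the reason
present/absent indicators are informative.  Outcomes are linear:
intercept + standardized covariate effects (height 0.40, age −0.15,
male sex 0.20 outcome units per SD) + Σβⱼ·latentⱼ + Gaussian noise.

True effects: 25 metabolites, at most one per block, fixed magnitude 0.25
with random sign, forced into the low-missingness tier so the signal
survives as continuous features.  The default noise SD (0.905) makes the
metabolite share of outcome variance ≈ 0.60 analytically (the block
covariance makes Var(βᵀa) exactly computable).  Validation cohorts shift
covariate distributions (age +4 y, different site labels, different
race/smoking mix), mirroring real two-cohort designs.

What the generator does **not** emulate — and hence what green tests do not
establish about real data: annotation chemistry and identification errors,
nonlinear or interaction effects, covariate–metabolite correlation
(confounding), drift within batches, heavy-tailed intensity distributions,
and cross-cohort effect heterogeneity beyond covariate shifts.  Transfer
R² on real cohorts will generally be lower than on these synthetic pairs.

## Sensitivity analyses

* **Cohort swap** reruns the identical pipeline with the roles exchanged;
  artifacts are tagged by direction.
* **Extreme-quintile weighting** gives the bottom and top outcome quintiles
  weight 5 (exactly ⌈n/5⌉ samples per tail, ordinal ranks breaking ties).
  The weights enter both stages (ridge initialization and the L1 stage):
  the procedure is a single weighted analysis, and applying the weights to
  only one stage would make the penalty factors inconsistent with the loss
  being minimized.

## Pathway over-representation

Universe = harmonized metabolites mappable to pathway ids (indicator
features excluded by the pipeline's convention; configurable at the API).
p = P(X ≥ k) under Hypergeom(N, K, n) — the observed overlap is included,
the standard ORA convention — BH-adjusted across pathways.  Pathway impact
is the centrality mass of matched metabolites over total pathway centrality
(exact Brandes betweenness, normalized, or out-degree; both provided since
web-tool impact weightings are not fully specified), reported as missing
(not zero) when a pathway has no graph.

## Known limitations and observed properties

* With ridge-CV initial weights and the λ-min rule, the adaptive procedure
  selects ~20 spurious features on pure-noise data where plain LASSO selects
  ~0 (tests exercise both), and at the default study conditions its
  false-positive count at the CV minimum is slightly *higher* than plain
  LASSO's.  Adaptive weighting buys
  interpretable, less-biased large coefficients rather than a sparser
  CV-min model; sparser selections require one-SE or information-criterion
  rules, which this pipeline deliberately does not use.
* The λ-min rule combined with p ≫ true support means selected sets (~100+
  features at the default conditions) are supersets of the truth; support
  recovery is high (≈ 92 % across seeds) but precision is modest, which is
  the expected trade-off of prediction-optimal tuning.
* Problem sizes in the test suite (train 650 / validation 1120 / 762
  metabolites for the full study; smaller for module tests) were chosen as
  the package's reference conditions; all heavy simulations are seeded and
  reproducible.
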