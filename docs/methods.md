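# Methods

## Model

oCPLS2-DA is two-class PLS2 regression on a centered class-indicator block
`Y` (n × 2) with score-orthogonality constraints. Writing `E_a`, `F_a` for
the deflated X and Y blocks at component `a` and `Z` for the centered
constraint matrix, the component is

1. `K = Zᵀ E_a`; `N` = orthogonal projector onto null(K) (computed from an
   SVD basis of row(K), robust to near-collinear constraints);
2. `w_a` = dominant left singular vector of `N Eᵀ_a F_a` (unit norm, sign
   fixed so the largest-magnitude entry is positive);
3. `t_a = E_a w_a` — since `w_a ∈ null(K)`, `Zᵀ t_a = K w_a = 0` exactly;
4. `p_a = Eᵀ_a t_a / tᵀ_a t_a`, `c_a = Fᵀ_a t_a / tᵀ_a t_a`; both blocks are
   deflated by `t_a`.

`B = W (PᵀW)⁻¹ Cᵀ` maps pretreated X to the centered response;
`R² = 1 − ‖F₀ − XB‖²/‖F₀‖²` (clamped to [0, 1]). With an empty `Z` the
algorithm is ordinary NIPALS PLS2-DA (verified against a full-eigendecomposition
oracle to 1e-8). The constraints are implemented in weight space (null-space
projection of the cross-covariance) rather than by pre-projecting X in
sample space: scores remain linear combinations of the actual training
data, and the orthogonality guarantee is explicit. The relative residual
`max|Zᵀt| / (‖Z‖·‖t‖)` of every constrained component fitted in a process
is logged (`ocplsda.model.CONSTRAINT_RESIDUALS`); across the test suite's
thousands of refits it stays at machine precision (~1e-13).

If the constraints span the response itself, no Y-correlated direction
survives the projection; the first component then falls back to the leading
constraint-respecting X-variance direction (with a warning), yielding a
well-defined null-signal model (B ≈ 0, Q² ≤ 0) rather than an error.

### Post-transformation

The fitted components are rotated into `A_pred` predictive plus `A_orth`
Y-orthogonal components. With `D = diag(tᵀt)`, the rotation is
`G = D^(−1/2) U`, where `U` comes from the full SVD of `D^(−1/2) Tᵀ Y_c`,
with the paired inverse-transpose `D^(1/2) U` applied to `W`, `P`, `C`.
This norm-weighted construction — rather than a plain orthonormal rotation —
is the unique member of the family `T→TG, (W,P,C)→(W,P,C)G⁻ᵀ` for which
*all* of the following hold simultaneously and exactly: fitted responses,
`TPᵀ` and `B` are unchanged; the trailing components have zero Y-loadings
*and* Y-orthogonal scores; rotated scores stay mutually orthogonal
(orthonormal, in fact); `A_pred = rank(TᵀY_c)` (= 1 for two classes, the
"A = 1+2" convention). A plain orthonormal rotation cannot zero the
trailing Y-loadings when score norms differ, because `C = M ᵀD⁻¹` interposes
`D⁻¹` between the rotation and the score–response product.

### Dimensionality choice

`n_components` is a user input (the convention reports it as
predictive+orthogonal after rotation). When unset, the smallest A whose
7-fold Q² stops improving by more than 0.01 is selected. A is capped per
refit at `min(A, n_train − 1 − c, p)` inside cross-validation and
subsampling, where `c` is the number of retained constraint columns.

## Pretreatment

Default: natural log, mean-centering, Pareto scaling (divisor = √SD of the
log intensities), the standard treatment for ESI-MS peak areas; each stage
is configurable (`PretreatSpec`). Zero-variance features receive a unit
divisor and a warning. Log transformation is parameter-free and applied
once; means and scales are refit inside every training fold/subset, so
held-out samples never contribute to any fitted statistic (asserted by a
spiked-outlier test). Binary covariates (numeric, boolean, or two-level
strings) encode to centered 0/1 columns; counts and continuous covariates
to one centered column each; constant covariates are dropped with a
warning. Miscarriage counts are treated as continuous.

## Validation

* **Q²** = 1 − PRESS/TSS over class-stratified folds, the entire pipeline
  refit per fold. TSS is referenced to the training-fold response mean
  (consistent with the no-leakage reading; the difference from a global
  mean reference is negligible and documented here).
* **Permutation test**: class labels permuted uniformly, X and Z fixed,
  full 7-fold CV Q² recomputed per permutation,
  `p = (#{Q²_perm ≥ Q²_obs} + 1)/(B + 1)`. Across 200 null datasets at
  n = 24, p = 200 with 99 permutations, the fraction of p ≤ 0.05 is ~0.035 —
  the calibrated instrument for small-n inference.
* **ROC**: AUC by the Mann-Whitney identity (ties ½); 95% CI by DeLong's
  asymptotic variance, truncated to [0, 1] (deterministic, unlike a
  bootstrap); operating threshold minimizing (1−Se)² + (1−Sp)², ties broken
  toward higher sensitivity. Cross-validated scores (the held-out
  case-class prediction) feed the model-level ROC.
* **Confounding screen**: metadata autoscaled, examined by PCA with
  per-component two-sample t-tests and by a PLS-DA with the metadata as the
  X-block; "no confounding" is declared when the metadata model's 7-fold
  Q² ≤ 0.
* **External factor check**: point-biserial correlation between the
  predictive score and a binary factor (e.g. chorioamnionitis), with its
  two-sided t-test p-value.

A small-sample caveat established during development: at n ≈ 24, CV
training sets share most of their samples, so a chance class-correlated
direction (|r| ≈ 0.3) survives cross-validation often enough that null Q²
is positive in ~15–20% of datasets, and the screen's Q² ≤ 0 rule is
similarly ~80–85% specific. Both become ≥ 95% reliable by n = 60. The
permutation test, not the sign of Q², carries the inferential weight at
small n; the null-behavior property tests therefore run at n = 60.

## Stability selection

Each of `n_subsets` (default 200) Monte-Carlo draws includes every sample
independently with probability 0.70 ("prior probability" read literally; a
fixed-fraction variant is available via `fixed_fraction`). Draws leaving
fewer than 3 samples in either class are redrawn (≤ 100 attempts). The full
pipeline is refit per subset at the same A; excluded samples are predicted
and scored by ROC at the top-left-closest threshold; features are ranked by
|B| of the case-class column (the coefficient is invariant under
post-transformation) and the top 50 are "selected". Selection frequencies
divide by the number of successfully fitted models; the panel keeps
features with frequency *strictly* greater than 0.90.

Two intrinsic small-n behaviors surfaced by the recovery harness
(`recovery_experiment`) are worth knowing:

* With inclusion 0.70 at n = 24, any two subsets share ≈ 70% of their
  samples, so a null feature's chance class-covariance is strongly
  correlated between refits; a handful (0–5 of 500) of pure-noise features
  can persist above the 90% threshold. The panel should be read jointly
  with the permutation p-value, not as an error-controlled set.
* Each constraint column costs one score dimension in every subset refit.
  With nine covariates and ~17-sample subsets only ~7 dimensions remain, and
  coefficient rankings cannot stabilize above 90% even for large marker
  effects under the generator's independence assumptions; with few
  constraints (or none) recall of planted markers at effect 1.5·SD is
  ≈ 0.75–0.8 with ≤ 1 false panel member. Real marker panels at full
  constraint load imply correlated marker blocks and larger effects than
  the independent-feature generator produces.

The constrained model's purpose is demonstrated directly: features driven
by a covariate that correlates with class at 0.6 enter the top-50 under
unconstrained PLS-DA at a mean frequency ≈ 0.2–0.4, but under the
constrained model at ≈ 0.05 — a mean suppression gap > 0.2 across seeds.

## Univariate complement

Welch t-test per feature on the pretreated (log-scale) matrix (Student's
available via `equal_var=True`), Benjamini-Hochberg q-values
(statsmodels step-up, cross-checked against a literal independent
implementation), significance at q < 0.20, and per-feature ROC with DeLong
CIs. Zero-variance features get p = 1 with a warning.

## Annotation

Monoisotopic masses are computed from CHNOPS formulas with IUPAC atomic
masses; [M+H]⁺/[M−H]⁻ adducts add/subtract 1.007276 Da (the proton;
electron mass neglected — < 1 ppm below m/z ~500 and irrelevant at the
10 ppm default tolerance, which sits above the largest plausible
instrument error for the application). Matching is by signed ppm error
within tolerance, negative mode trying [M−H]⁻ and positive [M+H]⁺, output
sorted by |ppm| then name; retention time is carried through but never
matched on. The bundled table covers typical amniotic-fluid annotations
(hydroxy/oxo fatty acids, muconic dialdehyde, leucinic acid,
S-adenosylmethionine, DHEAS, a phosphatidylcholine exemplar); entries
identified only to metabolite class carry no formula and are skipped by the
matcher. The phosphatidylcholine record is a synthetic exemplar formula
(C42H82NO7P) standing in for the lipid class, and the class-only records
are likewise placeholders, not resolved structures.

## Synthetic data

The generator emulates a small obstetric metabolomics study: two groups
(default 12+12; unbalanced via a pair), p features (default 1400) with
per-feature baseline log-intensity ~ N(9, 1.5²), i.i.d. Gaussian log-scale
noise (SD 0.5), exponentiated — i.e. log-normal peak areas, strictly
positive, no missing values by default (an off-by-default left-censoring
floor exists). Marker features shift the case group by
`marker_effect·noise_sd` on the log scale; confounded features regress on a
standardized covariate with slope `confounder_effect`; the designated
confounder (maternal age) correlates with class membership at
`confounder_class_assoc`. Covariates mirror a clinical metadata sheet
(age, BMI, miscarriage count, gestational age 21–28 weeks, four therapy
flags, newborn sex), independent of each other and of class except the
designated confounder. Feature identifiers follow the "RT_mz" convention.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: between-feature correlation (adducts, isotopes,
pathway co-regulation), intensity-dependent noise, retention-time drift,
batch effects, missingness. In particular, marker recovery rates on real
cohorts, where markers arrive in correlated blocks, can differ in either
direction from the independence-based results here.

## Numerical choices

* Degenerate cross-covariance (‖M‖ ≤ 1e-12·‖E‖·‖F‖) stops extraction with
  a warning (fewer components returned); on the first component it triggers
  the null-signal fallback described above.
* Rank decisions (constraint basis, A_pred) use SVD with
  `max(shape)·eps·s₁`-style thresholds.
* Sign convention everywhere: a component's largest-|weight| entry is
  positive, so reports and serialized models are reproducible.
* Stratified folds and Monte-Carlo draws come from `numpy.random.default_rng`
  seeded explicitly; the pipeline derives all stage seeds from one master
  seed via `SeedSequence`, making `report.json` byte-reproducible.
* Fold assignment re-randomizes (≤ 100 times) if any training part would be
  single-class; subset draws likewise for the 3-per-class floor.

## Problem sizes

The test suite and acceptance script run at the study's own scale where
that is cheap (n = 24, p = 500–1369; 99–500 permutations; 100–200 subsets)
and at n = 60 for the null-behavior properties discussed above. These sizes
were chosen as representative, fast-converging instances of each claim.

## Known limitations

Two classes only (G = 2 is structural: the centered two-column indicator
has rank 1). No O2PLS/kernel variants, no nested CV for hyperparameters, no
imputation or batch correction, no MS/MS spectral scoring, no live
database queries. DeLong CIs are asymptotic and optimistic at n ≈ 24 with
AUC near 1 (they truncate at the boundary).
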