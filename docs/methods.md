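# Methods

## Problem and model

Cohort studies that profile both the plasma/serum proteome (aptamer arrays)
and metabolome (untargeted MS) yield thousands of correlated analytes. The
package reduces them to modules of co-varying analytes, summarizes each
module by principal components of its z-scored submatrix, and treats those
PC scores as biomarkers. The statistical model behind the survival stage is
a standard Cox proportional-hazards model, one exported PC at a time,
adjusted for clinical covariates; effect sizes are hazard ratios per
*discovery-cohort* SD of the PC score, which keeps them comparable when the
model is transferred to another cohort.

## Preprocessing

Protein arm: Bland–Altman CV over blind duplicate pairs on the raw scale —
CV = √(meanᵢ((aᵢ−bᵢ)²)/2) / mean of all duplicate values — with proteins
above `cv_max = 0.5` excluded; log2 transform; single-pass winsorization at
mean ± `winsor_k = 5` SD (moments from the original column, so the pass is
deterministic and idempotent). The raw scale for the CV is the conventional
choice for duplicate-based coefficients of variation. Metabolite arm:
xenobiotic-flagged metabolites dropped; missing fraction > `missing_max =
0.80` dropped; scaling to a median of 1 (log2 median 0); log2 variance <
`var_min = 0.01` dropped. Exclusion tables record one row per dropped
analyte with the triggering statistic.

Panels are intersected across cohorts *after* per-cohort filtering, so an
exclusion in either cohort removes the analyte from both — a requirement
for model transfer. Finalization imputes each missing cell with the
analyte's observed minimum (the matched choice when missingness is
detection-limit left-censoring, which is exactly what the generator
produces) and then caps at mean ± 5 SD with moments recomputed after
imputation. Proteins have no missingness filter; any protein NA would be
minimum-imputed at finalization.

## Module detection

Spearman correlation is computed densely; each analyte proposes its
`edges_per_node = 20` largest-|ρ| partners (ties broken by analyte
position) and the network is the symmetric union of proposals. This
per-node top-k sparsification is the package's own edge filter: it keeps
the strongest edges per node, is deterministic, and its sparsity is
directly configurable. Connected components are clustered independently:
within a component the dissimilarity d = 1 − |ρ| is recomputed densely (so
average-linkage heights are defined for every pair), the tree is cut at
`cut_height = 0.75`, clusters of ≥ `min_module_size = 2` become modules,
and everything else goes to the background module (id 0). Unsigned
dissimilarity is the default because protein–metabolite biology includes
inverse regulation; a fixed-height cut was chosen over adaptive cutting for
reproducibility. Module ids are assigned by decreasing size (ties by
smallest member id), so permuting samples changes nothing and permuting
analytes changes only the numbering.

## Module PCs

Per module, columns are z-scored by discovery mean/SD and decomposed by
SVD. Robustness to outliers comes from the upstream winsorization/capping;
`rank_pca = true` additionally offers PCA on rank-transformed columns.
Sign conventions make fits reproducible: PC1 is oriented so the mean
Spearman correlation of components with PC1 is ≥ 0; higher PCs so their
largest-|loading| entry is positive. Modules whose first PCs correlate
above `merge_threshold = 0.9` (signed by default; `abs_merge` covers the
absolute reading) are merged highest-correlation-first, one pair at a time
with a refit after each merge, to avoid order artifacts; the merged module
keeps the smaller id and provenance is recorded. Export rule: smallest K
with cumulative variance fraction ≥ `pc_var_target = 0.50`, capped at
`max_pcs = 3`. The frozen `ModuleModel` (JSON) carries memberships,
means, SDs, loadings, variance fractions, PC score SDs and merge history —
everything `apply_model` needs, so scoring a new cohort is a pure function
of (model, matrix).

## Characterization and survival

Trait characterization uses univariable OLS of each PC on each trait
(slope, Wald 95 % CI, R², plus Spearman ρ), complete-case per trait; urine
protein is log2-transformed. Age can be residualized on GFR: in a CKD
trial, enrolment by GFR window couples age positively to GFR, distorting
raw age–PC correlations relative to a general-population cohort;
regressing age on GFR removes this selection artifact. Module layouts are
classical metric MDS of the within-module d = 1 − |ρ| (deterministic up to
reflection, which is fixed by the first analyte's coordinate signs).

Cox fits maximize the partial likelihood via statsmodels' PHReg with
Breslow tie handling by default (`ties = "efron"` available); convergence
is verified by the score-vector norm (< 1e−6) and flagged, never silent.
Covariate sets differ by cohort: the general-population profile includes
center, diabetes, antihypertensive medication and ACR; the CKD-trial
profile drops those (they are degenerate by design) and uses 24 h urine
protein. Total cholesterol and BMI enter as linear splines {x, max(x−knot,
0)} with knots at 200 mg/dL and 25 kg/m². Bonferroni selection uses a
strict inequality p < α/m with m the number of exported PCs tested;
replication in the validation cohort tests only discovery-significant PCs
at α / (their count) and records direction consistency of log HR.

## Synthetic cohorts

The generator emulates the data-generating assumptions the pipeline
relies on, with defaults chosen as a realistic desk-scale study:

- Latent factors Z ~ N(0,1); analyte log2 signal λ·Z + N(0, σ), σ = 0.6;
  per-factor λ evenly spaced on [0.5, 0.95] so modules differ in coherence
  (needed for a meaningful cross-cohort coherence correlation); 20 factors
  × (10 proteins + 5 metabolites), 40 background analytes, ~10 % xenobiotic
  metabolites. Within-module correlation is λ²/(λ²+σ²_eff) with σ²_eff =
  σ² + (CV/ln 2)² including measurement noise.
- Raw abundances are 2^(signal + offset) times multiplicative log-normal
  measurement noise with per-analyte CV (0.08; 5 % of proteins get 0.8 so
  the CV filter has true positives). Blind duplicates re-measure the same
  specimen.
- Metabolite missingness is left-censoring at a per-analyte detection-limit
  quantile (0.05; 5 % of metabolites at 0.85 to exercise the missingness
  filter).
- Clinical covariates follow two profiles: an elderly general-population
  cohort (age 75.7 ± 5.2, eGFR 65 ± 18, ACR median 11) and a CKD trial
  cohort (age 54.5 ± 10.7, mGFR 46 ± 13, 24 h urine protein median 109, no
  diabetes, all on antihypertensives, age–GFR correlation 0.5 from the
  enrolment window). GFR, sex, glucose and urine protein couple to
  specific factors.
- Survival is Weibull (shape 1, baseline rate 0.029/y; validation hazard ×
  1.5) with log-hazard Σβ_k Z_k + covariate terms; default causal factors
  β₃ = 0.33 and β₄ = −0.30 per SD; censoring uniform over ≈5–8 y
  (discovery) and 7–10.5 y (validation). The rates were calibrated once so
  the discovery cohort sees ≈23 % deaths over ≈6.6 y mean follow-up and
  the validation cohort ≈20 % — the regime the pipeline targets.

What the generator does *not* emulate: batch/plate effects, analyte-specific
marginal distributions, non-linear factor loadings, informative censoring,
competing risks, and longitudinal visits. Passing tests therefore show the
pipeline recovers structure under its own model assumptions, not that real
cohort idiosyncrasies are handled.

## Evaluation studies and problem sizes

`omod.evaluation` fixes the study sizes used by tests and the acceptance
script: module recovery at n = 1000 with uniform λ = 0.8 (ARI vs truth);
causal-PC power over 25 replicates at n = 4000 (~23 % events), Cox-testing
the causal factor's module PC1 against α / (exported PC count); family-wise
error over 50 replicates of 50 null factor scores at n = 500; transfer
fidelity on one default-design cohort pair plus a column-permutation
negative control. These sizes give Monte-Carlo error small enough for the
asserted margins while keeping a full run to a few minutes. Note the
estimated causal log HR is attenuated relative to the generative β by
regression dilution (the PC is a noisy proxy of Z, corr ≈ 0.97 at default
design) plus Cox non-collapsibility; the mean |log HR| lands near 0.31 for
β = 0.33, and the 95 % CI still covers the generative HR in ≈92 % of
replicates.

## Numerical choices and edge cases

- All randomness flows from `numpy.random.default_rng(seed)`; replicate
  seeds are spawned from the base seed and stay below 2³¹.
- Constant columns: unchanged by winsorization; excluded by the metabolite
  variance filter; an error if one reaches PCA (it indicates a filtering
  bug upstream).
- Spearman ties use average ranks; degenerate (constant) columns get ρ = 0
  in the network rather than NaN.
- Merge loop tie-breaks by module id; boundary p = α/m is not significant
  (strict inequality); PC-export boundary uses a 1e−12 tolerance on the
  cumulative variance fraction.
- Wald CIs use the normal quantile 1.959963…; HR, CI and p all derive from
  the same β̂ and SE.

## Known limitations

The edge filter is top-k per node, not a boosting-based filter; adaptive
tree cutting is not implemented; only up to 3 PCs per module are exported;
no PH diagnostics, competing risks or risk-prediction metrics; covariate
missingness is handled by complete-case analysis only.
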