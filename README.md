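# omod — integrated proteomic–metabolomic modules and mortality

Circulating proteins and metabolites are biochemically entangled — enzymes
and their substrates, transporters and their cargo — and many of them are
individually associated with all-cause mortality. `omod` implements an
integrated analysis for epidemiological cohort studies that measures both
layers: instead of testing thousands of correlated analytes one at a time,
it clusters them into **modules** of co-varying proteins and metabolites,
summarizes each module by a few principal components, and uses those PC
scores as biomarkers for cross-sectional characterization, Cox mortality
association, and transfer to an independent cohort.

It is written for epidemiologists and computational biologists working with
sample × analyte abundance tables (aptamer proteomics, untargeted MS
metabolomics) plus clinical covariates and survival follow-up.

## Method

1. **Preprocessing.** Proteins: blind-duplicate Bland–Altman CV filter
   (CV = √(mean(Δ²)/2) / grand mean > 0.5 excluded), log2 transform,
   winsorization at mean ± 5 SD. Metabolites: xenobiotics excluded,
   > 80 % missing excluded, scaled to median 1, log2, variance < 0.01
   excluded. Panels are restricted to analytes present in both cohorts;
   missing cells are imputed with the analyte's observed minimum (matching
   detection-limit left-censoring) and all values capped at ± 5 SD.
2. **Module detection.** Each analyte proposes edges to its *k* strongest
   partners by |Spearman ρ|; connected components of the resulting sparse
   network are clustered by average-linkage on d = 1 − |ρ|, the tree is cut
   at a fixed height, clusters of ≥ 2 analytes become modules and the rest
   form a background module.
3. **Module scores.** Per module, the z-scored submatrix is decomposed by
   PCA; modules whose first PCs correlate > 0.9 are merged; up to 3 PCs are
   exported per module (fewer once they explain ≥ 50 % of module variance).
   Scores are reported in *discovery SD units*.
4. **Association.** Each PC enters a covariate-adjusted Cox proportional-
   hazards model (linear splines for total cholesterol at 200 mg/dL and BMI
   at 25 kg/m²; urine protein log2); Bonferroni selection at α / (number of
   exported PCs).
5. **Transfer.** The frozen model (memberships, loadings, discovery
   means/SDs/PC SDs) is applied unchanged to a validation cohort;
   transferability is the cross-cohort agreement of each module's mean
   component–PC1 Spearman correlation, and discovery-significant PCs are
   re-tested at α / (their count).

Real multi-omics cohort data of this kind are access-controlled, so the
package ships a synthetic two-cohort generator (`omod.simulate`) with known
latent-factor modules, detection-limit missingness, blind duplicates,
trait–factor couplings and Weibull survival, used as the truth-known test
bed for every stage.

## Worked example

```python
from omod import (RunConfig, SimDesign, simulate_pair, preprocess_pair,
                  spearman_network, cluster_modules, fit_scores,
                  associate_mortality, bonferroni_select, build_covariates,
                  transferability)
from omod.survival import DISCOVERY_COVARIATES

cfg = RunConfig(seed=1)
disc, val, truth = simulate_pair(SimDesign(), seed=1)
m_d, m_v, excl = preprocess_pair(disc, val, cfg)
net = spearman_network(m_d, cfg.edges_per_node)
part = cluster_modules(net, m_d, cfg.cut_height)
part, model, scores = fit_scores(m_d, part, cfg)
print(part.n_modules(), len(part.background()), len(model.score_columns()))

cov = build_covariates(disc.clinical, DISCOVERY_COVARIATES)
sig = bonferroni_select(associate_mortality(scores, cov, disc.outcome), cfg.alpha)
print([(r.module_id, r.pc, round(r.hr, 2)) for r in sig])
print(round(transferability(model, m_d, m_v).overall_spearman, 3))
```

prints

```
20 36 24
[(2, 1, 0.73), (9, 1, 1.38)]
0.989
```

— the 20 generative factors are recovered as 20 modules (36 analytes stay
in the background), represented by 24 exported PCs; the two causal module
PCs are Bonferroni-significant with hazard ratios near their generative
values (e^0.33 ≈ 1.39 and e^−0.30 ≈ 0.74 per discovery SD); and the
within-module coherence profile transfers across cohorts with a
correlation of 0.99.

The same pipeline is available from the shell:

```sh
omod all --out run/ --seed 1     # or: simulate, preprocess, modules,
                                 # characterize, associate, transfer
```

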