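# eprsqol

Does the brain's insulin-receptor gene network modify how depressive symptoms
translate into quality of life?  Expression-weighted polygenic scores
(ePRS) aggregate allele dosages over the SNPs of a co-expression gene
network, weighting each SNP by its expression effect size and by the sign of
its gene's co-expression with the index gene — here the insulin receptor in
the hippocampus.  `eprsqol` implements the full analysis chain needed to ask
that question in an epidemiological cohort, end to end and fully testable on
synthetic data:

- **Genotype QC** — call-rate, MAF and Hardy–Weinberg exact-test filters
  (call rate > 95%, tightened to > 99% when MAF < 5%; MAF > 1%;
  HWE p > 10⁻⁶), sample call-rate/heterozygosity checks, and genotype
  principal components for population-stratification adjustment.
- **Network scoring** — greedy LD clumping (lowest selection p-value within a
  window), effect-allele reconciliation, the signed weighted sum
  `score_i = Σ_j dosage_ij · β_j · sign_j`, within-sample standardization,
  and the three-level categorization (low < −0.5 SD ≤ moderate ≤ 0.5 SD < high).
- **Instruments** — BDI-21 totals (0–63, screen-positive at ≥ 10) with
  melancholic / non-melancholic subtyping by comparing subscale mean ratings
  (ties → melancholic); SF-36 version-1 scoring to eight 0–100 domains and
  norm-based PCS/MCS component T-scores (mean 50, SD 10 in the reference
  sample); derived covariates (HOMA-IR = fasting glucose × insulin / 22.5,
  leisure-time physical activity in MET·h/week, comorbidity classes, WHO 2006
  OGTT glucose status).
- **Inference** — statsmodels-style model objects: `BootstrapGLM` (OLS point
  estimates, case-resampling bootstrap SEs/percentile CIs/z-based p-values),
  `InteractionModel` (depression-type × score product terms with a joint
  bootstrap Wald test, per-stratum simple slopes, adjusted cell means and
  contrasts via marginal standardization), `MultinomialSubtypeModel`
  (average predicted subtype probabilities per score category with bootstrap
  SEs), and Bonferroni adjustment over the family of HRQoL outcomes.
- **Synthetic cohorts** — `simulate_study` generates genotypes with blockwise
  LD, a SNP weight table, and a phenotype table from a latent model
  `MCS* = baseline + main(subtype) + β_int · score_z · 1[melancholic] + covariates + noise`,
  with every generating parameter recorded in a `TruthRecord`.

## Worked example

```python
from eprsqol import simulate_study, InteractionModel
from eprsqol.pipeline import build_analysis_table

bundle = simulate_study(seed=7)            # n=1558, ~4000 markers, 498 genes
data, info = build_analysis_table(bundle.genotypes, bundle.weights, bundle.cohort)

model = InteractionModel(data, outcome="mcs", modifier="eprs_z")
result = model.fit(n_boot=1000, seed=0)
print(round(result.interaction_pvalue, 4))
print(result.stratum_slopes().round(2))
```

prints

```
0.0028
                 estimate    se  ci_lower  ci_upper  pvalue
subtype
none                -0.51  0.23     -0.93     -0.05    0.03
non_melancholic      0.39  0.61     -0.70      1.59    0.52
melancholic         -3.22  0.87     -4.89     -1.47    0.00
```

The joint Wald test of the depression-type × score product terms rejects
(p ≈ 0.003), and the score is associated with lower mental quality of life
only within the melancholic stratum: the slope −3.22 (95% CI −4.89 to −1.47)
estimates the injected ground truth of −3.4 MCS points per SD of the score,
while the non-depressed and non-melancholic strata are essentially flat.
The full report
pipeline (characteristics table, crude/fully-adjusted association tables,
predicted subtype probabilities, interaction summaries) runs with

```bash
eprsqol pipeline --out report/ --seed 42
```

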