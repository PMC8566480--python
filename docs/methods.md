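# Methods

This note documents the models, scoring rules, numerical choices and known
limitations of `eprsqol`.

## The question and the estimand

The package studies effect modification: whether an expression-weighted
polygenic score for a brain insulin-receptor gene network (ePRS) changes the
association between the *type* of depressive symptoms (none /
non-melancholic / melancholic) and health-related quality of life, measured
as the SF-36 mental and physical component summaries (MCS, PCS).  The core
estimands are (i) the joint depression-type × score interaction on MCS and
(ii) the simple slope of the score within each depression stratum, in MCS
T-score points per SD of the score.

## Genotype QC

Marker filters use strict inequalities, applied in a fixed order that
determines the reported primary reason code (call rate → MAF → HWE): call
rate > 0.95 (tightened to > 0.99 when MAF < 0.05), MAF > 0.01, and
Hardy–Weinberg exact-test p > 10⁻⁶.  The HWE test is the exact conditional
test: holding the allele counts fixed, it sums the probabilities of all
heterozygote counts whose conditional probability does not exceed that of the
observed count.  It is computed in log space with a shared log-factorial
table; a relative tie tolerance of 10⁻¹² guards against floating-point
round-off at exact ties.  Samples are dropped for call rate ≤ 0.95 or
heterozygosity outside mean ± 3 SD — the ±3 SD band is this package's choice;
chip-level per-genotype clustering quality has no analogue in dosage data and
is recorded as out of scope in the QC report metadata.

Population stratification covariates are the leading principal components of
the column-standardized (mean-imputed) dosage matrix, 3 by default.  Signs
are fixed by making each component's largest-magnitude loading positive.  For
matrices above ~250k entries a randomized truncated SVD (fixed internal seed,
10 oversamples, 7 power iterations) replaces the exact SVD; the power
iterations keep the leading subspace accurate even when the trailing spectrum
is flat, and the exact invariances (e.g. marker-order invariance) hold on the
exact branch used for small panels.

## Network score

The weight table carries, per SNP: an expression effect size β, the sign of
its gene's co-expression with the index gene, and a selection p-value.
Clumping is greedy and window-based: repeatedly retain the remaining SNP with
the lowest p-value and drop all others within the window (250 kb default) on
the same chromosome.  No r² pruning is applied — the window-only rule is the
minimal version of "lowest p-value within a clumping window", and the window
is configurable.  Scoring reconciles the effect allele against the panel
(flipping dosage d → 2−d when orientations are swapped; dropping and logging
strand-ambiguous A/T–C/G pairs and allele mismatches), mean-imputes missing
dosages so scores stay comparable across samples, and sums dosage × β × sign.
Higher score means higher predicted network expression.  Scores are
standardized within the analysis sample (not an external reference) and
categorized at ±0.5 SD with boundaries inclusive in "moderate".

## Instruments

**BDI-21.** Total = Σ of 21 items rated 0–3 (range 0–63); total ≥ 10 screens
positive.  Screen-positive respondents are subtyped by comparing the mean
rating of the melancholic item set against the rest; equal means classify as
melancholic.  The default melancholic set — sadness, past failure, loss of
pleasure, guilt, punishment feelings, irritability, loss of interest, change
of sleeping, change of appetite — maps to positions (1, 3, 4, 5, 6, 11, 12,
16, 18) on the standard 21-item form.  The map is configurable data, not
code, because item numbering differs across instrument versions.  Subscale
means use all mapped items, not only endorsed ones.

**SF-36 (version 1).** Item responses are recoded linearly to 0–100 (higher =
better functioning); a domain is the mean of its recoded items, scored when
at least half its items are answered (half-scale rule) and left missing
otherwise — missing domains propagate to the component scores rather than
being fabricated.  Components standardize the eight domains with reference
means/SDs, combine the z-scores with factor-score coefficients, and report
T = 50 + 10 × component.  Two norm sources are built in: published US
general-population (1990) constants (bundled data file), and norms estimated
from a user-supplied norming sample.  Estimation uses a two-component
principal-factor solution of the domain correlation matrix with varimax
rotation and regression-method factor scores, rescaled to unit SD — so
applying the scorer to its own norming sample reproduces mean 50, SD 10 by
construction.  The component loading predominantly on the physical domains
(PF, RP, BP, GH) is labelled PCS; signs are fixed so better health raises
both components.

**Covariates.** HOMA-IR = fasting glucose (mmol/l) × fasting insulin (mU/l)
/ 22.5; leisure-time physical activity = Σ MET × hours × weekly frequency;
comorbidity count capped at "2+"; glucose status by WHO 2006 OGTT rules
(diabetes: fasting ≥ 7.0 or 2-h ≥ 11.1 mmol/l or a known-diabetes flag;
prediabetes: fasting 6.1–6.9 or 2-h 7.8–11.0; else normoglycaemia).

## Inference

`BootstrapGLM` fits the mean model by least squares on the full analysis
sample (complete cases, with the dropped count recorded) and draws inference
from nonparametric case resampling of individuals: percentile confidence
intervals, and two-sided p-values from the bootstrap-z statistic
(estimate / bootstrap SE against the standard normal).  "Bootstrap-style"
analysis is otherwise underdetermined; case resampling with percentile CIs is
the most common reading and is recorded here as the package's choice.  The
resampled solves are batched normal-equation solves, so 10,000 replications
on a cohort of ~1,500 with ~25 design columns take seconds.  Collinear
designs raise an error naming the aliased columns.

The interaction model adds depression-type × score product terms to the fully
adjusted model (age, sex, stratification PCs, smoking, alcohol, SES,
comorbidity class, BMI, LTPA; reference categories: no depression, low score
category).  The joint test is a Wald chi-square using the bootstrap
covariance of the interaction coefficients.  Stratum summaries are computed
by marginal standardization (g-computation): adjusted means average the
fitted predictions over the observed covariate distribution with the group
set counterfactually, which places continuous covariates at their means and
categorical ones at observed proportions; simple slopes are unit-increment
counterfactual contrasts.  All of these are linear functionals of the
coefficients, so their bootstrap distributions come free from the coefficient
draws.  Screening covariate × depression-type interactions into the model is
supported in principle by fitting such terms explicitly, but is off by
default.  The multinomial subtype model (statsmodels MNLogit inside a
case-resampling loop, warm-started at the full-sample fit; default 1,500
replications) reports sample-averaged predicted subtype probabilities per
score category and pairwise category differences.  Bonferroni adjustment uses
min(1, m·p) with m = 10 for the HRQoL family (8 domains + MCS + PCS),
implying the companion α = 0.005 rule.

## Synthetic data generator

The generator emulates a cohort of 1,558 older adults with subtype
prevalences 1262/199/97, component baselines 56.4 (MCS) and 49.2 (PCS),
subtype main effects −13.1/−11.8 (MCS) and −7.1/−3.4 (PCS), an injected
interaction of −3.4 MCS points per SD of the score in the melancholic group
only, and latent noise SD 8 chosen to match the reported within-group
summary-score SDs.  Covariate marginals (age 61.5 ± 2.9, 56.2% women, BMI
27.7 ± 4.6, smoking/alcohol/SES/comorbidity frequencies, log-normal OGTT
values) follow the emulated cohort's characteristics table; their joint
distribution is not documented there, so covariates are drawn independently.

Genotypes: within an LD block all markers share one allele frequency and each
haplotype copies the previous marker's allele with probability 0.9,
giving geometric within-block correlation while keeping marginal frequencies
exact; blocks are independent.  Allele pairs are drawn non-ambiguous (real
pipelines drop A/T–C/G SNPs upstream).  The ground-truth effect modifier is
defined as the standardized signed score over the *clumped* weight set — the
same functional the scoring stage computes — so the injected coefficient is
exactly the estimand the analysis recovers (QC removes essentially nothing at
the default MAF range and missingness of 1%).

SF-36 items are generated monotonically from domain latents that are affine
in the latent components (domain = 50 + 1.2·(component − 50) + noise), with
centers and slope chosen to keep targets inside the 0–100 item range for the
realized latent spread: floor/ceiling compression would otherwise make the
latent → scored mapping nonlinear and bias slope recovery.  Item realism is
deliberately not a goal; the scorer's round trip is.  BDI items are drawn
Binomial(3, p) with p = 0.45 on the dominant subscale and 0.15 on the other
for screen-positive subtypes and 0.05 otherwise, which yields ≥ 95% agreement
between intended and scored subtype and exercises the tie rule when the
margin is set to zero.

What passing synthetic tests does **not** show: robustness to realistic
haplotype structure and imputation artefacts, admixture beyond a two-group
PC check, informative missingness, item-level response styles, or
measurement non-invariance of the instruments in real populations.

## Numerical and design choices

- Standardization SDs use ddof = 1 throughout (score z-scores, SF-36 norms).
- Score category boundaries are inclusive in "moderate" (z = ±0.5).
- Percentile CIs use the 2.5/97.5 empirical percentiles; a degenerate
  bootstrap SE of 0 yields p = 1 (no evidence), which arises only for
  constant outcomes.
- Bootstrap replicate designs that are singular fall back to a pseudoinverse
  solve; with cohort-scale data this is vanishingly rare.
- All randomness flows from integer seeds through `numpy.random.SeedSequence`
  spawns, so every bundle, fit and pipeline run is bit-reproducible.
- Problem sizes used by the validation suite: type-I error from 1,000 null
  simulations at n = 500 with 500 resamples; interaction recovery, power and
  size from 200 study-scale cohorts (n = 1,558, ~4,000 markers) each with 500
  resamples; the end-to-end pipeline runs at 1,000 GLM / 300 multinomial
  resamples.

## Known limitations

- The bootstrap Wald interaction test relies on approximate normality of the
  coefficient draws; with very small strata (a melancholic group of ~100) the
  joint test's size is near but not exactly nominal.
- Multinomial bootstrap resamples that fail to converge fall back to the
  full-sample fit (counted, rare); predicted-probability SEs are slightly
  conservative in that case.
- The weight table is treated as an opaque input: deriving the gene network,
  expression betas or co-expression signs from transcriptome/eQTL resources
  is out of scope, as are relatedness/sex checks and imputation itself.
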