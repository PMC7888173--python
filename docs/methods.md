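# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices and the known limitations of `ewaskit`.

## Study design being modelled

The pipeline mirrors a multi-cohort blood-methylation study of smoking:
five discovery cohorts (1407 samples in total; 269 current, 495 former,
643 never smokers) profiled on an 850k-style array, followed by
replication of novel signals in two larger trans-ethnic cohorts (2325
and 1100 samples) and follow-up analyses at the discovery DMPs. The
per-cohort sample sizes, smoking compositions, sex ratios and age
structures used as generator defaults are those of the study conditions:
one all-female twin cohort of 407 (23/147/237 current/former/never),
three birth cohorts (236, 235, 235 samples) and one 294-sample subset
selected for adversity and therefore enriched for smokers (125 current).
Real datasets of this kind are access-controlled, so the package ships a
generator rather than data; every stage accepts on-disk TSV/CSV inputs
with the same schemas should real data be available.

## Per-cohort association model

At each probe the response is the rank-based inverse-normal transform of
beta values, using the Blom constant: z = Φ⁻¹((r − 3/8)/(n + 1/4)) with
average ranks for ties. ("Normalized to N(0,1)" admits a z-score
reading too; `zscore_transform` provides it behind a switch, but rank-INT
is the default because it is the common EWAS practice and is invariant
to monotone rescalings of methylation.) Normalization is computed within
the two-group contrast subset actually fitted. The design is: intercept,
smoking indicator (never = 0), sex indicator (dropped in single-sex
cohorts), four cell-type proportions, BMI, optionally age (enabled for
cohorts that are not birth-year-homogeneous), and reference-coded chip
and chip-position indicators. Zero-variance covariates are dropped with
a warning; collinear columns are removed greedily in design order, and a
collinear smoking column is an error. Beta-scale effect sizes come from
refitting the identical model on untransformed betas.

Unrelated-sample cohorts use OLS, vectorised across probes sharing a
design (closed-form cross-products; t reference with residual df).
Family cohorts use a random intercept per family. The fitter is a
profiled-REML solver written for this package: with variance ratio
λ = σ²_g/σ²_e the covariance whitens group-wise by shrinking each
group-mean component by 1 − (1 + kλ)^−½, so X'V⁻¹X = X'X − Σ_k c_k(λ)A_k
where the per-group-size aggregates A_k depend only on the design. They
are precomputed once, making each REML evaluation O(p³) independent of
sample size and the genome-wide mixed scan ~100× faster than a generic
per-probe mixed-model fit; the generic implementation (statsmodels
MixedLM) serves as an independent cross-check in the test suite.
P-values use a Satterthwaite-type df: df = 2v²/(gᵀAg), with v the
coefficient variance, g its numerical gradient in (σ²_e, σ²_g) and A the
inverse of the numerical REML information; failures fall back to a
Wald-normal p, flagged per probe. When the REML optimum hits the λ = 0
boundary the fit reduces exactly to OLS (and is reported as such), which
also covers all-singleton grouping. One grouping factor (family) is
supported; for twin data a separate zygosity intercept is statistically
redundant once family is included (zygosity is constant within pair), so
the smaller-variance term is by construction the one dropped.

## Meta-analysis and multiple testing

Fixed-effects inverse-variance pooling over the cohorts in which a probe
was successfully fitted; probes present in a single cohort are reported
with k = 1 and no heterogeneity statistics rather than silently dropped.
Two-sided p from the normal distribution of z = β̂/SE (standard IVW
practice). Heterogeneity: Q = Σw_i(b_i − β̂)², Qp from χ²(k−1),
I² = max(0, (Q − (k−1))/Q)·100. The exclusion rule is the conjunction
Qp < 0.10 AND I² > 50 (both cutoffs configurable); at k = 5 this fires
for ≈9% of truly homogeneous probes — a property of the rule, not a bug.
The Bonferroni denominator defaults to the realized number of pooled
probes, with `nominal_m` available to force a round nominal count
(e.g. 800,000) as studies sometimes print. BH-FDR q-values come from
statsmodels' step-up implementation (hand-verified in tests). Genomic
inflation λ divides the median observed χ²₁ statistic by 0.4549364.
Novelty flags: `novel_epic_only` marks probes absent from the older
450k-style array; `novel_gene` additionally requires the annotated gene
to contain no previously reported probe (the prior catalogue is an input
column of the manifest, not a computation).

## Replication and persistence

Replication pools the replication cohorts with the same IVW machinery,
then requires (i) sign agreement with the discovery pooled estimate
(zero estimates never agree — a conservative tie-break) and (ii) p below
α divided by the number of probes actually tested; probes failing QC in
replication shrink that denominator. Persistence re-tests discovery DMPs
in the former-vs-never contrast, pooled across cohorts, against
α/(number of DMPs tested).

## Enrichment

For an annotation family (CGI class, chromHMM state, gene region), each
category yields a 2×2 table of DMP vs non-DMP tested probes, in vs out
of category; significance is the two-sided Fisher exact test (point
probabilities ≤ observed) and effect is log₂(DMP proportion /
tested-probe proportion). The log base is 2 and is recorded in output
metadata. Probes with missing annotation leave both margins for that
family.

## Classifier

Panels are small CpG sets; features are *unadjusted* betas at the panel
probes plus covariates (age, sex, cell proportions, BMI, chip and
position one-hot encoded), fitted with unpenalised logistic regression.
Evaluation draws 20 random 60/40 train/test splits (uniform over
samples; splits leaving a class empty are redrawn with a log note;
per-split seeds are master seed + split index) and reports each split's
AUC and their mean. AUC is the Mann–Whitney concordance probability with
ties counted ½. "Ever smoked" merges current and former smokers into
the positive class. The phenotype-selected cohort subset is excluded
from classifier evaluation by default (`classifier_exclude`), mirroring
how selected subsets bias prevalence.

## Synthetic-data generator

Simulation happens on the logit scale and maps back through the sigmoid,
which enforces beta ∈ [0, 1] while keeping effects additive:

logit(β_ijc) = l_j + smoking offset + covariate terms + chip + position
+ family intercept + noise.

* **Baselines** l_j = logit(m_j) with m_j from a bimodal Beta mixture
  (35% Beta(2,10), 35% Beta(10,2), 30% Beta(4,4)) — the typical
  low/high/intermediate methylome shape. Spiked probes whose baseline
  cannot accommodate their effect are re-drawn from the central
  component (logged); `spike_baseline_range` pins spiked baselines for
  controlled regimes.
* **Spiked effects**: target beta-scale current-minus-never differences,
  magnitudes log-uniform on [0.02, 0.25] (matching the observed range of
  smoking effect sizes, average a few percent, maximum ~25 points), 74%
  negative (the observed hypomethylated share). Because averaging
  through the sigmoid shrinks differences toward 0.5, the logit offset is
  solved numerically (Gauss–Hermite expectation + bisection) so the
  *expected* beta difference equals the recorded truth; the recovery
  tests depend on this calibration. Former smokers receive the offset
  that produces persistence_fraction × effect (0 = full reversal,
  1 = fully persistent; defaults cycle {0, 0.25, 0.5, 1}).
  Heterogeneous probes get cohort-specific sign/magnitude multipliers
  (±, ×U(0.3, 1.5)). 36% of spiked probes are drawn from enhancer
  probes, reproducing the observed enhancer share among smoking DMPs
  against a 12% background.
* **Covariates** are independent of smoking status (so unadjusted
  group-difference tests stay calibrated); each probe has small random
  logit-scale slopes for sex, age, BMI and cell proportions (SDs in
  `covariate_slope_sds`), making covariate adjustment matter for
  precision. Chip (8 samples each) and position effects are N(0, 0.10)
  and N(0, 0.05) per probe×level; residual noise SD is 0.50 on the logit
  scale. Family cohorts split the noise into a family intercept plus
  individual residual at ICC 0.40 (MZ/DZ labels assigned 50/50 but not
  differentiated — no quantitative-genetic model is attempted).
* **Manifest**: annotation categories drawn independently at EPIC-like
  marginal proportions (islands 18%, enhancers 12%, gene bodies 42%…),
  47% of probes on the older array, ~4% cross-reactive, ~5% with nonzero
  MAF (U(0, 0.25)), and a previously-reported flag on a random subset of
  older-array probes standing in for a prior DMP catalogue.

What the generator does **not** emulate: Infinium I/II probe-type
chemistry, genomic autocorrelation of methylation, covariate–smoking
confounding, ancestry structure, and any raw-intensity-level artefacts
(the pipeline starts from clean betas; intensity-level QC and
normalization are out of scope, with exclusion lists supplied via the
manifest). Passing tests therefore demonstrate the statistical machinery
is correct and calibrated under this model, not that it is robust to
every artefact of real array data.

## Calibration conditions and problem sizes

Calibration checks (type-I error, λ, heterogeneity rate, FWER, null-panel
AUC) run on `null_config`: five balanced cohorts of 1000 samples
(30/20/50% current/former/never) with no spiked probes, at 5000–6000
probes. Large balanced cohorts keep residual df high so pooled
z-statistics are nearly normal; under the *default* unbalanced study
(one cohort has 23 current smokers against ~45 design columns) λ sits
near 1.07 — the mild small-sample inflation multi-cohort scans report in
practice, which is why calibration is asserted under the balanced
configuration. The acceptance script simulates at 6000 probes with 60
spiked (6 heterogeneous); the test suite uses 2500 probes for the
discovery fixture and smaller dedicated simulations per property. These
sizes were chosen to keep simulation error well below the asserted
tolerances while remaining desk-scale.

## Numerical choices and degenerate inputs

* Filter order is fixed (cross-reactive → polymorphic MAF > 0.05 →
  missingness > 0.05, strict inequalities); a probe failing several
  filters is counted once, at the first stage. Missingness filtering
  happens before normalization.
* All-tied inputs to the rank-INT map to all zeros (average ranks);
  fewer than 3 non-missing values is an error.
* P-values are floored at the smallest positive double rather than
  reported as 0.
* REML optimisation is bounded on log λ ∈ [−12, 6] with an explicit
  λ = 0 boundary comparison; the Satterthwaite df is clamped to
  [1, n − p].
* BED export converts the 1-based manifest coordinates to 0-based
  half-open single-base intervals; result tables are written at %.17g so
  read-back is bit-exact; missing values are the literal `NA`.
* All randomness derives from a single seed per run; replication-stage
  seeds are offset from the master seed.

## Limitations

* The mixed model supports one random intercept (family). Crossed or
  nested designs (e.g. family × zygosity, plates within batches) are not
  modelled.
* Fixed-effects pooling only; no random-effects meta-analysis or
  leave-one-cohort-out sensitivity.
* The heterogeneity rule is the conjunction of Qp and I² cutoffs; other
  readings of "strong evidence for heterogeneity" can be configured but
  not mixed per probe.
* Classifier evaluation is repeated random splits, not external
  validation; AUCs on synthetic data reflect the generator's noise
  model.
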