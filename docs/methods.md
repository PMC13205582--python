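# Methods

This note documents the statistical procedures, the synthetic-data model, the
defaults and the numerical conventions used throughout `eqtlgwas`, and what
the test suite does and does not establish about behaviour on real data.

## Pipeline overview

Stages run in this order (`eqtlgwas.pipeline.run_pipeline`): simulate or load
cohorts → genotype/expression QC → per-cohort cis-eQTL mapping → eQTL
meta-analysis with BH FDR → matched-null enrichment → per-cohort GWAS → GWAS
meta-analysis → intersection → report tables. Every stage writes a TSV; the
run manifest records the seed, thresholds and counts at each filter.

## Quality control

Variant filters, applied in a fixed order so exclusion reasons are
deterministic: MAF ≥ 0.01, missing rate < 0.05, exact Hardy–Weinberg p >
1 × 10⁻⁵, imputation-quality score ≥ 0.3. The HWE test is the exact
conditional test on the heterozygote count given allele counts (two-sided
minimum-likelihood rule), not the chi-square approximation, because the filter
operates at p = 1e-5 where asymptotics are poor for rare variants. Genes with
mean FPKM < 0.1 are dropped (boundary kept). Missing dosages are mean-imputed
per variant for PCA and regression — standard, and preserves sample size.

Expression is normalized gene-wise by the rank-based inverse-normal transform
Φ⁻¹((rank − 0.5)/n) with average ranks on ties. No tie/offset convention is
universal; this one is symmetric (exact zero mean when there are no ties) and
is the common choice in eQTL pipelines. A constant vector maps to all zeros
with a warning.

Ancestry covariates are the top sample-score principal components of the
column-standardized dosage matrix (default 3 in the pipeline, configurable).
Hidden expression confounders are estimated by gene-wise residualization on
known covariates followed by SVD of the residual matrix; the factor count
defaults to 15 to match common practice. This is a deterministic surrogate
for PEER's variational Bayes factor model: it captures the same linear
confounding directions but makes no sparsity or ARD assumptions.

## Cis-eQTL mapping

Pairs are enumerated within ±1 Mb of the strand-aware TSS (start for +, end
for − genes), boundary-inclusive. `tss_distance` is signed pos − tss with the
sign flipped on − strands, so positive always means downstream of
transcription. Mapping uses the Frisch–Waugh–Lovell residualization fast
path: covariates are regressed out of expression and dosage once, simple
regression follows, and the residual degrees of freedom are corrected for the
covariate count — identical to the full multiple regression (asserted to
1e-8 on the t statistic in the tests). Degenerate fits report the smallest
positive float as the p-value with a `degenerate` flag, never exactly zero.
BH adjustment is applied to all tested pairs in a single global pool, with no
per-gene hierarchical correction.

## Meta-analysis and heterogeneity

Fixed-effects inverse-variance pooling, with Cochran's Q, I² = max(0,
(Q − df)/Q)·100, and the chi-square heterogeneity p. Pairs with I² ≥ 75% and
P_Het < 0.05 are flagged as substantially heterogeneous and reported, not
silently dropped. The pooled p uses the normal approximation of z (the
fixed-effects convention). Pairs observed in a single cohort pass through as
k = 1 and are labelled `single_cohort`; a strict mode requires presence in
all cohorts. Before pooling external summary statistics, alleles are
harmonized: swapped effect/reference alleles flip the beta sign, and
strand-ambiguous (A/T, C/G) mismatches are dropped because a swap cannot be
distinguished from a strand difference.

Printed OR / 95% CI stage summaries are combined by converting each to
(log OR, se) with se = (ln U − ln L)/(2 z₀.₉₇₅), pooling, and exponentiating
the pooled estimate and Wald bounds. Recovered combined p-values are not
exactly those computed from unrounded inputs, so only the OR and CI bounds
are meaningful at printed precision.

## Matched-null enrichment

Per gene, the lead pair minimizes FDR with ties broken by raw p, then larger
|β|, then variant id. Controls are non-significant variants (FDR ≥ 0.05)
sampled without replacement from the same stratum of MAF deciles (computed on
the pooled lead + pool distribution) × |TSS distance| bins at 0–1 kb, 1–10 kb,
10–100 kb, 100 kb–1 Mb. On stratum exhaustion the sampler borrows from the
nearest stratum by Manhattan distance on bin indices (ties toward the lower
MAF bin), logging each borrow. One matched draw is taken per run;
replicate-level calibration lives in the test suite. Overlap follows the BED
convention: a 1-based variant at pos overlaps a 0-based half-open interval iff
pos − 1 ∈ [start, end). Fisher's exact test gives the two-sided p
(minimum-likelihood rule); the OR and its Woolf log-scale CI use a
Haldane–Anscombe 0.5 on all cells only when some cell is zero, and the exact
p is never corrected. Multiplicity: BH across functional categories and
histone marks, Bonferroni across TF and RBP families. Gene-set
over-representation is the upper hypergeometric tail.

A note on calibration testing: exact-test p-values are discrete and
conservative (their mean exceeds 0.5 under the null), so raw p-values cannot
be distribution-uniform. The calibration test therefore checks the
randomized-PIT (smoothed) exact p — exactly uniform under the null — plus the
conservative direction of the raw tail (P(p < 0.05) ≤ 0.05). This is a
diagnostic convention only; all reported p-values are the standard exact ones.

## GWAS and power

Per-variant logistic regression (case status ~ dosage + age + sex + PCs) is
fit by Newton-scoring IRLS, convergence at log-likelihood change < 1e-8
within 100 iterations. Non-convergence or |log OR| > 10 (quasi-separation)
flags the variant for downstream exclusion rather than penalizing the fit, so
estimates stay comparable with the 2×2 closed form used as the oracle.
Genomic inflation is λ = median(χ²₁(p))/0.45494. Suggestive variants satisfy
P_meta < 1 × 10⁻⁵ and per-cohort p < 0.05; concordant effect direction across
cohorts is additionally required by default (implied by fixed-effects pooling,
made explicit and configurable). Loci are formed by greedy p-ascending
clumping at a 500 kb gap — the grouping rule is a declared convention, the
gap configurable.

Trend-test power uses the genotype-relative-risk parameterization of GWAS
power calculators: additive-on-risk penetrances f₁ = r·f₀, f₂ = (2r − 1)·f₀
with f₀ solved from the population prevalence under Hardy–Weinberg genotype
frequencies; case/control genotype distributions follow by Bayes' rule; the
noncentrality is the squared expected score difference over its null (pooled)
variance; power is the noncentral χ²₁ tail beyond the central critical value.
Prevalence defaults to 0.01 and is exposed because published power figures
rarely state it: at MAF 0.20, relative risk 1.20, α = 1e-5, 5130/5776 the
package computes 0.833, which agrees with its Monte-Carlo oracle to
simulation error; calculators with different prevalence or risk-scale
conventions report values up to ~10 points higher, so cross-tool comparisons
of this number are qualitative.

## Integration

Inner join of suggestive GWAS variants with FDR-significant eQTL pairs on
variant id; a GWAS variant absent from the eQTL table is dropped (only
intersections are reported; an unmatched listing is available). Each
candidate records both evidence streams, its locus, the heterogeneity flag,
and a direction note (risk/protective allele increases/decreases expression)
that states the sign relation without asserting mechanism.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
any particular population:

- **Genotypes** — Gaussian copula: per haplotype, a latent AR(1) vector with
  block-diagonal lag-one correlation `ld_rho` (block size `ld_block_size`) is
  thresholded at the allele-frequency quantile; dosage is the sum of two
  independent haplotypes. `ld_rho = 0` gives exact Hardy–Weinberg draws. The
  variant panel (positions uniform on one synthetic chromosome, MAFs uniform
  in `maf_range`, quality scores) depends only on the configuration, so
  cohorts share variants while samples are independent. Missingness is
  injected completely at random (default 0).
- **Expression** — latent = baseline + β·dosage + hidden factors + known
  covariates + noise, emitted on a positive FPKM-like scale by a per-gene
  exponential map (monotone, so the rank-based transform is unaffected). The
  non-genetic variance is normalized to `noise_sd²` per gene, making β an
  effect per allele in non-genetic-SD units — the scale on which the
  downstream INT regression recovers it without attenuation. A configurable
  fraction of genes is pushed below the 0.1 FPKM floor to exercise the filter.
  `het_fraction` of causal pairs flip effect sign in the second cohort.
- **Phenotypes** — case probability = inverse-logit(α + Σ log OR·dosage +
  covariates) with α calibrated by bisection (tolerance 1e-6 on the mean
  probability) to hit `case_fraction`; statuses are independent Bernoulli.
  `risk_overlap_causal` plants risk variants among the causal eQTL variants
  so the integration stage has true positives.
- **Annotations** — interval windows cover causal variants with probability
  min(1, enrichment × coverage) versus coverage elsewhere, plus categorical
  labels with causal variants preferentially non-intergenic.

All randomness flows from one seed through named substreams, so any artifact
is reproducible in isolation. Fixtures are written as VCF 4.2 (dosages in a
DS FORMAT field, MAF and quality in INFO), TSV tables, BED tracks and a YAML
manifest, and round-trip through the module readers.

What the generator does **not** emulate: realistic recombination maps or LD
decay, population structure beyond a two-subpopulation test scenario, allele
frequency spectra, cell-type composition or other non-linear confounding,
retrospective (case-enriched) sampling, and genotyping/imputation error
beyond a scalar quality score. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to everything real cohorts contain.

## Problem sizes in the test suite

The statistical acceptance properties run at sizes chosen to give stable
Monte-Carlo behaviour on a single CPU: 50 null studies of 2 × 150 samples and
5,000 pairs for FDR calibration; 200 planted pairs (β = 0.25, 300
samples/cohort) for recovery and coverage; 100 replicates for the meta power
gain and enrichment power; 200 replicates for enrichment calibration; 10,000
variants at 800 samples for null-GWAS inflation; 50,000 replicates for the
trend-power oracle. Tolerances are stated in each test as multiples of the
corresponding binomial or Monte-Carlo standard error.

## Known limitations

- The PEER surrogate captures linear confounding only; factor counts are not
  selected automatically.
- Locus clumping is distance-based; no LD-aware clumping or conditional
  analysis.
- No trans-eQTL mapping, interaction models, colocalization posterior, or
  random-effects meta-analysis.
- The matched-null sampler controls MAF and TSS distance only (no GC content
  or LD-aware matching).

## Demo configuration

The README's pipeline example uses:

```yaml
outdir: demo2
seed: 7
sim:
  n_samples_per_cohort: {cohortA: 250, cohortB: 250}
  n_variants: 250
  n_genes: 25
  n_causal_pairs: 4
  beta_causal: 1.0
  n_risk_variants: 3
  risk_overlap_causal: 1.0
  risk_or: 3.0
  maf_range: [0.2, 0.5]
```
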