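# Methods

## The analysis

The package studies percent methylation (0–100 scale, as read out by
bisulfite pyrosequencing) at seven CpG sites in the proximal *INS*
promoter, comparing diabetic cases with age-matched non-diabetic
controls. Three questions drive the design:

1. **Which CpGs differ between cases and controls?** Per-CpG two-sided
   Wilcoxon rank-sum tests; methylation distributions are bounded and
   often skewed near the 100 % ceiling, so rank tests are the primary
   inference and a normal-theory t-test is never used.
2. **Is there a multi-CpG disease signature?** A subject is *relatively
   hypomethylated* at a CpG when their value is strictly below
   `μ_c − 2σ_c`, where μ_c and σ_c are the mean and sample SD (n−1
   divisor) of the designated control group. The signature of interest
   is simultaneous hypomethylation at CpGs −19, −135 and −234; its
   case/control contrast is tested with Fisher's exact test on the 2×2
   membership table.
3. **Is methylation under cis-genetic control?** Kruskal–Wallis tests of
   methylation across the 0/1/2 risk-allele genotype groups of rs689 and
   three neighbouring SNPs (allele-specific methylation, ASM).

Raw p-values are reported (no correction across the 7 CpGs, matching
standard practice for a candidate-region panel this size);
Benjamini–Hochberg adjustment is available as an explicit helper.
Displayed p-values are floored at `<2.2e-16` — the familiar R reporting
convention — while machine-readable outputs keep the computed value.

## Synthetic-cohort generator

No subject-level data are distributed, so the generator is a first-class
part of the package: it produces cohorts carrying exactly the structure
the analysis assumes, calibrated to the published summary statistics.

**Methylation marginals.** Per group g and CpG j,
`X_j = μ_gj + σ_gj · Z_j` with `Z ~ N(0, R_g)` a zero-mean unit-variance
multivariate normal (Gaussian copula), then clipped to [0, 100]. A
clipped Gaussian on the percent scale (rather than a logit-normal) is
used because the calibration targets are published directly as
mean ± SD in percent; clipping is inactive for mid-range CpGs and mildly
compresses the upper tail for CpGs with means ≥ 90 (−69, −206), which is
accepted and does not affect the rank-based tests materially.

**Correlation structure.** The T1D calibration couples the
disease-associated trio tightly (latent r: −19/−135 = 0.77,
−135/−234 = 0.65, −19/−234 = 0.60), couples −180 to the trio at
0.40–0.45, and leaves the remaining CpGs weakly correlated (0.15–0.30).
Control-group correlations reuse the case matrix — the published account
only states that the correlation is "also seen" in controls, so this is
a calibration assumption. The T2D calibration uses a weaker matrix with
the −19/−234 pair at 0.10, since those two CpGs move independently (and
in opposite directions) in that cohort.

**Genotypes and LD.** Each subject gets two haplotypes; each haplotype
thresholds a latent multivariate normal draw with correlation matrix
`ld_r`, so each SNP's allele frequency is exact and pairwise LD is one
latent correlation per pair. `ld_r = 1` reproduces complete LD
(identical genotype columns); note the latent correlation is a
tetrachoric correlation, so the *allele-scale* r is attenuated at
intermediate values — an accepted property of the copula model.
Defaults: rs689 risk (A) allele frequency 0.70, rs3842748 0.68 with
r = 0.95 to rs689, and the two distant SNPs (rs4320932, rs6356) at
0.30/0.40 with r ≤ 0.25.

**Allele-specific effects.** Methylation gains
`Σ_s β_sj · g_s` where g_s counts risk alleles. Only rs689 carries
direct effects (+1.5, +2.0, +3.0, +1.5 %/allele at CpGs −69, −102, −180,
−206); rs3842748's observed association arises purely through LD, which
reproduces the observed decay of the genotype–epigenotype relationship
with genetic distance. The preset constructors store *baseline*
marginals adjusted by `−Σ_s 2·freq_s·β_sj` (and SDs shrunk by the
additive genotype variance `Σ_s 2pq·β²`), so the realized population
moments land on the published mean ± SD values.

**Age.** Ages are Gaussian (T1D: 12 ± 4.9 yr, floor 1 yr; T2D: 55 ± 8
yr, an assumption — the published account gives no T2D age moments).
The default young-cohort calibration has zero methylation-age slope;
`with_age_slopes(config, -0.2)` enables the downward drift (percent per
year) reported for older control cohorts.

**Covariates.** HbA1c (8.1 ± 1.4 %) and diabetes duration (7.5 ± 8.5 yr,
clipped at 0) are generated independently of methylation, reflecting the
reported absence of correlation with either. Sex is Bernoulli(0.5).

**Randomness.** One root seed; ages/sex, genotypes, methylation and
clinical covariates use separately spawned streams, and methylation is
drawn per group from its own sub-stream — so extending the SNP panel or
resizing one group never perturbs the other draws. Identical configs
produce byte-identical cohort files.

**What the generator does not emulate.** Bisulfite-conversion error,
pyrosequencing peak noise, read counts, batch effects, population
stratification, VNTR repeat lengths (LD with rs689 stands in for VNTR
class), or any dependence of methylation on HbA1c/duration. Passing
tests therefore demonstrate correctness of the statistical machinery and
faithfulness to the published summary structure — not robustness to
assay artefacts in real data.

## Classifier conventions

- "Below −2SD" is a strict `<`; boundary equality is not flagged.
- The reference is always fit on the control subset designated by the
  caller and is self-referential for the control group itself (controls
  are flagged against thresholds fit on their own sample) when no
  external reference is supplied.
- Subjects missing a methylation value get an NA flag at that CpG and
  are excluded from (NA in) any pattern containing it; pattern
  percentages use the full group size as denominator and round to the
  nearest integer, matching the published n (%) convention.
- A symmetric +2SD hypermethylation rule is deliberately *not* applied
  by default (the published definition is one-sided); hypermethylation
  (CpG −180) is picked up by the association tests instead.

## Statistical conventions and numerics

- **Wilcoxon rank-sum:** exact enumeration when both n ≤ 10 with no
  ties; otherwise normal approximation with mid-ranks and tie-corrected
  variance, continuity correction off. Turning the correction off keeps
  the algebraic identity H = z² with the two-group Kruskal–Wallis test,
  which the suite checks to 1e-9.
- **Kruskal–Wallis:** tie-corrected H, chi-square p on k−1 df; all-tied
  input returns H = 0, p = 1 instead of NaN.
- **Correlation:** signed Pearson r is primary (Spearman switchable);
  pairwise complete cases, two-sided p via the t transform; constant
  columns yield flagged NaN entries, never silent zeros. An adjusted-R²
  view is exposed as an auxiliary accessor.
- **Logistic regression:** `disease ~ methylation + age`, Newton/IRLS,
  convergence tolerance 1e-8, max 50 iterations; perfect separation and
  non-convergence raise explicit errors rather than returning inflated
  coefficients.
- **Fisher exact:** two-sided by summation of hypergeometric point
  probabilities ≤ the observed one, computed in log space (stable at the
  n ≈ 800 relevant here); verified against exact rational enumeration
  for n ≤ 40. The stored odds ratio uses the Haldane–Anscombe +0.5
  correction so it stays finite when a cell is zero.
- **Heatmap ordering:** agglomerative clustering with Euclidean distance
  and complete linkage on the complete-case matrix; rows are sorted by
  subject id before clustering, making the leaf order deterministic and
  permutation-invariant.

## Problem sizes

Simulation-based tests use the study-sized cohorts (802 and 318
subjects), 25 replicates for the replicated significance-bound checks,
2,000 replicates for type-I-error calibration, and 5,000–20,000 draws
for distributional fidelity checks. The full suite and the acceptance
script each run in well under a minute on a single CPU.

## Known limitations

- The latent correlations, LD values, allele frequencies and β effect
  sizes beyond the published mean ± SD tables are calibration choices
  informed by the published figures, not fitted quantities.
- Simulated hypomethylation prevalences (e.g. ~26 % of cases
  triple-flagged) exceed the published real-cohort counts (14 %):
  Gaussian marginals at the published mean ± SD overlap differently than
  the real, heavier-tailed distributions. Count-based checks therefore
  use the published counts as inputs, and simulation-based checks target
  significance bounds and correlations, which are robust to this.
- The −2SD rule's false-positive rate is the Gaussian tail Φ(−2) ≈ 2.3 %
  per CpG by construction; on real (non-Gaussian) data the realized
  control flag rate may differ.
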