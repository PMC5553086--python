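# Methods

## Scope and model

`wpair` tests for association between a pair of diallelic SNPs and a binary
phenotype by comparing the distribution of the k ≤ 9 genotype combinations
between cases and controls, and benchmarks a battery of such tests by
simulation. Genotypes are minor-allele dosages (0/1/2); the 2 × 9 table uses
lexicographic column order (SNP1 genotype outer, SNP2 inner), with row 0 the
controls. All tests are invariant under exchanging the two SNPs (a column
permutation transposing the 3 × 3 genotype grid), and the χ²/likelihood-ratio
tests are additionally invariant under exchanging the case and control rows.

## The W-test

Each observed category contributes a normalized log odds ratio
zᵢ = log-OR(p̂₁ᵢ, p̂₀ᵢ)/SEᵢ with
SEᵢ² = 1/n₀ᵢ + 1/n₁ᵢ + 1/(N₀−n₀ᵢ) + 1/(N₁−n₁ᵢ). The combined statistic is
W = h·Σzᵢ², referred to χ²_f via the regularized upper incomplete gamma
function (valid for non-integer f, no continuity correction). The
sum-of-squares combination form is not printed in the source descriptions of
the method; it is the natural reading of "k non-independent quantities are
combined" into a scaled χ², and is adopted here as a design choice. Its
p-value is strictly decreasing in the statistic for fixed (h, f).

**Category reduction.** The zᵢ are computable only where
0 < n_jᵢ < N_j in both rows. Besides cells empty in either row, we also drop
a cell whose complement count is zero (n_jᵢ = N_j), since the SE terms
1/(N_j − n_jᵢ) are then undefined — an inference from the SE formula, as the
verbal rule only mentions empty cells. k is the number of retained columns.

**(h, f) defaults and bootstrap.** Defaults are h = (k−1)/k, f = k−1. The
bootstrap estimator draws B = 200 replicates, each with
N_B = min(1000, N) individuals and P_B = min(1000, P) SNP pairs sampled
without replacement, and phenotypes permuted independently of genotype
(preserving the case:control ratio; when N_B < N the permuted labels are
subset, so the sampled ratio is hypergeometric around the study ratio).
Each pair contributes (S = Σz², k); pooled values are moment-matched per k:
if h·S ~ χ²_f then E S = f/h and Var S = 2f/h², giving
h_k = 2·mean(S)/var(S), f_k = 2·mean²(S)/var(S). k strata with fewer than
two pooled values fall back to the defaults. One root seed drives all
sampling, so estimates are reproducible. Under the null with common MAFs the
estimated f₉ falls below 9, reflecting the positive dependence among cells of
the two multinomials (covariance [Diag(π) − ππᵀ]/N_j).

## Comparator tests

* **CHI-f**: Pearson χ² on the full 2 × 9 table, df = 8, computed through
  `scipy.stats.chi2_contingency` without continuity correction; undefined
  (NA) when any expected count is zero, i.e. whenever a category or a row is
  entirely unobserved.
* **CHI-r**: the same after dropping columns whose total count is zero,
  df = k′ − 1; undefined when fewer than two categories remain. No Yates
  correction even for tables that reduce to 2 × 2, keeping the test a pure
  Pearson statistic at every k′.
* **LR tests**: likelihood-ratio tests between nested logistic models fitted
  by our own IRLS on the 18 weighted covariate-pattern rows of the table
  (likelihood-identical to the individual-level fit, and far faster inside
  replicate loops). LR8 uses the saturated genotypic parameterisation
  (intercept + 2 + 2 indicator main effects + 4 indicator interactions);
  LR3/LR1/LRI use raw allelic dosage coding. df is the difference in
  estimable parameter counts: aliased columns (structurally absent
  categories) are detected by pivoted QR on the weighted design and dropped;
  a test whose df reduces to zero is undefined. Separation (a covariate
  pattern perfectly predicting outcome) leaves the LRT finite; fits that hit
  the 100-iteration cap with |logit| > 12 are flagged and their boundary
  log-likelihood used. IRLS converges on relative log-likelihood change
  < 1e−8; coefficient covariance is the inverse Fisher information at the
  optimum. The fitter is cross-checked against statsmodels GLM in the test
  suite, and LR8 against the closed-form G² deviance of the table.

## Simulator

Haplotype frequencies for targets (maf₁, maf₂, r²) use the positive root
D = +√(r²·p₁q₁p₂q₂) — minor alleles coupled, the conventional sign choice;
feasibility requires D ≤ min(p₁q₂, q₁p₂) and violations report the feasible
r² range. Individuals are unions of two independent haplotype draws, giving
an exact 9-category genotype distribution. Retrospective ascertainment sets
P(g|case) ∝ pen(g)·P(g) and P(g|control) ∝ (1−pen(g))·P(g); replicates are
multinomial draws of exactly n_cases and n_controls from these, seeded by
(scenario seed, replicate index).

**Calibration to control-group targets.** Benchmark designs state MAF and r²
*among controls*; under a non-null model these differ from the population
haplotype values. `calibrate_control_scenario` numerically inverts the
ascertainment map (scipy hybrid root-finder, equal MAFs at both loci) so the
analytic control distribution hits the stated control MAF and control dosage
r² to ~1e−9. The combined-sample r² is emergent, not targeted.

**Effect sizes.** The benchmark alternatives' generating coefficients are
not published numerically, so the shipped presets are synthetic stand-ins
chosen once: logit-linear coefficients of 0.25–0.35 at common/low MAF
(baseline prevalence 0.1, α = logit(0.1)), and for the rare-variant scenario
a 3 × 3 log-odds table (`COMPLEX_EFFECTS_LOG_ODDS`) that (i) is verifiably
outside the span of {1, x₁, x₂, x₁x₂} (residual norm > 0.1 after projection),
and (ii) yields control MAF 0.01 and case MAF ≈ 0.03 after calibration. With
those settings the rarest genotype combinations (e.g. major-homozygote ×
minor-homozygote, probability ≈ 4e−6) have essentially zero chance of
appearing in 1000 samples, so the full-table χ² is undefined in effectively
every replicate — the accounting regime the benchmark isolates.

## Benchmarking and diagnostics

`run_scenario` tallies, per test, defined results and rejections at alpha
(default 0.05, recorded in every output header), and reports power under two
conventions: ignoring undefined replicates (0/0 reported as undefined, never
as 0) and counting them as non-detections over all replicates. Per-replicate
failures are recorded, never raised. Q-Q data pair the i-th smallest of n
p-values with expected quantile (i − 0.5)/n on the −log₁₀ scale, excluding
undefined entries with a logged count; genomic-control λ is the median
statistic over the χ²₁ median (≈ 0.4549), returned as-is when below 1.

## Problem sizes and what the tests show

The test suite uses the full study geometry (500 cases + 500 controls;
5000 null replicates for calibration checks, 1000 for the sparse-data
accounting, 50-SNP/1225-pair panels for cross-test agreement), with a 99%
binomial band around alpha as the calibration criterion (the W-test is
additionally allowed to be conservative, which it is designed to be). The
simulator draws from exact category distributions, so passing tests
demonstrate correct calibration and accounting *under the assumed two-locus
retrospective model*; they do not speak to genotyping error, missingness
structure, population stratification, covariates, or LD with unmodelled
causal loci — all absent from the generator by construction.

## Known limitations

* Tables for more than two loci (k = 3^L) and single-SNP (k = 3) scans are
  representable in the data model but no operations target them.
* The bootstrap (h, f) estimator requires a multi-SNP panel; with only two
  SNPs available the defaults or externally supplied values must be used.
* PLINK text dialects (.ped/.map, .raw) and delimited dosage tables are
  supported; binary .bed is not.
* p-values from the χ² reference distributions are asymptotic; no exact
  (Fisher-type) small-sample option is provided.
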