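# Methods

## Overview

`vdrmr` implements a two-sample Mendelian randomization (MR) analysis in
which single-SNP instruments for allele-specific VDR binding and a
multi-SNP instrument for serum 25(OH)D are tested against MS case-control
status, per study and pooled across studies. Because individual-level
data from the original cohorts are access-restricted, the package pairs
the analysis code with a generative module that simulates cohorts and
ChIP-exo counts under the model assumptions; all distributional claims
verified by the test suite are claims about data generated this way.

## Allele-specific binding caller (`vdrmr.asb`)

At a heterozygous site covered by ChIP-exo reads, the read count on the
reference allele is modelled as Binomial(n, 1/2) under no allele-specific
binding. The caller:

1. filters site x sample entries to total reads >= 5 with at least one
   read per allele (guarding against PCR-duplication artifacts at
   single-allele stacks);
2. pools surviving counts across cell lines per site and applies an exact
   two-sided binomial test, p = min(1, 2·min(P(X <= x), P(X >= x))). The
   doubled-tail convention was chosen over the minimum-likelihood-sum
   alternative as the simplest defensible two-sided rule; for this reason
   `scipy.stats.binomtest` (which defaults to minlike) is used nowhere in
   the implementation, and tests validate against exact integer
   enumeration instead;
3. calibrates a per-test p cutoff by parametric simulation: null datasets
   are redrawn with the observed per-site totals at pi = 1/2, and the
   largest cutoff whose estimated false-discovery ratio (mean null
   discoveries / observed discoveries) stays below the 2% target is
   selected from the observed p-values. If no cutoff qualifies the
   calibration returns 0 with a warning flag rather than guessing;
4. estimates each passing site's binding effect as the least-squares
   slope of per-sample allele-level read counts on the allele indicator
   — equivalently mean(alt) − mean(ref) — reported as a positive effect
   for the allele with increased binding. Counts are regressed raw; no
   normalization is applied.

Copy-number correction and read mapping are out of scope; the simulator
generates CNV-free counts (total ~ Poisson(lambda), ref ~ Binomial(total,
pi), pi = 1/2 at null sites).

## Instruments (`vdrmr.giv`)

Genotype QC keeps variants with imputation info > 0.8, per-SNP
missingness < 0.05 and MAF > 0.05 (strict inequalities as stated), and
drops samples with missingness >= 0.05 on the surviving panel
("missingness per cohort" is read as per-sample missingness, the natural
counterpart of per-SNP). Residual missing dosages are imputed with twice
the within-study effect-allele frequency — mean-dosage imputation; the
literal "impute with the MAF" would be on the wrong (allele-frequency)
scale.

Summary statistics are LD-clumped greedily: variants sorted by ascending
p (ties broken by chromosome, position, rsID) are accepted when p < 1e-8
and r² < 0.001 with every accepted variant within 10,000 kb on the same
chromosome. Scores are plain weighted sums of effect-allele dosages
(PLINK `--score` with averaging disabled). Allele orientation is resolved
by exact allele-pair matching only; strand-ambiguous pairs (A/T, C/G)
that would require a flip raise an error rather than silently guessing
strand. The published instrument tables orient 25(OH)D betas
inconsistently across sections (per increased vs per reduced serum
level); the package takes whatever orientation the supplied weights file
carries and records it in output metadata rather than guessing.

## Per-study models (`vdrmr.assoc`)

`CaseControlLogit` builds the design (instrument terms plus sex,
within-study birth-year quintile indicators with the first quintile as
reference, HLA carriage 0 vs >= 1 allele, six PCs) and `fit()` returns a
results object with Wald SEs from the inverse observed information.
Maximum likelihood is computed by statsmodels' Newton iterations (IRLS
for the logit link) with convergence at max |Δβ| < 1e-8 within 50
iterations; rank deficiency, non-convergence and separation each raise a
distinct error — separation is never papered over with penalization,
which would silently change the estimand. Wald inference is used
throughout (the reporting convention of the surrounding literature); the
likelihood-ratio statistic is checked against Wald in the tests but is
not the default.

The interaction model forms the GIV_VDR x GIV_25OHD product on raw
scores by default, since no centering or standardization is specified for
the original analysis; a `standardize_25ohd` flag exists for sensitivity
runs and its use is recorded in output metadata. The printed interaction
OR from the original analysis is on an unstated scale, so the package
makes no attempt to reproduce its magnitude — only the inferential
behaviour of b3 (type-I error under pure pleiotropy, power under genuine
interaction) is studied, by simulation.

## Meta-analysis and multiplicity (`vdrmr.meta`)

DerSimonian-Laird pooling with fixed-effect-weight Q (not iterated), tau²
floored at zero, no Hartung-Knapp adjustment, heterogeneity p from the
chi-square survival function at k−1 df, and I² = max(0, (Q−df)/Q)·100 on
the percent scale. With one study the pooled result degrades gracefully
to the study itself (tau² = Q = 0, p_Q = 1, I² = 0). Benjamini-Hochberg
correction is applied within a family per model type per 25(OH)D
instrument — the most conservative consistent reading of the original
correction structure, and configurable.

A note on BH: the step-up adjusted values dominate the inputs, are
bounded by 1 and are order-preserving, but they are *not* a fixed point
of the adjustment map — re-adjusting an adjusted vector can only inflate
it (counterexample: (0.25, 1.0) -> (0.5, 1.0) -> (1.0, 1.0); R's
`p.adjust` behaves identically). The test suite asserts the true
properties.

## Synthetic data (`vdrmr.simulate`)

Cohorts are drawn from the logistic disease model
`logit P(case) = b0 + (b_vdr + b_pleio)·GIV_VDR + b_25ohd·GIV_25OHD +
b_int·GIV_VDR·GIV_25OHD + covariates`, with genotypes at Hardy-Weinberg
equilibrium (dosage ~ Binomial(2, maf)), and case-control ascertainment
emulated by sampling the requested numbers of cases and controls without
replacement from a population pool (the original studies are ascertained
case-control designs). `b_vdr` (causal, through binding) and `b_pleio`
(outside binding) are summed in generation and exist separately for
scenario control; either may be a vector to simulate many binding
variants at once, which the instrument-family analyses require.

Defaults emulate the study populations: female fraction 0.5 in the
population with a log(3) female log-OR (yielding ~75% female cases),
HLA-DRB1\*15:01 allele frequency 0.15 with a log(3) carriage log-OR
(~55% carriage in cases vs ~28% in controls), birth years N(1960, 12²),
PCs standard normal and independent of genotype (covariate plumbing
only — genotype-correlated structure is out of scope), 8 score SNPs with
MAFs uniform on (0.1, 0.5) and per-SD effects N(0, 0.05²), and
missingness injected completely at random. Birth-year quintiles are
computed within study, because all analyses are per-study. What the
simulator deliberately omits: LD structure between variants, population
stratification correlated with genotype, informative missingness, and
imputation noise beyond a scalar info score — so passing tests establish
the statistical machinery under the stated model, not robustness of the
original findings to those real-data complications.

The ChIP-exo generator carries hidden per-site truth labels in a separate
attribute used only to evaluate the caller's FDR; they never travel
through the count TSV format, so calling code cannot see them.

The packaged fixture stores the published per-study case/control summary
counts verbatim; `summarize_cohorts` recomputes group percentages
(rounded to one decimal, the table convention) and across-study totals
from the raw counts.

## Problem sizes and numerical choices

The operating-characteristic studies use four simulated cohorts of
1,000/1,000 with 2,000 replicates for the type-I error of the b3 test
(binomial SE ~0.5% around the 5% nominal level), 100 replicates of four
cohorts of 6,250/6,250 (pooled n = 50,000) for CI coverage of a true OR
1.10, and 50 ChIP-exo datasets of 400 sites x 16 samples (20% true
binding variants, pi = 0.9, lambda = 50, 20 null calibration replicates)
for the caller's empirical FDR; the acceptance script scales the type-I
cell to 1,000 replicates and adds a 400-replicate power cell at
interaction OR 2.17. Rejection sampling aborts with an explicit error
(naming the expected case fraction) after 1,000x the requested sample
size has been drawn, which only occurs for degenerate intercepts. All
randomness flows from user-supplied seeds through `numpy.random.
SeedSequence.spawn`, so every table and TSV is byte-reproducible.

## Known limitations

- Single-variant instruments cannot be checked with multi-SNP pleiotropy
  diagnostics (MR-Egger, median estimators); the b3 interaction is the
  only pleiotropy guard, and interactions need substantially larger
  samples than main effects (the power study quantifies this).
- The DL Wald test with few studies (k = 4) is known to be slightly
  miscalibrated under heterogeneity; the simulations here are
  homogeneous across cohorts.
- The ASB caller pools counts across cell lines before testing;
  per-sample testing with p-value combination is a reasonable alternative
  not implemented here.
- LD r² is computed from dosage vectors supplied by the caller; no
  external reference panel is bundled.
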