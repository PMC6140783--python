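# Methods

## Setting and data model

The package targets candidate-region studies in which a genotyped variant
is suspected of acting on gene regulation through DNA methylation. The
measurements it models are those of a targeted bisulphite-pyrosequencing
design: per-sample genotypes at a few SNPs, percent methylation at an
ordered run of CpG sites (one value per sample per CpG per tissue, in
[0, 100]), triplicate allele-percentage readings at transcript SNPs in
genomic DNA and cDNA, qPCR cycle thresholds, and paired firefly/renilla
luminescence counts. All tables travel as delimited text with a header;
genomic coordinates are 1-based inclusive internally (so
chr6:44,695,068–44,695,721 spans 654 bp) and are converted to 0-based
half-open only on BED export. Missing values are propagated, never
imputed; each analysis takes complete cases for the variables it uses.

Genotypes are stored as unordered allele pairs against a per-SNP
declaration of valid alleles and the risk allele; risk-allele dosage
(0/1/2) is a derived view. When a SNP is assayed through a perfect-LD
proxy (a common pyrosequencing practicality), the substitution is
declared in the SNP specification (`proxy_for`), never inferred.

## mQTL testing and boundary calling

Per CpG, methylation is stratified by genotype and tested with a classic
pooled-variance one-way ANOVA (`scipy.stats.f_oneway`). Two grouping
modes are offered: three genotype classes, or a two-class comparison of
risk-allele carriers against non-carriers for cohorts whose rare
homozygote class is too small — in the two-class mode the ANOVA F equals
the squared pooled t statistic, an identity the tests assert. A genotype
class containing a single sample is dropped with a warning (it
contributes no within-group variance); a CpG left with fewer than two
populated classes is flagged untestable rather than raising. P-values
are Bonferroni-corrected over the CpGs actually tested within one
tissue run, not across tissues.

The region call takes the significant set {CpG : p_adj < α} and reports
the first and last members in genomic order as the 5′/3′ boundaries.
Interior non-significant CpGs do not truncate the call — tissue panels
routinely show one weak interior site inside an otherwise consistent
region — but are listed as gaps with the contiguity flag cleared. An
across-CpG Bonferroni on the omnibus p was chosen over pairwise post-hoc
corrections; the grouping and correction scope are recorded in the
result so either convention can be audited.

## Variance partitioning

For each CpG, percent methylation is regressed on risk-allele dosages by
OLS, with SNPs entered sequentially. The contribution of the k-th SNP is
the incremental R² on entry, ×100; nested fits guarantee the
contributions are non-negative and sum exactly to the combined-model R²
(asserted to 1e-9; floating-point negatives below 1e-10 are clamped with
a warning). The combined R² is invariant to entry order, but the split
between correlated SNPs is not, so the order used is always recorded.
The default order is descending marginal log-worth (strongest marginal
association first); a user-fixed order is accepted. Log-worth is
−log10 of each SNP's marginal t-test p in the full model. A SNP whose
dosage column adds no rank to the design (a perfect-LD proxy) receives a
contribution of exactly 0 with a collinearity flag. Dosage (additive)
coding is the default, using one degree of freedom per SNP; a
categorical genotype-class coding is available behind a flag.

## Allelic expression imbalance

Replicate QC follows the pyrosequencing convention: a sample-material
whose replicate allele percentages span more than 5 percentage points
(configurable) is excluded, and a sample missing either material after
QC is dropped — the normalized ratio needs both. The "5%" threshold is
interpreted as percentage points of allele percentage, the assay's
native unit. Ratios are odds-style transforms of the replicate-mean
percentage, r = p/(100−p); the normalized ratio divides the cDNA ratio
by the same sample's DNA ratio, cancelling amplification and detection
bias (a fold f maps to a cDNA numerator fraction f/(1+f), so 68.75%
against a 50:50 DNA baseline is exactly 2.2-fold). A mean percentage of
0 or 100 is monoallelic and excluded with a flag.

Two cohort tests:

* **Paired mode** (transcript SNP in perfect LD with the regulatory
  variant): two-sided paired t-test of per-sample cDNA vs DNA ratios.
  Direction is reported relative to the numerator allele only when the
  LD link is declared. A `log2` option runs the test on log ratios.
* **Variance mode** (unlinked transcript SNP): direction is unknowable,
  so ratios are folded to max(r, 1/r) and the spread in compound
  heterozygotes (heterozygous at transcript **and** association SNP) is
  compared with that in association-SNP homozygotes. The default is a
  two-sided F-test of variance equality, mirroring the classical "test
  of variances"; a Brown–Forsythe (median-centred Levene) alternative is
  provided.

**A caveat stated prominently:** folding the null ratios makes them
distinctly non-normal, and the plain F-test is anti-conservative on
folded data — in the package's own null simulations (fold 1 in both
strata, 10+10 samples, 1000 cohorts) it rejects at roughly 9–11% at
nominal 5%. The Brown–Forsythe route holds its size (≈3.5–5%, mildly
conservative at these stratum sizes) and is what the calibration suite
asserts; use it whenever the p-value matters rather than the variance
ratio itself.

## meQTL regression

Per CpG, the per-sample mean normalized ratio is regressed on percent
methylation by simple OLS; p comes from the slope's t-test. Whether
ratios are inverted first is an explicit flag — inverted for
unlinked-SNP analyses, signed for linked ones — and inverting then
regressing is identical to composing with the AEI module's inversion
(asserted). Per-sample means, not replicate-level values, are the unit
of analysis. Raw per-CpG p-values are reported, with an optional
Bonferroni column; fewer than three matched samples flags the CpG
untestable, and zero variance in either variable flags it degenerate
(slope 0, p 1) rather than producing numerical noise.

## Reporter reductions

Relative expression uses 2^−ΔCt with the housekeeper aggregate defined
as the arithmetic mean of housekeeper Cts per sample — equivalent to a
geometric mean of linear housekeeper expression, the standard
multi-reference convention. Fold change between conditions is the ratio
of mean relative expression, which is invariant to any global Ct shift.
Condition effects across genes/isoforms are tested by two-way ANOVA
with Type II sums of squares (statsmodels `anova_lm`), which equals
Type I exactly on balanced designs (asserted) and tolerates mild
unbalance.

Luciferase wells are normalized per well as firefly/renilla, then
divided by the mean ratio of the empty-vector wells sharing the same
in-vitro methylation state, so each matched control's mean activity is
exactly 1 by construction. Construct-vs-control comparisons use the
two-sided exact Mann–Whitney U: the exact null distribution when the
pooled data are tie-free, an exact permutation of the mid-rank statistic
for tied samples up to n+m = 20, and the tie-corrected normal
approximation beyond.

## The synthetic cohort generator

The generator reproduces the statistical structure the analyses assume,
with every generating parameter stored in a truth sidecar:

* **Genotypes.** Each sample is two independent draws from a declared
  haplotype frequency table (Hardy–Weinberg). LD is therefore specified
  generatively; a helper reports realized pairwise genotype r² so
  configurations can be tuned. The default four-SNP table
  (A-T-C-T 0.65, G-C-T-C 0.28, A-C-T-T 0.05, A-C-C-T 0.02 over the
  association SNP rs10948172, flanking SNP rs10948155, intra-region SNP
  rs62435998 and transcript SNP rs529125) realizes r² ≈ 0.72/0.79/0.91
  among the first three and exactly 1.0 for the proxy pair, matching the
  LD pattern reported for the locus; the second gene's transcript SNP
  rs1200428 segregates independently at MAF 0.23.
* **Methylation.** value = clip(baseline + Σ effect×dosage +
  N(0, σ), 0, 100). Defaults: baseline 65%, σ = 4%, association-SNP
  effect −8% per risk allele at sites 2–12 (−2% at the weak site 6,
  zero at sites 1 and 13–15), small additional effects (−1, −0.8) for
  the two LD partners. Gaussian noise with clipping was preferred over a
  beta model because targeted assays report percent ± SEM summaries;
  a beta option is a possible extension. The synthetic CpG coordinates
  place sites 2–12 exactly 572 bp apart, so a correct boundary call
  reproduces that span.
* **Allele quantification.** DNA replicates are drawn around 50%, cDNA
  replicates around the fraction implied by the gene's fold (f/(1+f)),
  with independent N(0, 1.5) percentage noise per replicate, three
  replicates per material. For the unlinked gene the imbalance appears
  only in association-SNP heterozygotes with random phase (a cis
  variant's two alleles are equally expressed in homozygotes); linked
  genes show it in every transcript-SNP heterozygote. Default folds:
  2.2 (linked gene), 1.3 (unlinked gene).
* **Expression and luminescence.** Per-condition Ct shifts (the default
  deletion condition shifts the long-isoform target by −log2(3.9)
  cycles, i.e. a 3.9-fold increase), Ct noise sd 0.2, six biological
  repeats; per construct×state activity multipliers (1.0 / 3.2 for the
  risk haplotype unmethylated, 1.79 / 8.24 methylated) with lognormal
  ratio noise (σ = 0.25) over 21 wells.

What the generator does **not** emulate — and hence what passing tests
do not certify about real data: bisulphite-conversion bias, batch and
plate effects, beta-like heteroscedasticity of methylation near 0/100,
cell-type composition differences between tissues, correlated noise
across neighbouring CpGs, and pyrosequencing systematic allele bias
beyond what DNA normalization removes.

## Numerical choices and degenerate inputs

All-identical ANOVA inputs give F = 0, p = 1 with a degenerate flag;
zero within-group variance with distinct means gives F = ∞, p = 0,
likewise flagged. A zero-variance stratum in the variance test yields
the limiting F (0 or ∞) with a flag rather than an exception. Exact
Mann–Whitney discreteness means "identical groups" return p = 1 rather
than 0.5-ish mid-p values. Seeds expand from one master integer through
`numpy.random.SeedSequence`, so cohorts are bit-identical under a fixed
configuration and pipeline stages consume independent streams.

## Validation scale

The calibration suite uses 1000 simulated cohorts per null-size check
(Monte-Carlo SE ≈ 0.007 at α = 0.05), 200 cohorts per fold-recovery
check and 100 per partition-dominance check, at the cohort sizes the
study design uses (60 samples; 8–10 informative heterozygotes per AEI
stratum; six qPCR repeats; 21 wells per construct). These sizes were
chosen so each property is decided well inside its Monte-Carlo noise.

## Known limitations

The variance-mode AEI p-value inherits the F-test's non-normality
sensitivity discussed above. The incremental-R² split between SNPs in
strong LD depends on entry order by construction; only the combined R²
is order-free. Bonferroni across CpGs ignores their spatial correlation
and is conservative for dense panels. The meQTL regressions treat
per-sample mean ratios as exact, ignoring replicate-level measurement
error (attenuation is expected to be mild at the assay's replicate
noise). None of the analyses model family structure or covariates such
as age and sex.
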