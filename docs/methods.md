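# Methods

## The interaction statistic

Everywhere in the package the two-locus test is the unbalanced two-way
fixed-effects ANOVA on genotype classes. For a SNP pair (i, j) with
dosages in {0,1,2}, the reduced model fits grand mean + row (genotype at
i) + column (genotype at j) effects by least squares; the full model fits
a free mean per non-empty cell of the 3×3 joint-genotype table. The
statistic is

    F = ((RSS_reduced − RSS_full) / df_int) / (RSS_full / df_res)

with df_int = (#non-empty cells) − rank(reduced design) and
df_res = n − (#non-empty cells); P_int is the upper tail of
F(df_int, df_res). With all nine cells occupied this is the familiar
4-df interaction test. Both models are functions of per-cell counts and
phenotype sums only, which is what the exhaustive scan and the
permutation engines exploit: per-cell statistics for all pairs come from
nine one-hot genotype cross products (dense matrix products), and the
reduced model is solved per pair through its 5×5 weighted normal
equations in a batched solve. Pairs with an empty marginal genotype
class, a singular reduced design (e.g. SNPs in perfect LD), or too few
residual degrees of freedom are routed through a fully guarded per-pair
path that determines ranks by SVD.

Degenerate outcomes are reported, not suppressed: a pair that leaves no
interaction degrees of freedom is *untestable* (P_int = 1, flagged); a
fit with zero full-model residual but positive interaction sum of
squares is *saturated* and reported at the smallest positive
representable P (≈ 5·10⁻³²⁴), flagged — the noiseless haplotype-recessive
showcase lands here by construction. Degrees of freedom adjust
automatically to empty cells; no minimum cell occupancy is imposed.

The conditional interaction test adds a background SNP to *both* models
as a 3-level genotype factor (not an additive dosage), so that recessive
single-locus signals — exactly the kind a masking haplotype produces —
can be absorbed by conditioning. A background in perfect LD (r² = 1) with
either pair member is flagged collinear and returns P_int = 1.

## Thresholds

With N post-QC SNPs and K marginal SNPs (single-SNP P ≤ 5×10⁻⁸), the
combined-search 5% genome-wide thresholds are

    t_full     = 0.05 / (N(N−1)/2 − (N−1)K)
    t_marginal = 0.05 / ((N−1)K)        (undefined for K = 0)

Pairs involving a marginal SNP are judged against t_marginal, all others
against t_full; comparisons use ≤, so the boundary counts as significant.
"Suggestive" is defined as the band (t, 10t] above the applicable
threshold — the band needed a hard rule and one order of magnitude is the
natural choice on the −log10 scale. The scan's retention threshold
(default P_int < 10⁻⁵, strict) and the local-pair rules (same chromosome,
distance < 1,000,000 bp, both strict) are fixed filters.

The window permutation threshold estimates the effective number of tests
inside a local region: sample a centre SNP with 20 SNPs on each side on
the same chromosome, permute the phenotype 100 times, test all 820
within-window pairs per permutation, record each permutation's minimum
P_int, take the per-window 5% point of the minima (order-statistic
interpolation), and average over 200 windows. One permutation is shared
by all pairs of a window, which preserves the within-window LD that the
procedure exists to capture. Under independence the threshold approaches
the Šidák/Bonferroni value 0.05/820 ≈ 6.1×10⁻⁵; with strong LD it rises
toward 0.05 as the effective test count collapses. The permutation
threshold is reported as a diagnostic; retention keeps using 10⁻⁵, which
is the more conservative choice genome-wide since the windowed value is
not corrected for the unknown number of local regions.

## QC and phenotype preparation

Filter order is fixed and recorded in the QC report: autosomes only →
sample call rate ≥ 0.97 → SNP call rate ≥ 0.95 → MAF ≥ 0.02 → exact
Hardy–Weinberg P ≥ 10⁻¹⁰ → individual heterozygosity (upper tail only,
robust z from median/MAD, Benjamini–Hochberg at FDR 0.01) → outliers of
the first three principal components of the identity-by-state matrix
(two-sided robust z, BH at FDR 0.005 per component, union). Each excluded
item carries exactly one primary reason — the first filter that trips.
The order is a package decision; sample-level filters run before
SNP-level ones recompute their statistics. QC is idempotent on its own
output. The robust-z + BH construction for the two FDR-based outlier
filters is this package's definition; it has the interface and intent of
the usual GWAS heterozygosity/stratification screens.

The Hardy–Weinberg test is the standard conditional exact test: given
the allele counts, sum the probabilities of all heterozygote counts no
more probable than the observed one. Monomorphic SNPs return P = 1 by
convention. The implementation (log-gamma arithmetic) is pinned to a
rational-arithmetic enumeration oracle in the tests to < 10⁻¹².

Phenotypes are prepared in three stages: OLS adjustment for covariates
(sex, age, centre as a factor), rank-based inverse-normal transform
Φ⁻¹((rank − ½)/n) with average ranks for ties, then residualization
against the polygenic mixed model y = Wβ + g + e with g ~ N(0, σ²_g·GRM)
and e ~ N(0, σ²_e·I), where W is an intercept plus the first ten IBS
principal components. The GRM is the VanRaden-style cross-product of
standardized dosages divided by the SNP count (missing dosages are
mean-imputed inside the GRM and PCA only, never in association tests;
IBS itself uses pairwise exclusion of missing genotypes). REML profiles
everything but the variance ratio λ = σ²_g/σ²_e, which is found by
bounded scalar minimization on log λ (tolerance 10⁻⁶) after rotating to
the GRM eigenbasis. Reported are the environmental residuals
ê = σ²_e V⁻¹(y − Wβ) — the trait actually scanned — and
h² = σ²_g/(σ²_g + σ²_e) with a curvature-based standard error. When the
GRM is numerically the identity the variance split is unidentifiable; the
unrelated-samples convention h² = 0 is used and ê reduces to OLS
residuals on W. Because relatedness is absorbed here, the single-SNP scan
downstream is plain least-squares regression of residual on dosage — the
unrelated-samples equivalent of a family score test, an equivalence the
tests exercise on unrelated simulated samples.

The genomic inflation factor λ regresses the sorted observed 1-df
chi-square quantiles (from P-values) through the origin on the expected
chi-square(1) order statistics; the chi-square scale (rather than the P
or −log10 P scale) makes λ the usual variance-inflation slope.

## The synthetic-data generator

The generator is the package's study design, not a convenience fixture.
Each haplotype block is a pool of haplotypes with frequencies; every
individual draws two haplotypes per block independently (random mating),
so HWE holds exactly at every SNP and within-block LD is exactly the LD
implied by the pool. Blocks are independent and coordinate-disjoint.
An untyped causal variant is a *label* on one haplotype — never a
genotyped column — and adds its effect only to individuals homozygous
for the flagged haplotype, mirroring a variant invisible to the panel.
The showcase block (`fig2_block`) has two SNPs and the four haplotypes at
frequency 0.25 each: allele frequencies 0.5, zero LD, and with affected
trait value 2 the single-SNP homozygote marginal mean is exactly 0.5
(one in four aa individuals is ab/ab). The phenotype model adds, in
order: additive dosage effects, 3×3 interaction cell offsets, the
causal-haplotype effect, a polygenic score (iid effects over a background
SNP set, rescaled so its variance is h²/(1−h²)·σ²_noise, i.e. h² is
defined against the polygenic-plus-noise part of the trait), covariate
effects and Gaussian noise. Dosages count minor alleles with the minor
allele fixed per SNP at generation time; positions are 1-based; missing
genotypes can be injected completely at random to exercise QC.
Regeneration from the same seed is bit-identical, and one global pipeline
seed fans out to named per-stage substreams (CRC-keyed SeedSequence).

What the generator does *not* emulate: coalescent-realistic LD decay
along a chromosome, allele-frequency spectra, X chromosome, imputation
dosages, case/control traits, or family structure. Passing tests
therefore demonstrate the statistical machinery under the stated model —
HWE, block-wise LD, Gaussian noise — not robustness to the full
complexity of real cohort data.

## Replication

Region-level replication of a discovery pair builds, per locus, the
window of the focal SNP (or its nearest-SNP proxy, ties to the lower
position) plus up to five SNPs on each side (truncated at chromosome
ends), and tests the up-to-121 cross-locus pairs only: the grid includes
the focal SNPs, excludes within-locus pairs to preserve the two-locus
structure, and errors if the two windows overlap (the loci are then not
separable). The observed best replicate pair is the grid minimum of
P_int and does not depend on the permutation seed; the 5% threshold is
the interpolated 5th percentile of the grid minima over 1000 phenotype
permutations. Verdicts: replicated (best ≤ threshold), nominal-only
(best ≤ 0.05), otherwise not replicated. Under a null replication
phenotype the false-replication rate is calibrated at 5% (verified to
±2% over 300 simulated discovery regions).

## Problem sizes used in the tests

All empirical tests run on simulated data at sizes chosen to make the
Monte-Carlo error small relative to the asserted bands: the worked
example at n = 100,000; null calibrations at n = 400–500 with 500–4000
SNPs; heritability recovery as means over 20 replicates at n = 500 with
1000 background SNPs per level h² ∈ {0, 0.3, 0.6}; the SNP-coverage
downsampling experiment on a 1000-SNP null panel counting pairs below
P_int = 10⁻³ (the published panels' counting threshold of 5×10⁻⁸ yields
expected null counts near zero at any simulable panel size, so the
combinatorial frac² scaling is measured where counts are plentiful; the
counting threshold is a parameter of `downsample_experiment`). The
window-threshold Šidák check uses 10 windows × 100 permutations; the
region-replication calibration uses 300 null regions × 1000 permutations.

## Known limitations

- The pairwise scan is dense linear algebra, sized for panels up to a few
  thousand SNPs in memory; genome-scale panels (10⁵–10⁶ SNPs) would need
  chunked out-of-core scanning or the bit-parallel engines built for that
  purpose.
- The REML fit uses a single full eigendecomposition (O(n³)); practical
  to a few thousand samples.
- The heterozygosity and PC outlier screens assume approximately
  unimodal null distributions; heavily admixed cohorts would need
  ancestry-aware QC before these filters are meaningful.
- P-values from the exact Hardy–Weinberg test are discrete; uniformity
  diagnostics on small samples should expect the usual conservatism.
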