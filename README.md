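# locepi

Local SNP–SNP interaction analysis for quantitative traits.

Genome-wide association studies (GWAS) test one SNP at a time and miss
causal variants that are visible only through *joint* genotypes of nearby
markers. A classic mechanism: an untyped recessive variant carried on one
haplotype of two neighbouring SNPs. Only individuals homozygous for that
haplotype (the double-homozygote genotype class *aabb*) are affected, so a
single-SNP scan sees a diluted marginal signal while a two-locus
contingency-style test sees a strong interaction. `locepi` implements the
full analysis path for finding and vetting such **local interactions**
(same-chromosome SNP pairs < 1 Mb apart) in quantitative-trait GWAS data:

- **Simulation** of GWAS-style cohorts: haplotype blocks under
  Hardy–Weinberg equilibrium and random mating, configurable MAF and
  within-block LD, untyped recessive variants tagged by a haplotype,
  additive/interaction/polygenic effects and covariates.
- **QC and phenotype preparation**: call-rate, MAF, exact Hardy–Weinberg
  and heterozygosity/PC-outlier filters; covariate adjustment, rank-based
  inverse-normal transform, and environmental residuals from a REML
  polygenic model (with heritability h²).
- **Single-SNP GWAS** on the residuals, with the genomic inflation factor
  λ and the genome-wide consensus threshold P ≤ 5×10⁻⁸ defining the set of
  K *marginal* SNPs.
- **Exhaustive pairwise interaction scan** over all N(N−1)/2 pairs using an
  unbalanced two-way genotype-class ANOVA F-test, retaining pairs with
  P_int < 10⁻⁵ and applying the combined-search Bonferroni thresholds
  0.05/(N(N−1)/2 − (N−1)K) (no marginal SNP involved) and 0.05/((N−1)K)
  (at least one marginal SNP involved).
- **Local-interaction tools**: composite LD r² (squared dosage
  correlation), permutation thresholds from random 41-SNP windows, and
  conditional interaction tests that ask whether a marginal SNP explains a
  local pair.
- **Replication**: SNP-level tests, nearest-SNP proxies, and region-level
  replication over 11×11 SNP neighbourhood grids against a
  permutation-derived 5% threshold.

## Worked example

Simulate the haplotype-masked recessive showcase: two SNPs with allele
frequency 0.5, the four haplotypes ab/aB/Ab/AB each at frequency 0.25 (so
the SNPs are in linkage equilibrium), and an untyped recessive variant on
the ab haplotype giving affected ab/ab homozygotes trait value 2:

```python
import numpy as np
from locepi import (fig2_block, simulate_genotypes, simulate_phenotype,
                    PhenoModelSpec, interaction_test, composite_r2)

geno = simulate_genotypes([fig2_block()], 100_000, seed=1)
spec = PhenoModelSpec(causal_haplotype_effect=2.0, noise_sd=0.0)
pheno, truth = simulate_phenotype(geno, spec, seed=2)
y = pheno["trait"].to_numpy()
d1, d2 = geno.dosages[:, 0], geno.dosages[:, 1]

print("mean(y | aa)   =", round(y[d1 == 2].mean(), 3))
print("mean(y | aabb) =", y[(d1 == 2) & (d2 == 2)].mean())
print("LD r^2         =", round(composite_r2(d1, d2), 5))
r = interaction_test(y, d1, d2)
print("interaction    :", r.flag, "P_int =", r.p_int)
```

Output:

```
mean(y | aa)   = 0.491
mean(y | aabb) = 2.0
LD r^2         = 1e-05
interaction    : saturated P_int = 5e-324
```

Only one in four single-SNP homozygotes is an affected ab/ab individual,
so the marginal genotype mean is ≈ 0.5 — weak for GWAS — while the joint
aabb class sits exactly at 2 with zero within-cell variance: the
interaction fit is saturated (P_int below the smallest representable
value) even though the two SNPs show no LD at all.

An end-to-end run (simulate → QC → GWAS → pairwise scan → local pairs),
writing TSV outputs and a reproducibility manifest:

```python
from locepi.pipeline import run_all, default_config
manifest = run_all(default_config(seed=5), "out/")
```

or from a shell: `locepi run-all --config config.yaml --out out/`
(subcommands `simulate`, `qc`, `gwas`, `episcan`, `local`,
`window-threshold`, `condition`, `replicate`, `downsample` run individual
stages on PLINK-text data).

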