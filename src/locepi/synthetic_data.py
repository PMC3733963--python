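"""Simulation of GWAS-style genotype/phenotype data with haplotype structure.

The generator draws, for every individual and every haplotype block, two
haplotypes independently from the block's haplotype pool (random mating), so
every SNP is in Hardy-Weinberg equilibrium and the linkage disequilibrium
within a block is exactly the LD implied by the haplotype frequencies.
Blocks are mutually independent.

A block may carry an *untyped* recessive causal variant: the variant is a
label attached to one haplotype of the pool and never appears as a genotyped
column.  Individuals homozygous for the flagged haplotype receive a trait
offset, which is what turns an invisible recessive variant into an apparent
statistical interaction between the genotyped SNPs of the block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1  # dosage sentinel for an uncalled genotype

__all__ = [
    "MISSING",
    "HaplotypeBlock",
    "GenotypeDataset",
    "PhenoModelSpec",
    "SimulationTruth",
    "fig2_block",
    "unlinked_blocks",
    "simulate_genotypes",
    "simulate_phenotype",
]


@dataclass(frozen=True)
class HaplotypeBlock:
    """A haplotype block: a pool of haplotypes over ``n_snps`` biallelic SNPs.

    Haplotypes are binary vectors (0 = major allele, 1 = minor allele).
    ``causal_flag`` optionally marks the haplotype that carries an untyped
    causal variant.
    """

    chromosome: int
    start_pos: int
    snp_spacing: int
    n_snps: int
    haplotypes: tuple[tuple[int, ...], ...]
    haplotype_freqs: tuple[float, ...]
    causal_flag: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.chromosome <= 22:
            raise ValueError(f"chromosome must be an autosome 1-22, got {self.chromosome}")
        if self.snp_spacing <= 0:
            raise ValueError("snp_spacing must be positive")
        if len(self.haplotypes) == 0:
            raise ValueError("haplotype pool is empty")
        if len(self.haplotypes) != len(self.haplotype_freqs):
            raise ValueError("haplotypes and haplotype_freqs differ in length")
        for h in self.haplotypes:
            if len(h) != self.n_snps:
                raise ValueError("every haplotype must have length n_snps")
            if any(a not in (0, 1) for a in h):
                raise ValueError("haplotype alleles must be 0/1")
        total = float(sum(self.haplotype_freqs))
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"haplotype_freqs must sum to 1, got {total}")
        if any(f < 0 for f in self.haplotype_freqs):
            raise ValueError("haplotype_freqs must be non-negative")
        if self.causal_flag is not None and not 0 <= self.causal_flag < len(self.haplotypes):
            raise ValueError("causal_flag out of range")

    @property
    def positions(self) -> np.ndarray:
        return self.start_pos + self.snp_spacing * np.arange(self.n_snps)

    @property
    def end_pos(self) -> int:
        return int(self.start_pos + self.snp_spacing * (self.n_snps - 1))


def fig2_block(
    chromosome: int = 1,
    start_pos: int = 1_000_000,
    snp_spacing: int = 10_000,
    causal: bool = True,
) -> HaplotypeBlock:
    """The two-SNP haplotype-masked recessive showcase block.

    Two biallelic SNPs, four haplotypes (ab, aB, Ab, AB) each at frequency
    0.25, so each SNP has allele frequency 0.5 and the two SNPs are in
    linkage equilibrium.  The ``ab`` haplotype (minor at both SNPs, index 0)
    carries the untyped recessive causal variant when ``causal`` is True.
    """
    return HaplotypeBlock(
        chromosome=chromosome,
        start_pos=start_pos,
        snp_spacing=snp_spacing,
        n_snps=2,
        haplotypes=((1, 1), (1, 0), (0, 1), (0, 0)),
        haplotype_freqs=(0.25, 0.25, 0.25, 0.25),
        causal_flag=0 if causal else None,
    )


def unlinked_blocks(
    n_snps: int,
    maf: float | np.ndarray = 0.3,
    chromosome: int = 1,
    start_pos: int = 100_000,
    spacing: int = 50_000,
) -> list[HaplotypeBlock]:
    """Convenience pool of single-SNP blocks, i.e. mutually independent SNPs."""
    mafs = np.broadcast_to(np.asarray(maf, dtype=float), (n_snps,))
    blocks = []
    for k in range(n_snps):
        p = float(mafs[k])
        blocks.append(
            HaplotypeBlock(
                chromosome=chromosome,
                start_pos=start_pos + k * spacing,
                snp_spacing=spacing,
                n_snps=1,
                haplotypes=((1,), (0,)),
                haplotype_freqs=(p, 1.0 - p),
            )
        )
    return blocks


@dataclass
class GenotypeDataset:
    """Sample-by-SNP minor-allele dosage matrix plus SNP map and sample ids.

    ``dosages`` is int8 with values {0,1,2} and ``MISSING`` (-1) for uncalled
    genotypes; it counts minor alleles, where "minor" is fixed per SNP at
    generation (or read) time.  ``snp_map`` has columns snp, chrom, pos
    (1-based).  ``hap_labels`` holds, per block index, the (n_samples, 2)
    haplotype indices actually drawn — simulation truth only, never written
    to disk as genotypes.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: list[str]
    hap_labels: dict[int, np.ndarray] | None = None
    blocks: list[HaplotypeBlock] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.snp_map) != m:
            raise ValueError("snp_map length does not match dosage columns")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or the missing sentinel")
        if self.snp_map["snp"].duplicated().any():
            raise ValueError("SNP identifiers must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        for _, grp in self.snp_map.groupby("chrom"):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError("positions must be strictly increasing within a chromosome")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_index(self, snp: str) -> int:
        idx = self.snp_map.index[self.snp_map["snp"] == snp]
        if len(idx) == 0:
            raise KeyError(f"unknown SNP {snp!r}")
        return int(idx[0])

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeDataset":
        sample_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        hap = None
        if self.hap_labels is not None:
            hap = {b: lab[sample_idx] for b, lab in self.hap_labels.items()}
        return GenotypeDataset(
            dosages=self.dosages[np.ix_(sample_idx, snp_idx)].copy(),
            snp_map=self.snp_map.iloc[snp_idx].reset_index(drop=True),
            sample_ids=[self.sample_ids[i] for i in sample_idx],
            hap_labels=hap,
            blocks=self.blocks,
        )


@dataclass(frozen=True)
class PhenoModelSpec:
    """Generative phenotype model.

    y = sum additive terms + sum 3x3 interaction cell offsets
        + causal_haplotype_effect * 1[homozygous for the flagged haplotype]
        + polygenic score (variance h2/(1-h2) * noise_sd^2 over background SNPs)
        + covariate terms + N(0, noise_sd^2) noise.

    ``causal_haplotype_effect`` is the trait value of affected (flagged-
    haplotype homozygote) individuals relative to the unaffected baseline;
    for the two-SNP showcase block that affected value is 2, which makes the
    single-SNP homozygote marginal mean 0.5.
    """

    marginal_effects: tuple[tuple[int, float], ...] = ()
    interaction_effects: tuple[tuple[int, int, tuple[tuple[float, ...], ...]], ...] = ()
    causal_haplotype_effect: float = 0.0
    polygenic_h2: float = 0.0
    background_snps: tuple[int, ...] = ()
    noise_sd: float = 1.0
    covariate_effects: tuple[float, float, tuple[float, ...]] | None = None
    n_centres: int = 3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.polygenic_h2 < 1:
            raise ValueError("polygenic_h2 must be in [0, 1)")
        if self.polygenic_h2 > 0 and len(self.background_snps) == 0:
            raise ValueError("polygenic_h2 > 0 requires a background SNP set")


@dataclass
class SimulationTruth:
    """Record of the generative parameters of one synthetic study."""

    spec: PhenoModelSpec
    blocks: list[HaplotypeBlock] | None
    seed: int
    realized_variances: dict[str, float] = field(default_factory=dict)


def _check_blocks(blocks: list[HaplotypeBlock]) -> None:
    if len(blocks) == 0:
        raise ValueError("at least one block is required")
    by_chrom: dict[int, list[HaplotypeBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chromosome, []).append(b)
    for chrom, bs in by_chrom.items():
        bs = sorted(bs, key=lambda b: b.start_pos)
        for a, b in zip(bs, bs[1:]):
            if b.start_pos <= a.end_pos:
                raise ValueError(f"blocks overlap on chromosome {chrom} near {b.start_pos}")


def simulate_genotypes(
    blocks: list[HaplotypeBlock],
    n_samples: int,
    seed: int,
    missing_rate: float = 0.0,
) -> GenotypeDataset:
    """Draw ``n_samples`` diplotypes per block under random mating.

    Each individual receives two haplotypes per block, drawn independently
    from the block's pool, so HWE holds at every SNP.  Dosage counts minor
    alleles.  ``missing_rate`` injects missing genotypes completely at
    random (to exercise QC); haplotype truth labels are kept regardless.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    _check_blocks(blocks)

    rng = np.random.default_rng(seed)
    cols = []
    hap_labels: dict[int, np.ndarray] = {}
    rows = []
    order = sorted(range(len(blocks)), key=lambda i: (blocks[i].chromosome, blocks[i].start_pos))
    for bi in order:
        block = blocks[bi]
        hmat = np.asarray(block.haplotypes, dtype=np.int8)
        freqs = np.asarray(block.haplotype_freqs, dtype=float)
        labels = rng.choice(len(freqs), size=(n_samples, 2), p=freqs / freqs.sum())
        hap_labels[bi] = labels
        cols.append(hmat[labels[:, 0]] + hmat[labels[:, 1]])
        for k, pos in enumerate(block.positions):
            rows.append((f"snp_c{block.chromosome}_{int(pos)}", block.chromosome, int(pos)))
    dosages = np.concatenate(cols, axis=1).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = MISSING
    snp_map = pd.DataFrame(rows, columns=["snp", "chrom", "pos"])
    sample_ids = [f"ind{i:06d}" for i in range(n_samples)]
    return GenotypeDataset(
        dosages=dosages,
        snp_map=snp_map,
        sample_ids=sample_ids,
        hap_labels=hap_labels,
        blocks=[blocks[i] for i in order],
    )


def _interaction_offsets(y, dos_i, dos_j, table) -> None:
    tab = np.asarray(table, dtype=float)
    if tab.shape != (3, 3):
        raise ValueError("interaction effect table must be 3x3")
    ok = (dos_i != MISSING) & (dos_j != MISSING)
    y[ok] += tab[dos_i[ok], dos_j[ok]]


def simulate_phenotype(
    geno: GenotypeDataset,
    spec: PhenoModelSpec,
    seed: int,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate a phenotype table (trait + covariates) for ``geno``.

    Returns the phenotype/covariate table (sample_id, trait, sex, age,
    centre) and the SimulationTruth with realized variance components.
    Missing dosages contribute 0 to genetic effect terms.
    """
    rng = np.random.default_rng(seed)
    n = geno.n_samples
    y = np.zeros(n)
    realized: dict[str, float] = {}

    dos = geno.dosages.astype(float)
    dos[geno.dosages == MISSING] = 0.0

    for idx, beta in spec.marginal_effects:
        if not 0 <= idx < geno.n_snps:
            raise ValueError(f"marginal effect SNP index {idx} out of range")
        y += beta * dos[:, idx]

    for i, j, table in spec.interaction_effects:
        if not (0 <= i < geno.n_snps and 0 <= j < geno.n_snps):
            raise ValueError("interaction effect SNP index out of range")
        _interaction_offsets(y, geno.dosages[:, i], geno.dosages[:, j], table)

    if spec.causal_haplotype_effect != 0.0:
        flagged = [
            (bi, b) for bi, b in enumerate(geno.blocks or []) if b.causal_flag is not None
        ]
        if not flagged or geno.hap_labels is None:
            raise ValueError(
                "causal_haplotype_effect requested but no block carries a causal_flag"
            )
        for bi, block in flagged:
            lab = geno.hap_labels[bi]
            hom = (lab[:, 0] == block.causal_flag) & (lab[:, 1] == block.causal_flag)
            y += spec.causal_haplotype_effect * hom
            realized[f"causal_hom_freq_block{bi}"] = float(hom.mean())

    if spec.polygenic_h2 > 0:
        bg = np.asarray(spec.background_snps, dtype=int)
        if bg.min() < 0 or bg.max() >= geno.n_snps:
            raise ValueError("background SNP index out of range")
        effects = rng.standard_normal(len(bg))
        score = dos[:, bg] @ effects
        sd = score.std()
        if sd == 0:
            raise ValueError("polygenic background score has zero variance")
        target_var = spec.polygenic_h2 / (1.0 - spec.polygenic_h2) * spec.noise_sd**2
        score = (score - score.mean()) / sd * np.sqrt(target_var)
        y += score
        realized["polygenic_var"] = float(score.var())

    sex = rng.integers(0, 2, size=n)
    age = rng.normal(50.0, 5.0, size=n)
    centre = rng.integers(0, spec.n_centres, size=n)
    if spec.covariate_effects is not None:
        b_sex, b_age, centre_off = spec.covariate_effects
        off = np.asarray(centre_off, dtype=float)
        if len(off) != spec.n_centres:
            raise ValueError("centre offsets must have length n_centres")
        y += b_sex * sex + b_age * age + off[centre]

    noise = spec.noise_sd * rng.standard_normal(n)
    realized["noise_var"] = float(noise.var())
    realized["genetic_plus_fixed_var"] = float(y.var())
    y = y + noise

    pheno = pd.DataFrame(
        {
            "sample_id": geno.sample_ids,
            "trait": y,
            "sex": sex,
            "age": age,
            "centre": centre,
        }
    )
    truth = SimulationTruth(
        spec=spec, blocks=geno.blocks, seed=seed, realized_variances=realized
    )
    return pheno, truth
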