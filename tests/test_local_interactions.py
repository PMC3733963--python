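"""Local-pair extraction, composite LD, window thresholds, conditioning."""

import numpy as np
import pytest

from locepi.epistasis_scan import InteractionResult
from locepi.local_interactions import (
    composite_r2,
    conditional_interaction_test,
    extract_local,
    region_conditional_sweep,
    window_bonferroni,
    window_permutation_threshold,
)
from locepi.synthetic_data import (
    MISSING,
    GenotypeDataset,
    HaplotypeBlock,
    PhenoModelSpec,
    fig2_block,
    simulate_genotypes,
    simulate_phenotype,
    unlinked_blocks,
)


def _result(snp_i, snp_j, p):
    return InteractionResult(snp_i=snp_i, snp_j=snp_j, p_int=p, f_stat=1.0,
                             df_int=4, df_res=10, n=20)


def _toy_geno():
    """6 SNPs at controlled positions on two chromosomes."""
    import pandas as pd

    rng = np.random.default_rng(0)
    snp_map = pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(6)],
            "chrom": [1, 1, 1, 1, 2, 2],
            "pos": [100, 1_000_099, 1_000_100, 2_500_000, 100, 600_000],
        }
    )
    dosages = rng.integers(0, 3, size=(50, 6)).astype(np.int8)
    return GenotypeDataset(dosages=dosages, snp_map=snp_map,
                           sample_ids=[f"i{k}" for k in range(50)])


class TestExtractLocal:
    def test_distance_and_chromosome_boundaries(self):
        geno = _toy_geno()
        results = [
            _result("s0", "s1", 1e-6),   # distance 999,999 -> kept
            _result("s0", "s2", 1e-6),   # distance 1,000,000 -> dropped (strict <)
            _result("s0", "s4", 1e-6),   # different chromosomes -> dropped
        ]
        kept = extract_local(results, geno)
        assert [(lp.result.snp_i, lp.result.snp_j) for lp in kept] == [("s0", "s1")]
        assert kept[0].distance == 999_999

    def test_p_value_boundary_strict(self):
        geno = _toy_geno()
        assert extract_local([_result("s0", "s1", 1e-5)], geno) == []
        assert len(extract_local([_result("s0", "s1", 9.99e-6)], geno)) == 1

    def test_hand_counted_mixture(self):
        geno = _toy_geno()
        results = [
            _result("s0", "s1", 1e-6),    # local
            _result("s1", "s2", 1e-7),    # local (distance 1)
            _result("s2", "s3", 1e-6),    # distance 1.5 Mb -> no
            _result("s4", "s5", 1e-8),    # local on chrom 2
            _result("s4", "s5", 1e-4),    # fails P rule
            _result("s0", "s4", 1e-9),    # cross-chromosome
            _result("s0", "s2", 1e-6),    # distance exactly 1 Mb -> no
            _result("s0", "s3", 1e-6),    # too far
            _result("s1", "s3", 1e-3),    # fails both
            _result("s2", "s3", 2e-6),    # too far
        ]
        assert len(extract_local(results, geno)) == 3

    def test_idempotent_and_subset(self, null_panel):
        geno, y = null_panel
        from locepi.epistasis_scan import pairwise_scan

        results, _ = pairwise_scan(y, geno, retain=1e-3)
        local = extract_local(results, geno, p_cut=1e-3)
        names = {(lp.result.snp_i, lp.result.snp_j) for lp in local}
        assert names <= {(r.snp_i, r.snp_j) for r in results}
        again = extract_local([lp.result for lp in local], geno, p_cut=1e-3)
        assert len(again) == len(local)


class TestCompositeR2:
    def test_identical_vectors(self):
        g = np.array([0, 1, 2, 0, 1, 2], dtype=np.int8)
        assert composite_r2(g, g) == pytest.approx(1.0)

    def test_hand_computable_zero(self):
        a = np.array([0, 1, 2, 0, 1, 2], dtype=np.int8)
        b = np.array([0, 1, 2, 2, 1, 0], dtype=np.int8)
        assert composite_r2(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_independent_snps_near_zero(self):
        geno = simulate_genotypes(unlinked_blocks(2, maf=0.5), 100_000, seed=1)
        assert composite_r2(geno.dosages[:, 0], geno.dosages[:, 1]) < 0.001

    def test_two_haplotype_pool_gives_unit_r2(self):
        # only ab and AB haplotypes -> the two SNPs are perfect copies
        block = HaplotypeBlock(
            chromosome=1, start_pos=100, snp_spacing=50, n_snps=2,
            haplotypes=((1, 1), (0, 0)), haplotype_freqs=(0.5, 0.5),
        )
        geno = simulate_genotypes([block], 5000, seed=2)
        assert composite_r2(geno.dosages[:, 0], geno.dosages[:, 1]) == pytest.approx(1.0)

    def test_symmetry_and_allele_flip_invariance(self):
        geno = simulate_genotypes([fig2_block()], 500, seed=3)
        a, b = geno.dosages[:, 0], geno.dosages[:, 1]
        r = composite_r2(a, b)
        assert composite_r2(b, a) == pytest.approx(r, abs=1e-15)
        assert composite_r2(2 - a, b) == pytest.approx(r, abs=1e-15)

    def test_constant_vector_undefined(self):
        assert np.isnan(composite_r2(np.zeros(10, dtype=np.int8),
                                     np.array([0, 1, 2] * 3 + [1], dtype=np.int8)))


def _ld_block(n_snps, flip_rate, chromosome=1, start=100_000, seed=0):
    """Haplotype pool derived from two complementary founders with per-SNP
    flips; lower flip_rate => higher within-block LD."""
    rng = np.random.default_rng(seed)
    haps = []
    for k in range(24):
        base = k % 2
        hap = np.full(n_snps, base, dtype=int)
        flips = rng.random(n_snps) < flip_rate
        hap[flips] = 1 - hap[flips]
        haps.append(tuple(hap))
    return HaplotypeBlock(
        chromosome=chromosome, start_pos=start, snp_spacing=1000, n_snps=n_snps,
        haplotypes=tuple(haps), haplotype_freqs=(1 / 24,) * 24,
    )


class TestWindowPermutationThreshold:
    def test_independent_snps_near_sidak_limit(self):
        geno = simulate_genotypes(unlinked_blocks(150, maf=0.3), 500, seed=4)
        y = np.random.default_rng(5).standard_normal(500)
        wt = window_permutation_threshold(y, geno, window=41, perms=100,
                                          windows=10, seed=6)
        sidak = 1 - 0.95 ** (1 / 820)
        bonf = window_bonferroni(41)
        assert bonf / 2 < wt.threshold < 2 * bonf
        assert wt.threshold == pytest.approx(sidak, rel=1.0)

    def test_threshold_monotone_in_ld(self):
        """Higher within-window LD => fewer effective tests => larger threshold."""
        y = np.random.default_rng(7).standard_normal(400)
        thresholds = []
        for flip in (0.45, 0.12, 0.02):
            geno = simulate_genotypes([_ld_block(41, flip, seed=8)], 400, seed=9)
            wt = window_permutation_threshold(y, geno, window=41, perms=100,
                                              windows=4, seed=10)
            thresholds.append(wt.threshold)
        assert thresholds[0] < thresholds[1] < thresholds[2]
        # near-duplicate limit: effective tests ~ few => far above Bonferroni
        assert thresholds[2] > 10 * window_bonferroni(41)

    def test_fixed_seed_bit_identical(self):
        geno = simulate_genotypes(unlinked_blocks(60, maf=0.3), 200, seed=11)
        y = np.random.default_rng(12).standard_normal(200)
        a = window_permutation_threshold(y, geno, window=21, perms=50, windows=3, seed=13)
        b = window_permutation_threshold(y, geno, window=21, perms=50, windows=3, seed=13)
        assert a.threshold == b.threshold
        assert a.per_window == b.per_window

    def test_genome_too_small_errors(self):
        geno = simulate_genotypes(unlinked_blocks(10, maf=0.3), 50, seed=14)
        with pytest.raises(ValueError, match="consecutive"):
            window_permutation_threshold(np.zeros(50), geno, window=41)


class TestConditionalInteractionTest:
    def test_haplotype_recessive_signal_absorbed_by_causal_snp(self):
        """Pair SNPs tag a recessive causal SNP between them: conditioning on
        the causal genotype removes the apparent interaction."""
        cleared = 0
        for rep in range(20):
            geno = simulate_genotypes([_ld_block(3, 0.12, seed=100 + rep)],
                                      2000, seed=200 + rep)
            d = geno.dosages
            y = 2.0 * (d[:, 1] == 2) + np.random.default_rng(300 + rep).standard_normal(2000)
            r = conditional_interaction_test(y, d[:, 0], d[:, 2], d[:, 1])
            cleared += r.p_int > 0.05
        assert cleared >= 18

    def test_genuine_interaction_survives_independent_background(self):
        survived = 0
        for rep in range(20):
            geno = simulate_genotypes(unlinked_blocks(3, maf=0.5), 2000,
                                      seed=400 + rep)
            tab = np.zeros((3, 3)); tab[2, 2] = 1.5
            spec = PhenoModelSpec(
                interaction_effects=((0, 1, tuple(map(tuple, tab))),), noise_sd=1.0
            )
            pheno, _ = simulate_phenotype(geno, spec, seed=500 + rep)
            d = geno.dosages
            r = conditional_interaction_test(
                pheno["trait"].to_numpy(), d[:, 0], d[:, 1], d[:, 2]
            )
            survived += r.p_int < 1e-2
        assert survived >= 18

    def test_collinear_background_flagged(self):
        geno = simulate_genotypes(unlinked_blocks(2, maf=0.4), 200, seed=15)
        d = geno.dosages
        y = np.random.default_rng(16).standard_normal(200)
        r = conditional_interaction_test(y, d[:, 0], d[:, 1], d[:, 0].copy())
        assert r.flag == "collinear_background" and r.p_int == 1.0

    def test_null_background_changes_p_little_on_average(self):
        """A background with no explanatory value shifts log10 P_int by < 1
        on average over planted-interaction replicates."""
        shifts = []
        for rep in range(20):
            geno = simulate_genotypes(unlinked_blocks(3, maf=0.5), 1500,
                                      seed=600 + rep)
            tab = np.zeros((3, 3)); tab[2, 2] = 1.0
            spec = PhenoModelSpec(
                interaction_effects=((0, 1, tuple(map(tuple, tab))),), noise_sd=1.0
            )
            pheno, _ = simulate_phenotype(geno, spec, seed=700 + rep)
            d = geno.dosages
            y = pheno["trait"].to_numpy()
            from locepi.epistasis_scan import interaction_test

            p0 = interaction_test(y, d[:, 0], d[:, 1]).p_int
            p1 = conditional_interaction_test(y, d[:, 0], d[:, 1], d[:, 2]).p_int
            shifts.append(abs(np.log10(p1) - np.log10(p0)))
        assert np.mean(shifts) < 1.0


class TestRegionConditionalSweep:
    def test_explained_and_independent_pairs_classified(self):
        # region: LD triplet (apparent pair around recessive causal SNP m0)
        # plus two unlinked SNPs with a genuine interaction, plus a null SNP
        blocks = [_ld_block(3, 0.12, chromosome=5, start=1_000_000, seed=17)]
        blocks += unlinked_blocks(3, maf=0.5, chromosome=5, start_pos=2_000_000,
                                  spacing=100_000)
        geno = simulate_genotypes(blocks, 3000, seed=18)
        d = geno.dosages
        rng = np.random.default_rng(19)
        y = 2.0 * (d[:, 1] == 2) + 2.0 * ((d[:, 3] == 2) & (d[:, 4] == 2))
        y = y + rng.standard_normal(3000)
        snps = geno.snp_map["snp"].tolist()
        sweep = region_conditional_sweep(
            y, geno,
            pairs_in_region=[(snps[0], snps[2]), (snps[3], snps[4])],
            marginal_snps_in_region=[snps[1], snps[5]],
        )
        cls = sweep.groupby(["snp_i", "snp_j"])["class"].first()
        assert cls[(snps[0], snps[2])] == "explained"
        assert cls[(snps[3], snps[4])] == "independent"

    def test_empty_region_empty_table(self):
        geno = simulate_genotypes(unlinked_blocks(3), 50, seed=20)
        sweep = region_conditional_sweep(np.zeros(50), geno, [], [])
        assert len(sweep) == 0

    def test_pair_member_background_skipped(self):
        geno = simulate_genotypes(unlinked_blocks(2, maf=0.4), 300, seed=21)
        y = np.random.default_rng(22).standard_normal(300)
        snps = geno.snp_map["snp"].tolist()
        sweep = region_conditional_sweep(
            y, geno, [(snps[0], snps[1])], marginal_snps_in_region=[snps[0]]
        )
        assert len(sweep) == 0
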