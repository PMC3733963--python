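"""SNP-level and region-level replication of epistatic pairs.

Exact replication of an interacting SNP pair in an independent cohort is
rarely possible: the discovery SNPs may not be genotyped there and LD
patterns differ.  The region-level protocol therefore tests every
cross-locus combination of small SNP neighbourhoods around the two
discovery loci (the focal or proxy SNP plus up to five SNPs on each side),
takes the best (lowest-P_int) replicate pair, and judges it against a 5%
threshold derived by permuting the replication phenotype and recording the
grid minimum each time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._anova import PairPermEngine, pair_anova
from .synthetic_data import GenotypeDataset

__all__ = ["ReplicationResult", "find_proxy", "snp_level_replication", "region_replication"]


@dataclass
class ReplicationResult:
    discovery_pair: tuple[str, str]
    proxy_pair: tuple[str, str]
    best_pair: tuple[str, str]
    best_p_int: float
    perm_threshold: float
    n_grid_pairs: int
    verdict: str  # region_level_replicated | nominal_only | not_replicated


def find_proxy(snp: str, chromosome: int, position: int, replication_map) -> str:
    """Nearest genotyped SNP on the same chromosome (ties -> lower position).

    ``replication_map`` is a snp_map DataFrame (snp, chrom, pos).  If the
    SNP itself is genotyped it is its own proxy.
    """
    cand = replication_map[replication_map["chrom"] == chromosome]
    if len(cand) == 0:
        raise ValueError(f"no replication SNPs on chromosome {chromosome}")
    exact = cand[cand["snp"] == snp]
    if len(exact) > 0:
        return snp
    dist = (cand["pos"] - position).abs()
    best = dist.min()
    tied = cand[dist == best].sort_values("pos")
    return str(tied["snp"].iloc[0])


def snp_level_replication(
    pair: tuple[str, str],
    residuals: np.ndarray,
    replication_geno: GenotypeDataset,
    alpha: float = 0.05,
) -> tuple[float, str]:
    """Direct interaction test of the exact pair in the replication data.

    Only possible when both SNPs are genotyped there; significant when
    P_int < alpha (5% nominal).
    """
    i = replication_geno.snp_index(pair[0])
    j = replication_geno.snp_index(pair[1])
    r = pair_anova(residuals, replication_geno.dosages[:, i], replication_geno.dosages[:, j])
    verdict = "snp_level_replicated" if r["p"] < alpha else "not_replicated"
    return float(r["p"]), verdict


def _locus_window(geno: GenotypeDataset, snp: str, flank: int) -> np.ndarray:
    """Indices of the focal SNP plus up to ``flank`` SNPs each side, same chromosome."""
    idx = geno.snp_index(snp)
    chrom = geno.snp_map["chrom"].iloc[idx]
    same = np.nonzero((geno.snp_map["chrom"] == chrom).to_numpy())[0]
    k = int(np.nonzero(same == idx)[0][0])
    return same[max(k - flank, 0) : k + flank + 1]


def region_replication(
    discovery_pair: tuple[str, str],
    discovery_positions: tuple[tuple[int, int], tuple[int, int]],
    residuals: np.ndarray,
    replication_geno: GenotypeDataset,
    flank: int = 5,
    perms: int = 1000,
    seed: int = 0,
    nominal_alpha: float = 0.05,
) -> ReplicationResult:
    """Region-level replication test of one discovery pair.

    ``discovery_positions`` gives (chromosome, position) per discovery SNP
    so proxies can be resolved when a SNP is absent from the replication
    panel.  The candidate grid is (locus-1 window) x (locus-2 window),
    cross-locus pairs only, truncated at chromosome ends; the observed
    best pair is the grid minimum of P_int (independent of the permutation
    seed), and the permutation threshold is the 5th percentile of the
    1000 per-permutation grid minima.
    """
    proxies = tuple(
        find_proxy(s, c, p, replication_geno.snp_map)
        for s, (c, p) in zip(discovery_pair, discovery_positions)
    )
    win1 = _locus_window(replication_geno, proxies[0], flank)
    win2 = _locus_window(replication_geno, proxies[1], flank)
    if np.intersect1d(win1, win2).size > 0:
        raise ValueError("locus windows overlap; loci are not separable at this flank")

    cols = np.concatenate([win1, win2])
    sub = replication_geno.dosages[:, cols]
    n1 = len(win1)
    pairs = [(a, n1 + b) for a in range(n1) for b in range(len(win2))]
    engine = PairPermEngine(sub, pairs)

    y = np.asarray(residuals, dtype=float)
    obs = engine.pvalues(y[:, None])[:, 0]
    best_k = int(np.argmin(obs))
    best_p = float(obs[best_k])
    snps = replication_geno.snp_map["snp"].to_numpy()
    best_pair = (snps[cols[pairs[best_k][0]]], snps[cols[pairs[best_k][1]]])

    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((perms, len(y))), axis=1)
    pmat = engine.pvalues(y[perm_idx].T)
    minima = pmat.min(axis=0)
    threshold = float(np.percentile(minima, 5.0))

    if best_p <= threshold:
        verdict = "region_level_replicated"
    elif best_p <= nominal_alpha:
        verdict = "nominal_only"
    else:
        verdict = "not_replicated"
    return ReplicationResult(
        discovery_pair=tuple(discovery_pair),
        proxy_pair=proxies,
        best_pair=best_pair,
        best_p_int=best_p,
        perm_threshold=threshold,
        n_grid_pairs=len(pairs),
        verdict=verdict,
    )
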