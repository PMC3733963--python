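"""Exhaustive pairwise interaction scan with combined-search thresholds.

Every i<j SNP pair is tested with the genotype-class ANOVA interaction
F-test (see :mod:`locepi._anova`); pairs with P_int below a retention
threshold (default 1e-5) are kept.  Significance uses the combined-search
Bonferroni thresholds: with N SNPs of which K are marginal (single-SNP
P <= 5e-8),

    t_full     = 0.05 / (N (N-1) / 2 - (N-1) K)   for pairs with no marginal SNP
    t_marginal = 0.05 / ((N-1) K)                 for pairs involving one

so pairs touching a marginal SNP are judged against a much more permissive
threshold while the overall 5% genome-wide error rate is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _anova
from .synthetic_data import GenotypeDataset

__all__ = [
    "InteractionResult",
    "ThresholdSet",
    "interaction_test",
    "pairwise_scan",
    "bonferroni_full",
    "bonferroni_marginal",
    "build_thresholds",
    "classify_significance",
    "results_to_frame",
]

RETAIN_P = 1e-5  # default retention threshold for scanned pairs


@dataclass
class InteractionResult:
    """One tested SNP pair."""

    snp_i: str
    snp_j: str
    p_int: float
    f_stat: float
    df_int: int
    df_res: int
    n: int
    cell_counts: np.ndarray = field(default_factory=lambda: np.zeros((3, 3), dtype=int))
    cell_means: np.ndarray = field(default_factory=lambda: np.full((3, 3), np.nan))
    marginal_involved: bool = False
    flag: str = ""


@dataclass(frozen=True)
class ThresholdSet:
    """Scan significance thresholds with their derivation parameters."""

    n_snps: int
    k_marginal: int
    t_full: float
    t_marginal: float
    t_retain: float = RETAIN_P
    gwas_consensus: float = 5e-8

    def __post_init__(self) -> None:
        if not 0 < self.t_full < 1:
            raise ValueError("t_full must be in (0, 1)")
        if np.isfinite(self.t_marginal) and not 0 < self.t_marginal < 1:
            raise ValueError("t_marginal must be in (0, 1)")
        if (
            self.n_snps > self.k_marginal + 1
            and np.isfinite(self.t_marginal)
            and self.t_full > self.t_marginal
        ):
            raise ValueError("t_full must not exceed t_marginal")


def bonferroni_full(n_snps: int, k_marginal: int) -> float:
    """5% genome-wide threshold for the full pairwise scan.

    0.05 / (N (N-1) / 2 - (N-1) K): the Bonferroni correction over all
    pairs not involving a marginal SNP.
    """
    n, k = int(n_snps), int(k_marginal)
    denom = n * (n - 1) / 2 - (n - 1) * k
    if denom <= 0:
        raise ValueError("no non-marginal pairs to correct for (K too large)")
    return 0.05 / denom


def bonferroni_marginal(n_snps: int, k_marginal: int) -> float:
    """5% threshold for interactions involving at least one marginal SNP.

    0.05 / ((N-1) K); undefined (inf) when K = 0.
    """
    n, k = int(n_snps), int(k_marginal)
    if k <= 0:
        return float("inf")
    return 0.05 / ((n - 1) * k)


def build_thresholds(n_snps: int, k_marginal: int, retain: float = RETAIN_P) -> ThresholdSet:
    return ThresholdSet(
        n_snps=int(n_snps),
        k_marginal=int(k_marginal),
        t_full=bonferroni_full(n_snps, k_marginal),
        t_marginal=bonferroni_marginal(n_snps, k_marginal),
        t_retain=retain,
    )


def interaction_test(residuals: np.ndarray, g_i: np.ndarray, g_j: np.ndarray) -> InteractionResult:
    """Genotype-class interaction F-test for one pair of dosage vectors.

    Symmetric in the two SNPs.  Untestable configurations (monomorphic
    SNP, no interaction degrees of freedom) return P = 1 with a flag;
    a saturated fit (zero full-model residual with positive interaction
    sum of squares) returns the smallest positive P, flagged "saturated".
    """
    r = _anova.pair_anova(residuals, g_i, g_j)
    return InteractionResult(
        snp_i="snp_i",
        snp_j="snp_j",
        p_int=r["p"],
        f_stat=r["f"],
        df_int=r["df_int"],
        df_res=r["df_res"],
        n=r["n"],
        cell_counts=r["counts"],
        cell_means=r["means"],
        flag=r["flag"],
    )


def pairwise_scan(
    residuals: np.ndarray,
    geno: GenotypeDataset,
    marginal_snps: set[str] | None = None,
    retain: float = RETAIN_P,
) -> tuple[list[InteractionResult], ThresholdSet]:
    """Full N(N-1)/2 interaction scan; returns retained pairs + thresholds.

    Pairs with P_int < ``retain`` are returned, each flagged by whether
    either SNP is in the marginal set, ordered by (P_int, i, j).
    """
    marginal_snps = marginal_snps or set()
    if geno.n_snps < 2:
        raise ValueError("need at least 2 SNPs to scan")
    scan = _anova.all_pairs_scan(residuals, geno.dosages)
    thresholds = build_thresholds(geno.n_snps, len(marginal_snps), retain=retain)
    snps = geno.snp_map["snp"].to_numpy()

    hits = np.nonzero(scan["p"] < retain)[0]
    order = hits[np.lexsort((scan["jj"][hits], scan["ii"][hits], scan["p"][hits]))]
    results = []
    for k in order:
        i, j = int(scan["ii"][k]), int(scan["jj"][k])
        exact = _anova.pair_anova(residuals, geno.dosages[:, i], geno.dosages[:, j])
        results.append(
            InteractionResult(
                snp_i=snps[i],
                snp_j=snps[j],
                p_int=float(scan["p"][k]),
                f_stat=float(scan["f"][k]),
                df_int=int(scan["df_int"][k]),
                df_res=int(scan["df_res"][k]),
                n=int(scan["n"][k]),
                cell_counts=exact["counts"],
                cell_means=exact["means"],
                marginal_involved=(snps[i] in marginal_snps) or (snps[j] in marginal_snps),
                flag="saturated" if scan["saturated"][k] else "",
            )
        )
    return results, thresholds


def classify_significance(result: InteractionResult, thresholds: ThresholdSet) -> str:
    """Combined-search class of one retained pair.

    Pairs involving a marginal SNP are judged against t_marginal, others
    against t_full; the boundary counts as significant (<=).  "suggestive"
    is within one order of magnitude above the applicable threshold.
    """
    t = thresholds.t_marginal if (result.marginal_involved and thresholds.k_marginal > 0) else thresholds.t_full
    if result.p_int <= t:
        return "significant_marginal" if result.marginal_involved else "significant_full"
    if result.p_int <= 10.0 * t:
        return "suggestive"
    return "retained"


def results_to_frame(
    results: list[InteractionResult],
    geno: GenotypeDataset,
    thresholds: ThresholdSet | None = None,
) -> pd.DataFrame:
    """Flatten scan results to the TSV layout (one row per pair)."""
    lookup = geno.snp_map.set_index("snp")
    rows = []
    for r in results:
        row = {
            "snp_i": r.snp_i,
            "snp_j": r.snp_j,
            "chr_i": lookup.loc[r.snp_i, "chrom"],
            "pos_i": lookup.loc[r.snp_i, "pos"],
            "chr_j": lookup.loc[r.snp_j, "chrom"],
            "pos_j": lookup.loc[r.snp_j, "pos"],
            "n": r.n,
            "f": r.f_stat,
            "df1": r.df_int,
            "df2": r.df_res,
            "p_int": r.p_int,
            "marginal_involved": r.marginal_involved,
            "flag": r.flag,
        }
        if thresholds is not None:
            row["class"] = classify_significance(r, thresholds)
        rows.append(row)
    return pd.DataFrame(rows)
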