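"""Local interactions: extraction, LD, permutation thresholds, conditioning.

A *local* interaction is a retained pair (P_int < 1e-5) whose SNPs sit on
the same chromosome less than 1 Mb apart.  Because local pairs live inside
regions whose LD structure varies across the genome, a dedicated
permutation threshold is derived from fixed-size SNP windows (41 SNPs: a
random centre plus 20 each side); it is reported as a diagnostic alongside
the Bonferroni value 0.05/820, while the retention threshold 1e-5 remains
the filter actually applied.

Conditional interaction tests ask whether a marginal SNP's signal explains
a local interaction: the background SNP enters both compared models as a
3-level genotype factor, so that recessive single-locus signals tagged by
a haplotype can be absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._anova import P_SATURATED, PairPermEngine
from .epistasis_scan import InteractionResult
from .synthetic_data import MISSING, GenotypeDataset

__all__ = [
    "LOCAL_MAX_DIST",
    "LocalPair",
    "WindowThreshold",
    "composite_r2",
    "extract_local",
    "window_bonferroni",
    "window_permutation_threshold",
    "conditional_interaction_test",
    "region_conditional_sweep",
    "local_pairs_to_frame",
]

LOCAL_MAX_DIST = 1_000_000  # base pairs; strict upper bound for "local"


@dataclass
class LocalPair:
    """A retained interaction that qualifies as local."""

    result: InteractionResult
    chromosome: int
    distance: int
    r2: float


@dataclass(frozen=True)
class WindowThreshold:
    """Permutation-derived local-interaction threshold and its provenance."""

    threshold: float
    per_window: tuple[float, ...]
    window_size_snps: int
    n_permutations: int
    n_windows: int
    seed: int


def composite_r2(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """Composite LD r^2: squared dosage correlation over shared samples.

    Needs no haplotype phase and is robust to Hardy-Weinberg deviations.
    Returns NaN when either vector is constant among jointly called samples.
    """
    gi = np.asarray(g_i)
    gj = np.asarray(g_j)
    mask = (gi != MISSING) & (gj != MISSING)
    a = gi[mask].astype(float)
    b = gj[mask].astype(float)
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def extract_local(
    results: list[InteractionResult],
    geno: GenotypeDataset,
    max_dist: int = LOCAL_MAX_DIST,
    p_cut: float = 1e-5,
) -> list[LocalPair]:
    """Filter retained pairs to local ones and attach distance and LD r^2.

    Both rules are strict: same chromosome, distance < max_dist and
    P_int < p_cut.  Idempotent; an empty result is valid.
    """
    lookup = geno.snp_map.set_index("snp")
    out = []
    for r in results:
        ci, pi = lookup.loc[r.snp_i, ["chrom", "pos"]]
        cj, pj = lookup.loc[r.snp_j, ["chrom", "pos"]]
        if ci != cj:
            continue
        dist = int(abs(int(pj) - int(pi)))
        if dist >= max_dist or not r.p_int < p_cut:
            continue
        r2 = composite_r2(
            geno.dosages[:, geno.snp_index(r.snp_i)],
            geno.dosages[:, geno.snp_index(r.snp_j)],
        )
        out.append(LocalPair(result=r, chromosome=int(ci), distance=dist, r2=r2))
    return out


def window_bonferroni(window_size: int = 41) -> float:
    """Bonferroni 5% threshold for all pairs within one SNP window."""
    return 0.05 / (window_size * (window_size - 1) / 2)


def window_permutation_threshold(
    residuals: np.ndarray,
    geno: GenotypeDataset,
    window: int = 41,
    perms: int = 100,
    windows: int = 200,
    seed: int = 0,
) -> WindowThreshold:
    """Permutation threshold for local interactions from random SNP windows.

    For each of ``windows`` randomly sampled centre SNPs (needing
    (window-1)/2 SNPs on both sides on the same chromosome), the phenotype
    is permuted ``perms`` times, all pairwise interactions within the
    window are tested per permutation, and the per-window 5% point of the
    per-permutation minimum P_int is recorded; the threshold is the mean
    of the per-window 5% points.  One phenotype permutation is shared by
    all pairs of a window, preserving the within-window LD structure.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    flank = (window - 1) // 2
    chrom = geno.snp_map["chrom"].to_numpy()
    eligible = []
    for c in np.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        if len(idx) >= window:
            eligible.extend(idx[flank : len(idx) - flank])
    if not eligible:
        raise ValueError(f"no chromosome has {window} consecutive SNPs")
    rng = np.random.default_rng(seed)
    eligible = np.asarray(eligible)
    centres = rng.choice(eligible, size=windows, replace=len(eligible) < windows)

    y = np.asarray(residuals, dtype=float)
    n = len(y)
    per_window = []
    for centre in centres:
        cols = np.arange(centre - flank, centre + flank + 1)
        pairs = [(a, b) for a in range(window) for b in range(a + 1, window)]
        engine = PairPermEngine(geno.dosages[:, cols], pairs)
        perm_idx = np.argsort(rng.random((perms, n)), axis=1)
        y_mat = y[perm_idx].T  # (n, perms)
        pmat = engine.pvalues(y_mat)
        minima = pmat.min(axis=0)
        per_window.append(float(np.percentile(minima, 5.0)))
    return WindowThreshold(
        threshold=float(np.mean(per_window)),
        per_window=tuple(per_window),
        window_size_snps=window,
        n_permutations=perms,
        n_windows=windows,
        seed=seed,
    )


def _factor_dummies(g: np.ndarray) -> np.ndarray:
    """3-level genotype factor dummies (reference = first observed level)."""
    levels = np.unique(g)
    return np.column_stack([(g == lv).astype(float) for lv in levels[1:]]) if len(levels) > 1 else np.zeros((len(g), 0))


def conditional_interaction_test(
    residuals: np.ndarray,
    g_i: np.ndarray,
    g_j: np.ndarray,
    g_background: np.ndarray,
) -> InteractionResult:
    """Interaction test with a background SNP factor in both models.

    Reduced model: mean + SNP-i factor + SNP-j factor + background factor;
    full model: free mean per non-empty (i, j) cell + background factor.
    A background in perfect LD with either pair SNP is flagged collinear
    and returns P = 1.
    """
    y = np.asarray(residuals, dtype=float)
    gi, gj, gb = (np.asarray(v) for v in (g_i, g_j, g_background))
    mask = (gi != MISSING) & (gj != MISSING) & (gb != MISSING) & np.isfinite(y)
    yv = y[mask]
    giv, gjv, gbv = gi[mask], gj[mask], gb[mask]
    n = len(yv)

    res = InteractionResult(
        snp_i="snp_i", snp_j="snp_j", p_int=1.0, f_stat=np.nan,
        df_int=0, df_res=0, n=n,
    )
    r2i = composite_r2(gbv, giv)
    r2j = composite_r2(gbv, gjv)
    if (np.isfinite(r2i) and r2i > 1 - 1e-12) or (np.isfinite(r2j) and r2j > 1 - 1e-12):
        res.flag = "collinear_background"
        return res

    labels = 3 * giv.astype(np.intp) + gjv.astype(np.intp)
    cells = np.unique(labels)
    cell_dum = np.column_stack([(labels == c).astype(float) for c in cells])
    bg_dum = _factor_dummies(gbv)
    x_full = np.column_stack([cell_dum, bg_dum])
    x_red = np.column_stack(
        [np.ones(n), _factor_dummies(giv), _factor_dummies(gjv), bg_dum]
    )

    def _fit(x):
        beta, rss, rank, _ = np.linalg.lstsq(x, yv, rcond=None)
        fitted = x @ beta
        return float(np.sum((yv - fitted) ** 2)), int(np.linalg.matrix_rank(x))

    rss_full, rank_full = _fit(x_full)
    rss_red, rank_red = _fit(x_red)
    df_int = rank_full - rank_red
    df_res = n - rank_full
    res.df_int, res.df_res = df_int, df_res
    if df_int < 1 or df_res < 1:
        res.flag = "untestable"
        return res
    ss_int = max(rss_red - rss_full, 0.0)
    scale = max(float(yv @ yv), 1.0)
    if rss_full <= 1e-12 * scale:
        if ss_int > 1e-12 * scale:
            res.f_stat, res.p_int, res.flag = np.inf, P_SATURATED, "saturated"
        return res
    f = (ss_int / df_int) / (rss_full / df_res)
    res.f_stat = float(f)
    res.p_int = float(stats.f.sf(f, df_int, df_res))
    return res


def region_conditional_sweep(
    residuals: np.ndarray,
    geno: GenotypeDataset,
    pairs_in_region: list[tuple[str, str]],
    marginal_snps_in_region: list[str],
    explained_p: float = 0.05,
    independent_p: float = 1e-2,
) -> pd.DataFrame:
    """Condition every regional pair on every regional marginal SNP.

    A pair is "explained" if some background lifts its conditional P_int
    above ``explained_p`` (the marginal signal accounts for the
    interaction), "independent" if it stays below ``independent_p``
    against every background, otherwise "ambiguous".  Backgrounds equal to
    a pair member are skipped.  Returns the long table plus a ``class``
    column repeated per pair.
    """
    rows = []
    for si, sj in pairs_in_region:
        gi = geno.dosages[:, geno.snp_index(si)]
        gj = geno.dosages[:, geno.snp_index(sj)]
        pvals = []
        for bg in marginal_snps_in_region:
            if bg in (si, sj):
                continue
            gb = geno.dosages[:, geno.snp_index(bg)]
            r = conditional_interaction_test(residuals, gi, gj, gb)
            pvals.append((bg, r.p_int, r.flag))
        if not pvals:
            continue
        ps = np.array([p for _, p, _ in pvals])
        if (ps > explained_p).any():
            cls = "explained"
        elif (ps < independent_p).all():
            cls = "independent"
        else:
            cls = "ambiguous"
        for bg, p, flag in pvals:
            rows.append((si, sj, bg, p, flag, cls))
    return pd.DataFrame(
        rows, columns=["snp_i", "snp_j", "background", "p_int", "flag", "class"]
    )


def local_pairs_to_frame(pairs: list[LocalPair], geno: GenotypeDataset) -> pd.DataFrame:
    lookup = geno.snp_map.set_index("snp")
    rows = []
    for lp in pairs:
        r = lp.result
        rows.append(
            {
                "snp_i": r.snp_i,
                "snp_j": r.snp_j,
                "chrom": lp.chromosome,
                "pos_i": lookup.loc[r.snp_i, "pos"],
                "pos_j": lookup.loc[r.snp_j, "pos"],
                "distance": lp.distance,
                "r2": lp.r2,
                "p_int": r.p_int,
                "f": r.f_stat,
                "n": r.n,
            }
        )
    return pd.DataFrame(rows)
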