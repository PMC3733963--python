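"""Quality control and phenotype preparation for quantitative-trait scans.

QC filters are applied in a fixed order: sample call rate, SNP call rate,
minor allele frequency, Hardy-Weinberg exact test, individual
heterozygosity (FDR on the upper tail), and principal-component outliers
from the identity-by-state matrix.  Defaults follow a common GWAS protocol:
individual call rate 97%, SNP call rate 95%, MAF 2%, HWE P 1e-10,
heterozygosity FDR 0.01, PC-outlier FDR 0.005 on the first three
components.

Phenotype preparation: covariate adjustment, rank-based inverse-normal
transform, then residualization against a polygenic mixed model
(y = PC beta + g + e, g ~ N(0, sigma_g^2 GRM)) fitted by REML through an
eigendecomposition of the genomic relationship matrix; the environmental
residuals e-hat are the trait actually scanned, and
h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, ndtri

from .synthetic_data import MISSING, GenotypeDataset

__all__ = [
    "QCThresholds",
    "QCReport",
    "hwe_exact_test",
    "qc_filter",
    "heterozygosity_outliers",
    "ibs_pca",
    "pc_outlier_filter",
    "rank_int",
    "polygenic_residuals",
    "grm",
    "prepare_phenotype",
]


@dataclass(frozen=True)
class QCThresholds:
    sample_call_rate: float = 0.97
    snp_call_rate: float = 0.95
    maf: float = 0.02
    hwe_p: float = 1e-10
    het_fdr: float = 0.01
    pc_fdr: float = 0.005
    pc_n: int = 3


@dataclass
class QCReport:
    """Exclusions (one primary reason each) and before/after counts."""

    thresholds: QCThresholds
    excluded_samples: list[tuple[str, str]] = field(default_factory=list)
    excluded_snps: list[tuple[str, str]] = field(default_factory=list)
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_snps_before: int = 0
    n_snps_after: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", sid, r) for sid, r in self.excluded_samples]
        rows += [("snp", sid, r) for sid, r in self.excluded_snps]
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])

    def validate(self) -> None:
        assert self.n_samples_before - len(self.excluded_samples) == self.n_samples_after
        assert self.n_snps_before - len(self.excluded_snps) == self.n_snps_after


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test on one SNP's genotype counts.

    Sums, conditional on the allele counts, the probabilities of all
    heterozygote counts no more probable than the observed one.  A
    monomorphic SNP returns 1 by convention.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("at least one genotyped individual is required")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        gammaln(n + 1)
        - gammaln(rare_hom + 1)
        - gammaln(hets + 1)
        - gammaln(common_hom + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def _bh_reject(pvals: np.ndarray, fdr: float) -> np.ndarray:
    """Benjamini-Hochberg step-up; returns a boolean rejection mask."""
    m = len(pvals)
    order = np.argsort(pvals)
    thresh = fdr * (np.arange(1, m + 1)) / m
    below = pvals[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        reject[order[: k + 1]] = True
    return reject


def _call_rates(dosages: np.ndarray, axis: int) -> np.ndarray:
    if dosages.shape[axis] == 0:
        return np.zeros(dosages.shape[1 - axis], dtype=float)
    return (dosages != MISSING).mean(axis=axis)


def _maf(dosages: np.ndarray) -> np.ndarray:
    ok = dosages != MISSING
    called = ok.sum(axis=0)
    alt = np.where(ok, dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt / (2.0 * called)
    freq = np.where(called == 0, 0.0, freq)
    return np.minimum(freq, 1.0 - freq)


def heterozygosity_outliers(geno: GenotypeDataset, fdr: float = 0.01) -> set[str]:
    """Samples with unacceptably HIGH heterozygosity, at the given FDR.

    Per-sample heterozygosity rate -> robust z (median/MAD) -> one-sided
    upper-tail normal P -> Benjamini-Hochberg.
    """
    if geno.n_samples < 10:
        raise ValueError("need at least 10 samples for outlier detection")
    ok = geno.dosages != MISSING
    het = ((geno.dosages == 1) & ok).sum(axis=1) / np.maximum(ok.sum(axis=1), 1)
    mad = stats.median_abs_deviation(het, scale="normal")
    if mad == 0:
        return set()
    z = (het - np.median(het)) / mad
    p = stats.norm.sf(z)
    rej = _bh_reject(p, fdr)
    return {geno.sample_ids[i] for i in np.nonzero(rej)[0]}


def ibs_pca(geno: GenotypeDataset, n_components: int = 10) -> np.ndarray:
    """Principal-component scores from the identity-by-state matrix.

    IBS(i, j) is the mean proportion of shared alleles over the SNPs called
    in both samples (pairwise exclusion of missing genotypes); the scores
    are classical multidimensional scaling coordinates of that similarity
    matrix, centered.  Returns (n_samples, k) with k <= n_components.
    """
    d = geno.dosages
    n = geno.n_samples
    g = [np.asarray(d == v, dtype=np.float64) for v in (0, 1, 2)]
    called = g[0] + g[1] + g[2]
    n_both = called @ called.T
    # |d_i - d_j| summed over jointly called SNPs, via one-hot cross products
    abs_diff = 2.0 * (g[0] @ g[2].T + g[2] @ g[0].T)
    abs_diff += g[1] @ (g[0] + g[2]).T + (g[0] + g[2]) @ g[1].T
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = (2.0 * n_both - abs_diff) / (2.0 * n_both)
    ibs[n_both == 0] = 0.0
    # classical MDS on the similarity matrix: double-center, eigendecompose
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = j @ ibs @ j
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    k = min(n_components, n)
    keep = order[:k]
    pos = np.clip(evals[keep], 0.0, None)
    scores = evecs[:, keep] * np.sqrt(pos)
    return scores - scores.mean(axis=0)


def pc_outlier_filter(
    scores: np.ndarray,
    sample_ids: list[str],
    n_pcs: int = 3,
    fdr: float = 0.005,
) -> set[str]:
    """Union of per-component robust-z outliers (two-sided, BH per PC)."""
    k = min(n_pcs, scores.shape[1])
    out: set[str] = set()
    for c in range(k):
        x = scores[:, c]
        mad = stats.median_abs_deviation(x, scale="normal")
        if mad == 0:
            continue
        z = (x - np.median(x)) / mad
        p = 2.0 * stats.norm.sf(np.abs(z))
        rej = _bh_reject(p, fdr)
        out.update(sample_ids[i] for i in np.nonzero(rej)[0])
    return out


def qc_filter(
    geno: GenotypeDataset,
    thresholds: QCThresholds | None = None,
) -> tuple[GenotypeDataset, QCReport]:
    """Apply the full QC protocol in fixed order; autosomes only.

    Order: sample call rate -> SNP call rate -> MAF -> HWE -> sample
    heterozygosity FDR -> sample PC outliers.  Raises if nothing survives.
    """
    th = thresholds or QCThresholds()
    report = QCReport(
        thresholds=th,
        n_samples_before=geno.n_samples,
        n_snps_before=geno.n_snps,
    )

    snp_keep = np.ones(geno.n_snps, dtype=bool)
    sample_keep = np.ones(geno.n_samples, dtype=bool)

    autosomal = geno.snp_map["chrom"].between(1, 22).to_numpy()
    for i in np.nonzero(~autosomal)[0]:
        report.excluded_snps.append((geno.snp_map["snp"].iloc[i], "non_autosomal"))
    snp_keep &= autosomal

    d = geno.dosages
    cr_sample = _call_rates(d[:, snp_keep], axis=1)
    drop = cr_sample < th.sample_call_rate
    for i in np.nonzero(drop)[0]:
        report.excluded_samples.append((geno.sample_ids[i], "call_rate"))
    sample_keep &= ~drop

    sub = d[sample_keep]
    cr_snp = _call_rates(sub, axis=0)
    drop = snp_keep & (cr_snp < th.snp_call_rate)
    for i in np.nonzero(drop)[0]:
        report.excluded_snps.append((geno.snp_map["snp"].iloc[i], "call_rate"))
    snp_keep &= ~drop

    maf = _maf(sub)
    drop = snp_keep & (maf < th.maf)
    for i in np.nonzero(drop)[0]:
        report.excluded_snps.append((geno.snp_map["snp"].iloc[i], "maf"))
    snp_keep &= ~drop

    for i in np.nonzero(snp_keep)[0]:
        col = sub[:, i]
        col = col[col != MISSING]
        counts = np.bincount(col, minlength=3)
        if hwe_exact_test(int(counts[0]), int(counts[1]), int(counts[2])) < th.hwe_p:
            report.excluded_snps.append((geno.snp_map["snp"].iloc[i], "hwe"))
            snp_keep[i] = False

    stage = geno.subset(np.nonzero(sample_keep)[0], np.nonzero(snp_keep)[0])
    if stage.n_samples >= 10:
        het_out = heterozygosity_outliers(stage, fdr=th.het_fdr)
        for sid in sorted(het_out):
            report.excluded_samples.append((sid, "heterozygosity"))
        keep_ids = [i for i, s in enumerate(stage.sample_ids) if s not in het_out]
        stage = stage.subset(keep_ids, None)

    if stage.n_samples >= 10:
        scores = ibs_pca(stage, n_components=th.pc_n)
        pc_out = pc_outlier_filter(scores, stage.sample_ids, n_pcs=th.pc_n, fdr=th.pc_fdr)
        for sid in sorted(pc_out):
            report.excluded_samples.append((sid, "pc_outlier"))
        keep_ids = [i for i, s in enumerate(stage.sample_ids) if s not in pc_out]
        stage = stage.subset(keep_ids, None)

    report.n_samples_after = stage.n_samples
    report.n_snps_after = stage.n_snps
    report.validate()
    if stage.n_samples == 0 or stage.n_snps == 0:
        raise ValueError("empty after QC: all samples or all SNPs removed")
    return stage, report


def rank_int(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform: Phi^-1((rank - 0.5) / n).

    Ties get average ranks; the output is monotone in the input and has
    mean ~0, sd ~1 by construction.  NaNs are propagated.
    """
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.nanstd(x[ok]) == 0:
        raise ValueError("rank transform undefined for constant input")
    out = np.full_like(x, np.nan)
    ranks = stats.rankdata(x[ok], method="average")
    out[ok] = ndtri((ranks - 0.5) / ok.sum())
    return out


def grm(geno: GenotypeDataset) -> np.ndarray:
    """VanRaden-style genomic relationship matrix from standardized dosages.

    Missing dosages are mean-imputed here only (never in association
    tests); monomorphic SNPs are dropped from the computation.
    """
    d = geno.dosages.astype(float)
    d[geno.dosages == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    sd = np.nanstd(d, axis=0)
    keep = sd > 0
    x = (np.where(np.isnan(d), mean, d) - mean)[:, keep] / sd[keep]
    return x @ x.T / keep.sum()


def _reml_neg2ll(log_ratio: float, d: np.ndarray, ystar: np.ndarray, wstar: np.ndarray) -> float:
    lam = np.exp(log_ratio)
    v = lam * d + 1.0
    n, p = wstar.shape
    wtw = (wstar / v[:, None]).T @ wstar
    wty = (wstar / v[:, None]).T @ ystar
    beta = np.linalg.solve(wtw, wty)
    r = ystar - wstar @ beta
    rss = float(np.sum(r * r / v))
    sign, logdet = np.linalg.slogdet(wtw)
    return float(np.sum(np.log(v)) + logdet + (n - p) * np.log(rss))


def polygenic_residuals(
    trait: np.ndarray,
    geno: GenotypeDataset | None,
    n_pcs: int = 10,
    scores: np.ndarray | None = None,
    relationship: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Environmental residuals and heritability from the polygenic model.

    Fits y = W beta + g + e with g ~ N(0, sigma_g^2 GRM), e ~ N(0,
    sigma_e^2 I) by REML over the single variance ratio on the eigenbasis
    of the GRM; W is an intercept plus the first ``n_pcs`` IBS principal
    components.  Returns (e_hat, h2, h2_se); e_hat = sigma_e^2 V^-1 (y -
    W beta) is the trait used by the downstream scans.

    If the GRM is numerically indistinguishable from the identity the
    variance split is unidentifiable; the unrelated-samples convention
    h2 = 0 is used and e_hat reduces to OLS residuals on W.
    """
    y = np.asarray(trait, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("trait must be complete; subset samples first")
    if relationship is None:
        if geno is None:
            raise ValueError("either geno or a relationship matrix is required")
        relationship = grm(geno)
    k = (relationship + relationship.T) / 2.0
    if scores is None:
        if geno is None:
            raise ValueError("PC scores are required when no genotypes are given")
        scores = ibs_pca(geno, n_components=n_pcs)
    w = np.column_stack([np.ones(len(y)), scores[:, : min(n_pcs, scores.shape[1])]])

    evals, u = np.linalg.eigh(k)
    if evals.min() < 0:
        jitter = 1e-6 - min(evals.min(), 0.0)
        evals = evals + jitter
    ystar = u.T @ y
    wstar = u.T @ w

    if np.max(np.abs(evals - 1.0)) < 1e-8:
        beta, *_ = np.linalg.lstsq(w, y, rcond=None)
        return y - w @ beta, 0.0, float("nan")

    res = optimize.minimize_scalar(
        _reml_neg2ll,
        bounds=(-12.0, 12.0),
        args=(evals, ystar, wstar),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise RuntimeError("REML optimisation failed to converge")
    lam = float(np.exp(res.x))
    # boundary solutions collapse to the unrelated model
    if res.x <= -11.5:
        lam = 0.0
    v = lam * evals + 1.0
    wtw = (wstar / v[:, None]).T @ wstar
    wty = (wstar / v[:, None]).T @ ystar
    beta = np.linalg.solve(wtw, wty)
    rstar = ystar - wstar @ beta
    h2 = lam / (1.0 + lam)
    e_hat = u @ (rstar / v)
    # curvature of the REML criterion in h2, by central differences
    h2_se = float("nan")
    if 0.0 < h2 < 1.0:
        eps = 1e-3
        lo, hi = max(res.x - eps, -12.0), min(res.x + eps, 12.0)
        f0 = _reml_neg2ll(res.x, evals, ystar, wstar)
        curv = (
            _reml_neg2ll(hi, evals, ystar, wstar)
            - 2 * f0
            + _reml_neg2ll(lo, evals, ystar, wstar)
        ) / eps**2
        if curv > 0:
            var_logratio = 2.0 / curv
            dh_dlog = lam / (1.0 + lam) ** 2
            h2_se = float(np.sqrt(var_logratio) * dh_dlog)
    return e_hat, float(h2), h2_se


def prepare_phenotype(
    pheno: pd.DataFrame,
    geno: GenotypeDataset,
    trait_col: str = "trait",
    covariate_cols: tuple[str, ...] = ("sex", "age", "centre"),
    n_pcs: int = 10,
) -> tuple[pd.DataFrame, float, float]:
    """Full phenotype preparation: covariates -> rank-INT -> polygenic residuals.

    Covariate adjustment is OLS on the listed columns (``centre`` treated as
    categorical); the rank-INT'ed residual is then residualized against the
    polygenic model.  Returns the table with added columns (trait_cov_adj,
    trait_int, residual) aligned to ``geno`` sample order, plus (h2, h2_se).
    """
    tab = pheno.set_index("sample_id").loc[geno.sample_ids].reset_index()
    y = tab[trait_col].to_numpy(dtype=float)
    cols = [np.ones(len(y))]
    for c in covariate_cols:
        if c not in tab.columns:
            continue
        if c == "centre":
            cols.append(pd.get_dummies(tab[c], drop_first=True).to_numpy(dtype=float))
        else:
            cols.append(tab[c].to_numpy(dtype=float)[:, None])
    x = np.column_stack(cols) if len(cols) > 1 else cols[0][:, None]
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    adj = y - x @ beta
    transformed = rank_int(adj)
    resid, h2, h2_se = polygenic_residuals(transformed, geno, n_pcs=n_pcs)
    out = tab.copy()
    out["trait_cov_adj"] = adj
    out["trait_int"] = transformed
    out["residual"] = resid
    return out, h2, h2_se
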