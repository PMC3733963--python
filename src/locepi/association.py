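"""Single-SNP association scan on prepared residuals and diagnostics.

Because relatedness and population structure are absorbed upstream (the
scanned trait is the environmental residual from the polygenic model), the
per-SNP test is a plain least-squares regression of residual on
minor-allele dosage with a two-sided t-test — the unrelated-samples
equivalent of a family score test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import MISSING, GenotypeDataset

__all__ = ["single_snp_scan", "marginal_set", "inflation_factor", "GWAS_CONSENSUS_P"]

GWAS_CONSENSUS_P = 5e-8  # genome-wide consensus threshold for marginal SNPs


def single_snp_scan(residuals: np.ndarray, geno: GenotypeDataset) -> pd.DataFrame:
    """Additive regression of the residual trait on each SNP's dosage.

    Missing dosages are dropped per SNP.  A SNP monomorphic among its
    called samples gets beta = 0, P = 1 and the ``monomorphic`` flag.
    Returns a DataFrame (snp, chrom, pos, beta, se, stat, p, n, monomorphic).
    """
    y = np.asarray(residuals, dtype=float)
    if len(y) != geno.n_samples:
        raise ValueError("residual vector does not match sample count")
    d = geno.dosages
    ok = d != MISSING
    x = np.where(ok, d, 0).astype(float)
    n = ok.sum(axis=0).astype(float)

    sx = x.sum(axis=0)
    sy = ok.T @ y
    sxx = (x * x).sum(axis=0)
    sxy = x.T @ y
    syy = ok.T @ (y * y)

    with np.errstate(invalid="ignore", divide="ignore"):
        vx = sxx - sx * sx / n
        cxy = sxy - sx * sy / n
        vy = syy - sy * sy / n
        beta = cxy / vx
        rss = vy - beta * cxy
        df = n - 2
        se = np.sqrt(np.clip(rss, 0.0, None) / np.clip(df, 1.0, None) / vx)
        tstat = beta / se
    mono = ~(vx > 0)
    testable = ~mono & (df >= 1)
    p = np.ones(geno.n_snps)
    p[testable] = 2.0 * stats.t.sf(np.abs(tstat[testable]), df[testable])
    beta[mono] = 0.0
    se[mono] = np.nan
    tstat[mono] = np.nan

    return pd.DataFrame(
        {
            "snp": geno.snp_map["snp"].to_numpy(),
            "chrom": geno.snp_map["chrom"].to_numpy(),
            "pos": geno.snp_map["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "stat": tstat,
            "p": p,
            "n": n.astype(int),
            "monomorphic": mono,
        }
    )


def marginal_set(results: pd.DataFrame, threshold: float = GWAS_CONSENSUS_P) -> set[str]:
    """SNPs with genome-wide significant marginal effects (P <= threshold)."""
    hit = results["p"] <= threshold
    return set(results.loc[hit, "snp"])


def inflation_factor(results: pd.DataFrame) -> float:
    """Genomic inflation factor lambda from observed vs expected quantiles.

    P-values are converted to 1-df chi-square quantiles; the sorted
    observed statistics are regressed through the origin on the expected
    chi-square(1) order statistics, and the slope is lambda.
    """
    import warnings

    p = results["p"].to_numpy(dtype=float)
    p = p[np.isfinite(p)]
    m = len(p)
    if m == 0:
        raise ValueError("no P-values to compute an inflation factor from")
    if m < 100:
        warnings.warn(f"inflation factor computed from only {m} SNPs", stacklevel=2)
    obs = np.sort(stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1))
    expq = stats.chi2.ppf((np.arange(1, m + 1) - 0.5) / m, df=1)
    return float(np.dot(obs, expq) / np.dot(expq, expq))
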