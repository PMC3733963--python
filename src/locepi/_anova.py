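"""Core two-locus genotype-class ANOVA machinery.

The interaction statistic everywhere in this package is the unbalanced
two-way fixed-effects ANOVA F-test on genotype classes: the reduced model
fits grand mean + row (SNP i genotype) + column (SNP j genotype) effects by
least squares, the full model fits a free mean per non-empty 3x3 cell, and

    F = ((RSS_reduced - RSS_full) / df_int) / (RSS_full / df_res)

with df_int = (#non-empty cells) - rank(reduced design) and df_res =
n - #non-empty cells.  Because both models are cell-level, everything is
computed from per-cell counts and phenotype sums, which is what makes the
exhaustive scan and the permutation engines fast.

Three entry points:
- :func:`pair_anova` - exact, fully guarded single-pair test.
- :func:`all_pairs_scan` - batched scan over every i<j pair via one-hot
  genotype cross products and batched 5x5 normal-equation solves.
- :class:`PairPermEngine` - fixed genotypes, many phenotype vectors
  (permutations) at once.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .synthetic_data import MISSING

P_SATURATED = np.nextafter(0.0, 1.0)  # smallest positive representable P

# cell -> reduced-design row, treatment coding (mu, r1, r2, c1, c2)
_BMAT = np.zeros((9, 5))
for _a in range(3):
    for _b in range(3):
        _c = 3 * _a + _b
        _BMAT[_c, 0] = 1.0
        if _a >= 1:
            _BMAT[_c, _a] = 1.0
        if _b >= 1:
            _BMAT[_c, 2 + _b] = 1.0


def _orth_basis(xw: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal column basis of xw (via SVD, rank-revealing)."""
    u, s, _ = np.linalg.svd(xw, full_matrices=False)
    rank = int(np.sum(s > tol * max(s[0], 1.0))) if s.size else 0
    return u[:, :rank]


def _reduced_design(nonempty: np.ndarray) -> np.ndarray:
    """Reduced-model design over the non-empty cells (rows of _BMAT)."""
    return _BMAT[nonempty]


def pair_anova(y: np.ndarray, g_i: np.ndarray, g_j: np.ndarray) -> dict:
    """Exact two-locus interaction ANOVA for one SNP pair.

    Handles missing dosages (jointly non-missing samples only), empty
    cells, rank-deficient reduced designs, monomorphic SNPs and saturated
    fits.  Returns a dict of statistic fields (see keys below).
    """
    y = np.asarray(y, dtype=float)
    gi = np.asarray(g_i)
    gj = np.asarray(g_j)
    mask = (gi != MISSING) & (gj != MISSING) & np.isfinite(y)
    yv, giv, gjv = y[mask], gi[mask].astype(np.intp), gj[mask].astype(np.intp)
    n = len(yv)

    out = {
        "n": n,
        "f": np.nan,
        "p": 1.0,
        "df_int": 0,
        "df_res": 0,
        "counts": np.zeros((3, 3), dtype=int),
        "means": np.full((3, 3), np.nan),
        "flag": "",
    }
    if n == 0:
        out["flag"] = "untestable"
        return out

    labels = 3 * giv + gjv
    counts = np.bincount(labels, minlength=9).astype(float)
    sums = np.bincount(labels, weights=yv, minlength=9)
    out["counts"] = counts.reshape(3, 3).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    out["means"] = means.reshape(3, 3)

    if len(np.unique(giv)) < 2 or len(np.unique(gjv)) < 2:
        out["flag"] = "monomorphic"
        return out

    nonempty = counts > 0
    n_cells = int(nonempty.sum())
    sw = np.sqrt(counts[nonempty])
    z = sums[nonempty] / sw
    xw = _reduced_design(nonempty) * sw[:, None]
    q = _orth_basis(xw)
    rank_red = q.shape[1]
    df_int = n_cells - rank_red
    df_res = n - n_cells
    out["df_int"], out["df_res"] = df_int, df_res
    if df_int < 1 or df_res < 1:
        out["flag"] = "untestable"
        return out

    full_exp = float(z @ z)
    red_exp = float(np.sum((q.T @ z) ** 2))
    ss_int = max(full_exp - red_exp, 0.0)
    yy = float(yv @ yv)
    rss_full = max(yy - full_exp, 0.0)
    scale = max(yy, 1.0)
    if rss_full <= 1e-12 * scale:
        if ss_int > 1e-12 * scale:
            out["f"] = np.inf
            out["p"] = P_SATURATED
            out["flag"] = "saturated"
        else:
            out["f"] = 0.0
            out["p"] = 1.0
        return out

    f = (ss_int / df_int) / (rss_full / df_res)
    out["f"] = float(f)
    out["p"] = float(stats.f.sf(f, df_int, df_res))
    return out


def _onehot(dosages: np.ndarray) -> list[np.ndarray]:
    return [np.asarray(dosages == v, dtype=np.float64) for v in (0, 1, 2)]


def all_pairs_scan(
    y: np.ndarray,
    dosages: np.ndarray,
    chunk: int = 512,
) -> dict[str, np.ndarray]:
    """Interaction F-test for every i<j SNP pair, vectorized.

    Per-cell counts and phenotype sums for all pairs come from 9 one-hot
    genotype cross products; the reduced model is solved per pair through
    its 5x5 weighted normal equations in a batched solve.  Pairs with an
    empty marginal genotype class, a singular reduced design or too few
    residual degrees of freedom are routed through :func:`pair_anova`.

    Returns flat arrays over pairs in (i<j, row-major) order: ii, jj, p, f,
    df_int, df_res, n, saturated (bool), untestable (bool).
    """
    y = np.asarray(y, dtype=float)
    nsam, nsnp = dosages.shape
    if nsnp < 2:
        raise ValueError("need at least 2 SNPs for a pairwise scan")
    g = _onehot(dosages)
    valid = g[0] + g[1] + g[2]
    y2 = y * y
    gy = [gb * y[:, None] for gb in g]
    vy2 = valid * y2[:, None]

    npairs = nsnp * (nsnp - 1) // 2
    res = {
        "ii": np.empty(npairs, dtype=np.int32),
        "jj": np.empty(npairs, dtype=np.int32),
        "p": np.ones(npairs),
        "f": np.full(npairs, np.nan),
        "df_int": np.zeros(npairs, dtype=np.int32),
        "df_res": np.zeros(npairs, dtype=np.int32),
        "n": np.zeros(npairs, dtype=np.int64),
        "saturated": np.zeros(npairs, dtype=bool),
        "untestable": np.zeros(npairs, dtype=bool),
    }

    pos = 0
    for j0 in range(1, nsnp, chunk):
        j1 = min(j0 + chunk, nsnp)
        js = np.arange(j0, j1)
        # counts[a,b] and sums[a,b]: (nsnp, B) for the column block
        cnt = np.empty((3, 3, nsnp, j1 - j0))
        sm = np.empty_like(cnt)
        for a in range(3):
            for b in range(3):
                cnt[a, b] = g[a].T @ g[b][:, j0:j1]
                sm[a, b] = g[a].T @ gy[b][:, j0:j1]
        yy = valid.T @ vy2[:, j0:j1]
        npair = valid.T @ valid[:, j0:j1]

        # keep i < j pairs only
        ii_grid, jj_grid = np.meshgrid(np.arange(nsnp), js, indexing="ij")
        keep = ii_grid < jj_grid
        ii = ii_grid[keep]
        jj = jj_grid[keep]
        w = cnt.reshape(9, nsnp, j1 - j0)[:, keep].T  # (P, 9)
        s = sm.reshape(9, nsnp, j1 - j0)[:, keep].T
        yy_p = yy[keep]
        n_p = npair[keep]
        np_here = len(ii)

        row_c = w.reshape(-1, 3, 3).sum(axis=2)
        col_c = w.reshape(-1, 3, 3).sum(axis=1)
        ncells = (w > 0).sum(axis=1)
        df_int = ncells - 5
        df_res = (n_p - ncells).astype(np.int64)

        a_mat = np.einsum("ck,pc,cl->pkl", _BMAT, w, _BMAT)
        norm = np.maximum(n_p, 1.0)
        det = np.linalg.det(a_mat / norm[:, None, None])

        easy = (
            (row_c > 0).all(axis=1)
            & (col_c > 0).all(axis=1)
            & (np.abs(det) > 1e-10)
            & (df_int >= 1)
            & (df_res >= 1)
        )

        p_out = np.ones(np_here)
        f_out = np.full(np_here, np.nan)
        sat = np.zeros(np_here, dtype=bool)
        unt = np.zeros(np_here, dtype=bool)

        if easy.any():
            rhs = np.einsum("ck,pc->pk", _BMAT, s[easy])
            beta = np.linalg.solve(a_mat[easy], rhs[..., None])[..., 0]
            red_exp = np.einsum("pk,pk->p", beta, rhs)
            full_exp = np.where(w[easy] > 0, s[easy] ** 2 / np.maximum(w[easy], 1.0), 0.0).sum(
                axis=1
            )
            ss_int = np.clip(full_exp - red_exp, 0.0, None)
            rss_full = np.clip(yy_p[easy] - full_exp, 0.0, None)
            scale = np.maximum(yy_p[easy], 1.0)
            d1 = df_int[easy].astype(float)
            d2 = df_res[easy].astype(float)
            saturated = (rss_full <= 1e-12 * scale) & (ss_int > 1e-12 * scale)
            nullfit = (rss_full <= 1e-12 * scale) & ~saturated
            with np.errstate(invalid="ignore", divide="ignore"):
                f_val = (ss_int / d1) / (rss_full / d2)
            p_val = stats.f.sf(f_val, d1, d2)
            p_val[saturated] = P_SATURATED
            f_val[saturated] = np.inf
            p_val[nullfit] = 1.0
            f_val[nullfit] = 0.0
            p_out[easy] = p_val
            f_out[easy] = f_val
            sat[easy] = saturated

        hard = np.nonzero(~easy)[0]
        for k in hard:
            r = pair_anova(y, dosages[:, ii[k]], dosages[:, jj[k]])
            p_out[k] = r["p"]
            f_out[k] = r["f"]
            df_int[k] = r["df_int"]
            df_res[k] = r["df_res"]
            sat[k] = r["flag"] == "saturated"
            unt[k] = r["flag"] in ("untestable", "monomorphic")

        sl = slice(pos, pos + np_here)
        res["ii"][sl] = ii
        res["jj"][sl] = jj
        res["p"][sl] = p_out
        res["f"][sl] = f_out
        res["df_int"][sl] = df_int
        res["df_res"][sl] = df_res
        res["n"][sl] = n_p.astype(np.int64)
        res["saturated"][sl] = sat
        res["untestable"][sl] = unt
        pos += np_here
    assert pos == npairs
    return res


class PairPermEngine:
    """Interaction P-values for fixed SNP pairs against many phenotypes.

    Precomputes, per pair, the cell membership one-hot matrix and the
    orthonormal basis of the weighted reduced design (both depend only on
    genotypes); :meth:`pvalues` then evaluates every pair against a whole
    matrix of phenotype columns (e.g. permutations) with dense matmuls.
    """

    def __init__(self, dosages: np.ndarray, pairs: list[tuple[int, int]]):
        nsam = dosages.shape[0]
        self.pairs = list(pairs)
        self._prep = []
        for i, j in self.pairs:
            gi, gj = dosages[:, i], dosages[:, j]
            mask = (gi != MISSING) & (gj != MISSING)
            labels = 3 * gi.astype(np.intp) + gj.astype(np.intp)
            h = np.zeros((nsam, 9))
            h[np.nonzero(mask)[0], labels[mask]] = 1.0
            counts = h.sum(axis=0)
            nonempty = counts > 0
            n_cells = int(nonempty.sum())
            n = int(mask.sum())
            poly = len(np.unique(gi[mask])) >= 2 and len(np.unique(gj[mask])) >= 2
            sw = np.sqrt(counts[nonempty])
            q = _orth_basis(_reduced_design(nonempty) * sw[:, None]) if poly else np.zeros((n_cells, 0))
            df_int = n_cells - q.shape[1]
            df_res = n - n_cells
            testable = poly and df_int >= 1 and df_res >= 1
            self._prep.append(
                {
                    "h": h[:, nonempty],
                    "sw": sw,
                    "q": q,
                    "df_int": df_int,
                    "df_res": df_res,
                    "maskf": mask.astype(float),
                    "testable": testable,
                }
            )

    def pvalues(self, y_mat: np.ndarray) -> np.ndarray:
        """P_int for every pair (rows) against every phenotype column."""
        y_mat = np.atleast_2d(np.asarray(y_mat, dtype=float).T).T
        if y_mat.ndim == 1:
            y_mat = y_mat[:, None]
        y2 = y_mat * y_mat
        nper = y_mat.shape[1]
        out = np.ones((len(self.pairs), nper))
        for k, pp in enumerate(self._prep):
            if not pp["testable"]:
                continue
            s = pp["h"].T @ y_mat
            z = s / pp["sw"][:, None]
            full_exp = np.einsum("cp,cp->p", z, z)
            qz = pp["q"].T @ z
            red_exp = np.einsum("cp,cp->p", qz, qz)
            ss_int = np.clip(full_exp - red_exp, 0.0, None)
            yy = pp["maskf"] @ y2
            rss_full = np.clip(yy - full_exp, 0.0, None)
            scale = np.maximum(yy, 1.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                f = (ss_int / pp["df_int"]) / (rss_full / pp["df_res"])
            p = stats.f.sf(f, pp["df_int"], pp["df_res"])
            sat = (rss_full <= 1e-12 * scale) & (ss_int > 1e-12 * scale)
            p[sat] = P_SATURATED
            p[(rss_full <= 1e-12 * scale) & ~sat] = 1.0
            out[k] = p
        return out
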