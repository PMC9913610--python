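"""Genotype QC and univariate linear-mixed-model association scan.

The scan follows the standard LMM GWAS formulation
``y = W a + x b + u + e`` with ``u ~ N(0, lambda * tau^-1 * K)`` and
``e ~ N(0, tau^-1 I)``: the variance ratio ``lambda`` is estimated once
under the null by REML on the spectral decomposition of the genomic
relationship matrix ``K``, then every marker is tested by GLS with a Wald
statistic referred to F(1, n - c - 1) where ``c`` counts the columns of
``W`` (intercept plus stratification PCs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .plinkio import GenotypeMatrix

SUGGESTIVE_P = 1e-4
GENOMEWIDE_P = 1e-5
LAMBDA_BOUNDS = (1e-5, 1e5)


# ---------------------------------------------------------------------------
# QC

@dataclass
class QcReport:
    n_input: int = 0
    n_fail_callrate: int = 0
    n_fail_maf: int = 0
    n_pruned_ld: int = 0
    n_output: int = 0
    notes: list = field(default_factory=list)


def marker_callrate(dosages: np.ndarray) -> np.ndarray:
    return 1.0 - np.isnan(dosages).mean(axis=0)


def marker_maf(dosages: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def qc_filter(geno: GenotypeMatrix, call_rate_min: float = 0.95,
              maf_min: float = 0.05) -> tuple[GenotypeMatrix, QcReport]:
    """Drop markers with call rate <= threshold or MAF < threshold.

    Boundary semantics follow the stated rules verbatim: call rate must
    exceed ``call_rate_min`` strictly, while MAF exactly at ``maf_min``
    is kept.
    """
    rep = QcReport(n_input=geno.n_markers)
    cr_ok = marker_callrate(geno.dosages) > call_rate_min
    maf_ok = marker_maf(geno.dosages) >= maf_min
    rep.n_fail_callrate = int((~cr_ok).sum())
    rep.n_fail_maf = int((cr_ok & ~maf_ok).sum())
    keep = cr_ok & maf_ok
    if not keep.any():
        raise ValueError("all markers removed by QC")
    rep.n_output = int(keep.sum())
    return geno.subset_markers(np.flatnonzero(keep)), rep


def _pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """Squared correlation between marker dosages (mean-imputed)."""
    X = mean_impute(dosages)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = np.inf
    Xn = X / sd
    r = Xn.T @ Xn / len(X)
    return r ** 2


def ld_prune(geno: GenotypeMatrix, window: int = 50, step: int = 5,
             r2_max: float = 0.5) -> tuple[GenotypeMatrix, QcReport]:
    """Greedy windowed LD pruning (indep-pairwise semantics).

    Within each ``window``-marker window, while any surviving pair has
    r^2 > ``r2_max`` the later marker (position order) of the pair is
    removed; the window then slides by ``step`` markers.  Chromosomes are
    pruned independently.
    """
    rep = QcReport(n_input=geno.n_markers)
    keep_global = np.ones(geno.n_markers, dtype=bool)
    for chrom in geno.bim["chrom"].unique():
        cidx = np.flatnonzero((geno.bim["chrom"] == chrom).to_numpy())
        removed = np.zeros(len(cidx), dtype=bool)
        start = 0
        while start < len(cidx):
            stop = min(start + window, len(cidx))
            live = [j for j in range(start, stop) if not removed[j]]
            if len(live) > 1:
                r2 = _pairwise_r2(geno.dosages[:, cidx[live]])
                for a in range(len(live)):
                    if removed[live[a]]:
                        continue
                    for b in range(a + 1, len(live)):
                        if removed[live[b]]:
                            continue
                        if r2[a, b] > r2_max:
                            removed[live[b]] = True
            if stop == len(cidx):
                break
            start += step
        keep_global[cidx[removed]] = False
    rep.n_pruned_ld = int((~keep_global).sum())
    rep.n_output = int(keep_global.sum())
    return geno.subset_markers(np.flatnonzero(keep_global)), rep


# ---------------------------------------------------------------------------
# relationship matrix and stratification covariates

def mean_impute(dosages: np.ndarray) -> np.ndarray:
    X = np.array(dosages, dtype=float, copy=True)
    mu = np.nanmean(X, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = mu[nan_c]
    return X


def grm_centered(geno: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Centered genomic relationship matrix K = Zc Zc' / m."""
    dosages = geno.dosages if isinstance(geno, GenotypeMatrix) else geno
    if dosages.shape[1] == 0:
        raise ValueError("no markers for the GRM")
    Zc = mean_impute(dosages)
    Zc = Zc - Zc.mean(axis=0)
    return Zc @ Zc.T / dosages.shape[1]


def stratification_pcs(geno: GenotypeMatrix | np.ndarray, n_pcs: int = 10) -> np.ndarray:
    """Covariate matrix W: intercept plus the top sample PCs of the markers."""
    dosages = geno.dosages if isinstance(geno, GenotypeMatrix) else geno
    n = dosages.shape[0]
    if n_pcs >= n:
        raise ValueError("n_pcs must be below the sample count")
    W = [np.ones(n)]
    if n_pcs > 0:
        K = grm_centered(dosages)
        vals, vecs = np.linalg.eigh(K)
        order = np.argsort(vals)[::-1][:n_pcs]
        W.extend(vecs[:, j] for j in order)
    return np.column_stack(W)


# ---------------------------------------------------------------------------
# LMM

@dataclass
class NullModel:
    lam: float                   # variance ratio lambda
    tau_inv: float               # residual variance tau^-1
    eigvals: np.ndarray
    rot_y: np.ndarray            # U' y
    rot_W: np.ndarray            # U' W
    U: np.ndarray
    boundary: bool = False
    logl: float = 0.0


def _reml_neg2ll(lam: float, d: np.ndarray, yr: np.ndarray, Wr: np.ndarray) -> float:
    h = lam * d + 1.0
    w = 1.0 / h
    WtHW = Wr.T @ (w[:, None] * Wr)
    sign, ld_whw = np.linalg.slogdet(WtHW)
    if sign <= 0:
        return np.inf
    sol = np.linalg.solve(WtHW, Wr.T @ (w * yr))
    resid = yr - Wr @ sol
    ypy = float(resid @ (w * resid))
    nc = len(yr) - Wr.shape[1]
    return float(np.sum(np.log(h)) + ld_whw + nc * np.log(ypy))


def lmm_null(y, W, K) -> NullModel:
    """REML of the variance ratio by 1-D optimization on K's spectrum."""
    y = np.asarray(y, dtype=float)
    W = np.atleast_2d(np.asarray(W, dtype=float))
    d, U = np.linalg.eigh(np.asarray(K, dtype=float))
    d = np.maximum(d, 0.0)
    yr, Wr = U.T @ y, U.T @ W
    obj = lambda loglam: _reml_neg2ll(10.0 ** loglam, d, yr, Wr)
    lo, hi = np.log10(LAMBDA_BOUNDS[0]), np.log10(LAMBDA_BOUNDS[1])
    # coarse grid then local refinement
    grid = np.linspace(lo, hi, 41)
    vals = np.array([obj(g) for g in grid])
    j = int(np.argmin(vals))
    a, b = grid[max(j - 1, 0)], grid[min(j + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(obj, bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-8})
    lam = 10.0 ** float(res.x)
    flat = bool(np.nanmax(vals) - np.nanmin(vals) < 1e-6)   # lambda unidentifiable
    boundary = flat or bool(res.x <= lo + 0.15 or res.x >= hi - 0.15)
    h = lam * d + 1.0
    w = 1.0 / h
    WtHW = Wr.T @ (w[:, None] * Wr)
    sol = np.linalg.solve(WtHW, Wr.T @ (w * yr))
    resid = yr - Wr @ sol
    ypy = float(resid @ (w * resid))
    nc = len(y) - W.shape[1]
    return NullModel(lam=lam, tau_inv=ypy / nc, eigvals=d, rot_y=yr, rot_W=Wr,
                     U=U, boundary=boundary, logl=-0.5 * float(res.fun))


def wald_scan(geno: GenotypeMatrix, y, W, K, null: NullModel | None = None) -> pd.DataFrame:
    """Per-marker GLS effect, SE and Wald p under the fitted null lambda.

    Monomorphic markers (after mean imputation) get NaN results.  Returns
    the association table (chr, rs, ps, beta, se, p_wald).
    """
    y = np.asarray(y, dtype=float)
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if null is None:
        null = lmm_null(y, W, K)
    n, c = len(y), W.shape[1]
    w = 1.0 / (null.lam * null.eigvals + 1.0)
    yr, Wr = null.rot_y, null.rot_W
    X = null.U.T @ mean_impute(geno.dosages)        # rotated markers, n x m

    WtHW = Wr.T @ (w[:, None] * Wr)
    WtHW_inv = np.linalg.inv(WtHW)
    Wty = Wr.T @ (w * yr)
    alpha0 = WtHW_inv @ Wty
    yPy0 = float(yr @ (w * yr) - Wty @ alpha0)

    wX = w[:, None] * X
    xHx = np.einsum("ij,ij->j", X, wX)
    WtHX = Wr.T @ wX                                 # c x m
    xPx = xHx - np.einsum("ij,ij->j", WtHX, WtHW_inv @ WtHX)
    xPy = X.T @ (w * yr) - WtHX.T @ alpha0

    dof = n - c - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = xPy / xPx
        s2 = (yPy0 - beta * xPy) / dof
        se = np.sqrt(np.maximum(s2, 0.0) / xPx)
        fstat = np.where(se > 0, (beta / se) ** 2, np.nan)
    p = stats.f.sf(fstat, 1, dof)
    mono = xPx <= 1e-12 * np.maximum(xHx, 1.0)
    beta[mono], se[mono], p[mono] = np.nan, np.nan, np.nan
    out = geno.bim[["chrom", "snp", "pos"]].rename(
        columns={"chrom": "chr", "snp": "rs", "pos": "ps"}).copy()
    out["beta"], out["se"], out["p_wald"] = beta, se, p
    out.attrs["lambda"] = null.lam
    out.attrs["tau_inv"] = null.tau_inv
    return out


def lambda_gc(pvalues) -> float:
    """Genomic-control inflation factor from a vector of scan p-values."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def significant_hits(res: pd.DataFrame, suggestive: float = SUGGESTIVE_P,
                     genomewide: float = GENOMEWIDE_P) -> pd.DataFrame:
    """Markers below the suggestive threshold, best first.

    Adds a ``genomewide`` flag for the stricter threshold; the table's
    ``mean_abs_beta`` attribute reports the mean absolute effect of hits.
    """
    hits = res[res["p_wald"] < suggestive].sort_values("p_wald").copy()
    hits["genomewide"] = hits["p_wald"] < genomewide
    hits.attrs["mean_abs_beta"] = (float(hits["beta"].abs().mean())
                                   if len(hits) else np.nan)
    return hits


def candidate_genes(hits: pd.DataFrame, gene_table: pd.DataFrame,
                    flank: int = 500_000) -> pd.DataFrame:
    """Genes overlapping [pos - flank, pos + flank] of each hit (closed
    interval, 1-based inclusive gene coordinates)."""
    rows = []
    genes = gene_table.copy()
    genes["chromosome"] = genes["chromosome"].astype(str)
    for _, hit in hits.iterrows():
        lo, hi = hit["ps"] - flank, hit["ps"] + flank
        sub = genes[(genes["chromosome"] == str(hit["chr"]))
                    & (genes["end"] >= lo) & (genes["start"] <= hi)]
        for _, g in sub.iterrows():
            rows.append({"rs": hit["rs"], "chr": hit["chr"], "ps": hit["ps"],
                         "gene": g["gene"], "gene_start": g["start"],
                         "gene_end": g["end"]})
    return pd.DataFrame(rows, columns=["rs", "chr", "ps", "gene",
                                       "gene_start", "gene_end"])


def manhattan_table(res: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: chr, pos, -log10 p."""
    out = res[["chr", "ps"]].copy()
    out["neglog10p"] = -np.log10(res["p_wald"])
    return out
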