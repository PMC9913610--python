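"""Principal-component composite index over per-calving breeding values.

A random-regression fit yields nine per-calving EGVs per animal.  Following
the Togashi–Lin construction these are standardized column-wise, the 9x9
correlation matrix is eigen-decomposed, and each animal is scored on the
first two components: Ipc1 (the "size" vector, near-uniform positive
loadings) and Ipc2 (the "shape" vector).  Their sum, IpcT, is the
composite pseudo-phenotype used for cohort selection and GWAS.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd


@dataclass
class PcaResult:
    eigenvalues: np.ndarray       # descending
    eigenvectors: np.ndarray      # columns, matching eigenvalue order
    variance_pct: np.ndarray

    @property
    def pc1(self) -> np.ndarray:
        return self.eigenvectors[:, 0]

    @property
    def pc2(self) -> np.ndarray:
        return self.eigenvectors[:, 1]


def standardize_panel(egvs: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (sample SD) of the per-calving EGV panel."""
    if len(egvs) < 2:
        raise ValueError("need at least two animals")
    sd = egvs.std(ddof=1)
    if (sd <= 0).any():
        bad = list(sd.index[sd <= 0])
        raise ValueError(f"zero-variance EGV columns: {bad}")
    return (egvs - egvs.mean()) / sd


def pca_eigen(panel: pd.DataFrame) -> PcaResult:
    """Eigen-decomposition of the correlation matrix of a standardized panel.

    Deterministic sign convention: within each eigenvector the
    largest-magnitude loading is made positive.
    """
    Xs = panel.to_numpy(dtype=float)
    corr = Xs.T @ Xs / (len(panel) - 1)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.maximum(vals, 0.0)
    for j in range(vecs.shape[1]):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return PcaResult(vals, vecs, 100.0 * vals / vals.sum())


def ipc_index(panel: pd.DataFrame, pc1ev: np.ndarray, pc2ev: np.ndarray) -> pd.DataFrame:
    """Animal scores on PC1 and PC2 and their sum IpcT."""
    Xs = panel.to_numpy(dtype=float)
    ipc1 = Xs @ np.asarray(pc1ev, dtype=float)
    ipc2 = Xs @ np.asarray(pc2ev, dtype=float)
    return pd.DataFrame({"Ipc1": ipc1, "Ipc2": ipc2, "IpcT": ipc1 + ipc2},
                        index=panel.index)


def select_cohort(ipct: pd.Series, n_top: int = 212, n_negative: int = 40) -> pd.Index:
    """Genotyping cohort: top animals from the upper quartile plus
    animals with a negative index (most negative first)."""
    s = ipct.sort_values(ascending=False)
    q3 = s.quantile(0.75)
    upper = s[s >= q3]
    if n_top > len(upper):
        warnings.warn(f"requested {n_top} upper-quartile animals, only {len(upper)} available")
    top = upper.index[:min(n_top, len(upper))]
    neg = s[s < 0].sort_values()
    if n_negative > len(neg):
        warnings.warn(f"requested {n_negative} negative-index animals, only {len(neg)} available")
    bottom = neg.index[:min(n_negative, len(neg))]
    return top.union(bottom, sort=False)


def index_table(panel: pd.DataFrame, pca: PcaResult | None = None) -> pd.DataFrame:
    """Full index table (animal, Ipc1, Ipc2, IpcT, rank), best first."""
    pca = pca or pca_eigen(panel)
    tab = ipc_index(panel, pca.pc1, pca.pc2)
    tab["rank"] = tab["IpcT"].rank(ascending=False, method="first").astype(int)
    return tab.sort_values("rank")
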