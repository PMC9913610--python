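"""Pedigree bookkeeping, inbreeding and relationship matrices.

The additive (numerator) relationship matrix ``A`` underlies every animal
model in this package.  Inbreeding coefficients are computed with the
Meuwissen & Luo algorithm (O(pedigree) memory, no dense ``A``); the dense
tabular ``A`` is provided only as a small-pedigree oracle, while model
fitting always uses the sparse ``A``-inverse built from Henderson's rules
with inbreeding.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = -1
_TABULAR_SIZE_GUARD = 5000


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Sorted pedigree in index form.

    ``sire``/``dam`` hold positional indices into ``ids`` (``-1`` =
    unknown parent, treated as an unrelated founder).  Instances are
    created through :meth:`from_frame` / :func:`read_pedigree`, which
    validate and topologically sort the records.
    """

    ids: np.ndarray           # object array of animal identifiers
    sire: np.ndarray          # int indices, -1 unknown
    dam: np.ndarray
    birth_year: np.ndarray    # int
    sex: np.ndarray           # 'M'/'F'
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    def loc(self, animal_id) -> int:
        return self._index[animal_id]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        return sort_pedigree(frame)

    def to_frame(self) -> pd.DataFrame:
        def name(idx):
            return np.where(idx >= 0, self.ids[np.maximum(idx, 0)], "0")
        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": name(self.sire),
                "dam": name(self.dam),
                "birth_year": self.birth_year,
                "sex": self.sex,
            }
        )


def _as_parent_col(col: pd.Series) -> pd.Series:
    col = col.astype(object).where(col.notna(), "0")
    col = col.map(lambda v: "0" if v in (0, "0", "", None) else v)
    return col


def sort_pedigree(frame: pd.DataFrame) -> Pedigree:
    """Validate and topologically sort a raw pedigree table.

    Parents always precede offspring in the result.  A cycle (an animal
    being its own ancestor) raises :class:`PedigreeError` naming the
    offending chain; unknown parents are encoded as ``-1``.
    """
    req = {"animal", "sire", "dam"}
    missing = req - set(frame.columns)
    if missing:
        raise PedigreeError(f"pedigree table lacks columns: {sorted(missing)}")
    animals = frame["animal"].astype(object).to_numpy()
    if len(set(animals)) != len(animals):
        dup = frame["animal"][frame["animal"].duplicated()].iloc[0]
        raise PedigreeError(f"duplicate animal id: {dup!r}")
    sires = _as_parent_col(frame["sire"]).to_numpy()
    dams = _as_parent_col(frame["dam"]).to_numpy()

    known = set(animals)
    # Parents appearing only as parents become founders appended up front.
    phantom = [p for p in pd.unique(np.concatenate([sires, dams]))
               if p != "0" and p not in known]

    ids = list(phantom) + list(animals)
    idx = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    sire_i = np.full(n, UNKNOWN, dtype=np.int64)
    dam_i = np.full(n, UNKNOWN, dtype=np.int64)
    off = len(phantom)
    for k in range(len(animals)):
        if sires[k] != "0":
            sire_i[off + k] = idx[sires[k]]
        if dams[k] != "0":
            dam_i[off + k] = idx[dams[k]]

    order = _toposort(ids, sire_i, dam_i)

    by = np.zeros(n, dtype=np.int64)
    sx = np.array(["U"] * n, dtype=object)
    if "birth_year" in frame.columns:
        by[off:] = pd.to_numeric(frame["birth_year"], errors="coerce").fillna(0).astype(int).to_numpy()
    if "sex" in frame.columns:
        sx[off:] = frame["sex"].astype(object).to_numpy()

    remap = np.empty(n, dtype=np.int64)
    remap[order] = np.arange(n)
    ids_arr = np.array(ids, dtype=object)[order]
    new_parent = lambda p: np.where(p[order] >= 0, remap[np.maximum(p[order], 0)], UNKNOWN)
    return Pedigree(
        ids=ids_arr,
        sire=new_parent(sire_i),
        dam=new_parent(dam_i),
        birth_year=by[order],
        sex=sx[order],
    )


def _toposort(ids, sire, dam):
    n = len(ids)
    n_unres = np.zeros(n, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p >= 0:
                n_unres[i] += 1
                children[p].append(i)
    ready = [i for i in range(n) if n_unres[i] == 0]
    heapq.heapify(ready)
    order = []
    while ready:
        i = heapq.heappop(ready)
        order.append(i)
        for c in children[i]:
            n_unres[c] -= 1
            if n_unres[c] == 0:
                heapq.heappush(ready, c)
    if len(order) < n:
        chain = _find_cycle(ids, sire, dam, set(range(n)) - set(order))
        raise PedigreeError(f"pedigree cycle: {' -> '.join(map(str, chain))}")
    return np.array(order, dtype=np.int64)


def _find_cycle(ids, sire, dam, suspects):
    start = min(suspects)
    seen, chain, cur = {}, [], start
    while cur not in seen:
        seen[cur] = len(chain)
        chain.append(ids[cur])
        nxt = sire[cur] if sire[cur] in suspects else dam[cur]
        cur = nxt
    chain.append(ids[cur])
    return chain[seen[cur]:]


def read_pedigree(path) -> Pedigree:
    """Read a delimited pedigree file (animal,sire,dam[,birth_year,sex])."""
    frame = pd.read_csv(path, dtype={"animal": str, "sire": str, "dam": str},
                        sep=None, engine="python", comment="#")
    return sort_pedigree(frame)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def _mendelian_d(sire, dam, F):
    """Mendelian-sampling variance for every animal (parents' F known)."""
    d = np.ones(len(F))
    has_s, has_d = sire >= 0, dam >= 0
    both = has_s & has_d
    d[both] = 0.5 - 0.25 * (F[sire[both]] + F[dam[both]])
    one_s = has_s & ~has_d
    d[one_s] = 0.75 - 0.25 * F[sire[one_s]]
    one_d = has_d & ~has_s
    d[one_d] = 0.75 - 0.25 * F[dam[one_d]]
    return d


def inbreeding_meuwissen_luo(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients by the Meuwissen & Luo algorithm.

    For each animal the nonzero entries of its row of the Cholesky-style
    factor ``L`` (A = L D L') are accumulated by walking its ancestor set
    in decreasing topological index, giving ``a_ii = sum_j L_ij^2 d_j``
    and ``F_i = a_ii - 1`` with O(pedigree) memory.
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    D = np.ones(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            D[i] = 1.0
            continue
        if s < 0 or d < 0:
            p = s if s >= 0 else d
            D[i] = 0.75 - 0.25 * F[p]
            F[i] = 0.0  # unknown parent is an unrelated founder
            continue
        D[i] = 0.5 - 0.25 * (F[s] + F[d])
        # a_ii for animal i via its ancestor walk
        w = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            wj = w.pop(j, 0.0)
            if wj == 0.0:
                continue
            aii += wj * wj * D[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    if p not in w:
                        heapq.heappush(heap, -p)
                        w[p] = 0.0
                    w[p] += 0.5 * wj
        F[i] = aii - 1.0
    return F


def a_matrix_tabular(ped: Pedigree) -> np.ndarray:
    """Dense additive relationship matrix by the tabular (recursive) method.

    Small-pedigree oracle only; refuses pedigrees beyond the size guard.
    """
    n = len(ped)
    if n > _TABULAR_SIZE_GUARD:
        raise PedigreeError(
            f"tabular A is a test oracle; {n} animals exceeds guard {_TABULAR_SIZE_GUARD}")
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def a_inverse_sparse(ped: Pedigree, F: np.ndarray | None = None) -> sparse.csc_matrix:
    """Sparse inverse of A from Henderson's rules with inbreeding.

    Built directly from parent triplets and the Mendelian-sampling
    variances ``d_i``; never forms A itself.
    """
    if F is None:
        F = inbreeding_meuwissen_luo(ped)
    n = len(ped)
    d = _mendelian_d(ped.sire, ped.dam, np.asarray(F))
    alpha = 1.0 / d
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r); cols.append(c); vals.append(v)

    for i in range(n):
        a = alpha[i]
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p >= 0]
        add(i, i, a)
        for p in parents:
            add(i, p, -0.5 * a)
            add(p, i, -0.5 * a)
            for q in parents:
                add(p, q, 0.25 * a)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    Ainv.sum_duplicates()
    return Ainv


def a_logdet(ped: Pedigree, F: np.ndarray | None = None) -> float:
    """log|A| = sum of log Mendelian-sampling variances."""
    if F is None:
        F = inbreeding_meuwissen_luo(ped)
    return float(np.log(_mendelian_d(ped.sire, ped.dam, np.asarray(F))).sum())


def inbreeding_classes(F: np.ndarray, width: float = 0.02, n_classes: int = 15) -> np.ndarray:
    """Cluster F into equal-width classes, capping at the last class."""
    if width <= 0:
        raise ValueError("class width must be positive")
    cls = np.floor(np.asarray(F) / width).astype(np.int64)
    return np.minimum(cls, n_classes - 1)
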