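"""REML animal models: repeatability and random-regression fits.

The engine maximizes the restricted likelihood through Henderson's
mixed-model equations (MME).  Early iterations use EM-REML updates
(monotone, unconditionally stable); once the trajectory stabilizes the
step switches to average-information (AI) updates with step-halving back
toward the EM step whenever an AI proposal leaves the parameter space or
decreases the restricted log-likelihood.  The coefficient covariance of
the random-regression animal effect (``Ka``) is updated as a full
symmetric matrix; EM steps keep it positive definite by construction and
AI proposals are rejected unless their Cholesky factorization succeeds.

Supported random structures:

* scalar variance against an arbitrary sparse inverse structure
  (``sigma^2 A`` with sparse ``A^{-1}``, or i.i.d.);
* a Kronecker regression block ``Ka (x) A`` for the animal trajectory;
* heterogeneous residual classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, sparse

from . import legendre
from .pedigree import Pedigree, a_inverse_sparse, a_logdet, inbreeding_meuwissen_luo

logger = logging.getLogger(__name__)

MAX_ITER = 200
LOGL_TOL = 1e-8
PARAM_TOL = 1e-6
N_EM_WARMUP = 3
VAR_FLOOR_FRAC = 1e-8
KA_EIG_FLOOR_FRAC = 1e-4   # relative eigenvalue floor keeping Ka invertible


# ---------------------------------------------------------------------------
# random-effect descriptions

@dataclass
class ScalarEffect:
    """u ~ N(0, sigma^2 * S) with sparse S^{-1} (None means identity)."""

    name: str
    Z: sparse.csr_matrix
    Sinv: sparse.spmatrix | None = None
    logdet_S: float = 0.0

    @property
    def n_levels(self) -> int:
        return self.Z.shape[1]


@dataclass
class RegressionEffect:
    """Coefficient block u ~ N(0, Ka (x) A), coefficient-major layout."""

    name: str
    Z: sparse.csr_matrix              # n x (n_coef * q)
    Ainv: sparse.spmatrix
    logdet_A: float
    n_coef: int

    @property
    def q(self) -> int:
        return self.Z.shape[1] // self.n_coef


@dataclass
class Theta:
    """Variance parameters: one entry per effect plus residual classes."""

    scalars: dict                     # name -> float
    kas: dict                         # name -> (n_coef x n_coef) ndarray
    resid: np.ndarray                 # per residual class

    def copy(self) -> "Theta":
        return Theta({k: float(v) for k, v in self.scalars.items()},
                     {k: v.copy() for k, v in self.kas.items()},
                     self.resid.copy())


@dataclass
class FitResult:
    """REML estimates, solutions and fit diagnostics."""

    components: dict
    logL: float
    n_params: int
    n_records: int
    converged: bool
    n_iter: int
    fixed_effects: np.ndarray = field(default=None, repr=False)
    solutions: dict = field(default_factory=dict, repr=False)
    history: list = field(default_factory=list, repr=False)
    meta: dict = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# engine

class REMLModel:
    """Mixed model y = X b + sum_k Z_k u_k + e with class-wise residuals."""

    def __init__(self, y, X, effects, res_class=None, n_res_classes: int = 1,
                 max_iter: int = MAX_ITER, logl_tol: float = LOGL_TOL,
                 param_tol: float = PARAM_TOL, n_em_warmup: int = N_EM_WARMUP):
        self.y = np.asarray(y, dtype=float)
        n = self.y.size
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.X, self.dropped_cols = _drop_dependent_columns(X)
        self.effects = list(effects)
        self.res_class = (np.zeros(n, dtype=int) if res_class is None
                          else np.asarray(res_class, dtype=int))
        self.n_res_classes = n_res_classes
        self.class_masks = [self.res_class == c for c in range(n_res_classes)]
        self.class_n = np.array([m.sum() for m in self.class_masks], dtype=float)
        if np.any(self.class_n == 0):
            raise ValueError("every residual class must contain records")
        self.max_iter, self.logl_tol, self.param_tol = max_iter, logl_tol, param_tol
        self.n_em_warmup = n_em_warmup

        blocks = [sparse.csr_matrix(self.X)] + [e.Z for e in self.effects]
        self.T = sparse.hstack(blocks, format="csr")
        self.p = self.X.shape[1]
        self.offsets = []
        off = self.p
        for e in self.effects:
            self.offsets.append(off)
            off += e.Z.shape[1]
        self.dim = off
        self.TtT_pattern = None

    # -- parameter bookkeeping ------------------------------------------------

    def start_values(self, split=None) -> Theta:
        """Phenotypic-variance split starting values (documented default:
        40% animal, 30% permanent environment, 10% HYS, 20% residual)."""
        var_y = float(np.var(self.y, ddof=1))
        fracs = split or {}
        scalars, kas = {}, {}
        default = {"animal": 0.40, "pe": 0.30, "hys": 0.10}
        for e in self.effects:
            frac = fracs.get(e.name, default.get(e.name, 0.2))
            if isinstance(e, ScalarEffect):
                scalars[e.name] = frac * var_y
            else:
                # spread the animal fraction over the leading coefficient
                ka = np.diag(frac * var_y * 2.0 * 0.5 ** np.arange(e.n_coef))
                kas[e.name] = ka
        resid = np.full(self.n_res_classes, fracs.get("resid", 0.20) * var_y)
        return Theta(scalars, kas, resid)

    def _floor(self) -> float:
        return VAR_FLOOR_FRAC * float(np.var(self.y, ddof=1))

    def _theta_vec(self, th: Theta) -> np.ndarray:
        parts = []
        for e in self.effects:
            if isinstance(e, ScalarEffect):
                parts.append([th.scalars[e.name]])
            else:
                ka = th.kas[e.name]
                parts.append([ka[k, l] for k in range(e.n_coef) for l in range(k, e.n_coef)])
        parts.append(th.resid)
        return np.concatenate([np.asarray(p, dtype=float) for p in parts])

    def _vec_theta(self, vec: np.ndarray) -> Theta:
        scalars, kas = {}, {}
        i = 0
        for e in self.effects:
            if isinstance(e, ScalarEffect):
                scalars[e.name] = float(vec[i]); i += 1
            else:
                ka = np.zeros((e.n_coef, e.n_coef))
                for k in range(e.n_coef):
                    for l in range(k, e.n_coef):
                        ka[k, l] = ka[l, k] = vec[i]; i += 1
                kas[e.name] = ka
        return Theta(scalars, kas, vec[i:].copy())

    def _valid(self, th: Theta) -> bool:
        floor = self._floor()
        if any(v < floor for v in th.scalars.values()):
            return False
        if np.any(th.resid < floor):
            return False
        for ka in th.kas.values():
            try:
                linalg.cholesky(ka, lower=True)
            except linalg.LinAlgError:
                return False
        return True

    def _clip(self, th: Theta) -> Theta:
        floor = self._floor()
        th = th.copy()
        for k in th.scalars:
            th.scalars[k] = max(th.scalars[k], floor)
        th.resid = np.maximum(th.resid, floor)
        return th

    def _bend(self, th: Theta) -> Theta:
        """Project a proposal back into the parameter space: floor the
        scalar variances and clip Ka eigenvalues at a small positive value
        (REML 'bending'), keeping boundary-seeking fits moving."""
        th = self._clip(th)
        for name, ka in th.kas.items():
            vals, vecs = np.linalg.eigh(ka)
            lo = max(KA_EIG_FLOOR_FRAC * float(np.trace(ka)) / ka.shape[0], 1e-10)
            if vals.min() < lo:
                vals = np.maximum(vals, lo)
                th.kas[name] = (vecs * vals) @ vecs.T
        return th

    # -- likelihood pieces ----------------------------------------------------

    def _rinv(self, th: Theta) -> np.ndarray:
        return 1.0 / th.resid[self.res_class]

    def _assemble(self, th: Theta):
        rinv = self._rinv(th)
        Tw = self.T.multiply(rinv[:, None]).tocsr()
        C = (self.T.T @ Tw).toarray()
        logdet_G = 0.0
        for e, off in zip(self.effects, self.offsets):
            if isinstance(e, ScalarEffect):
                s2 = th.scalars[e.name]
                q = e.n_levels
                sl = slice(off, off + q)
                if e.Sinv is None:
                    idx = np.arange(off, off + q)
                    C[idx, idx] += 1.0 / s2
                else:
                    C[sl, sl] += (e.Sinv / s2).toarray()
                logdet_G += q * np.log(s2) + e.logdet_S
            else:
                ka = th.kas[e.name]
                kinv = linalg.inv(ka)
                q = e.q
                for k in range(e.n_coef):
                    for l in range(e.n_coef):
                        slk = slice(off + k * q, off + (k + 1) * q)
                        sll = slice(off + l * q, off + (l + 1) * q)
                        C[slk, sll] += (e.Ainv * kinv[k, l]).toarray()
                sign, ldka = np.linalg.slogdet(ka)
                logdet_G += q * ldka + e.n_coef * e.logdet_A
        rhs = self.T.T @ (rinv * self.y)
        logdet_R = float(np.sum(self.class_n * np.log(th.resid)))
        return C, rhs, rinv, logdet_G, logdet_R

    def loglik(self, th: Theta):
        """Restricted logL at th, or None when the MME are not PD."""
        try:
            C, rhs, rinv, ldG, ldR = self._assemble(th)
            cho = linalg.cho_factor(C, lower=True, check_finite=False)
        except (linalg.LinAlgError, ValueError):
            return None
        sol = linalg.cho_solve(cho, rhs, check_finite=False)
        return self._logl_from(cho, sol, rhs, rinv, ldG, ldR)

    def _logl_from(self, cho, sol, rhs, rinv, ldG, ldR):
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        ypy = float(self.y @ (rinv * self.y) - sol @ rhs)
        n, p = self.y.size, self.p
        return -0.5 * (ldR + ldG + logdet_C + ypy + (n - p) * np.log(2 * np.pi))

    # -- one full iteration ---------------------------------------------------

    def _stats(self, th: Theta):
        """Factorize, solve, invert; return everything one update needs."""
        C, rhs, rinv, ldG, ldR = self._assemble(th)
        cho = linalg.cho_factor(C, lower=True, check_finite=False)
        sol = linalg.cho_solve(cho, rhs, check_finite=False)
        logl = self._logl_from(cho, sol, rhs, rinv, ldG, ldR)
        Cinv = _chol_inverse(cho[0])
        ehat = self.y - self.T @ sol
        # per-record quadratic forms t_i' Cinv t_i
        TC = self.T @ Cinv
        tq = np.asarray(self.T.multiply(TC).sum(axis=1)).ravel()
        return {"cho": cho, "sol": sol, "rinv": rinv, "logl": logl,
                "Cinv": Cinv, "ehat": ehat, "tq": tq}

    def _em_and_score(self, th: Theta, st):
        """EM candidate and the REML score vector at th (shared traces)."""
        sol, Cinv = st["sol"], st["Cinv"]
        em = th.copy()
        score = []
        for e, off in zip(self.effects, self.offsets):
            if isinstance(e, ScalarEffect):
                s2 = th.scalars[e.name]
                q = e.n_levels
                sl = slice(off, off + q)
                u = sol[sl]
                if e.Sinv is None:
                    quad = float(u @ u)
                    tr = float(np.trace(Cinv[sl, sl]))
                else:
                    quad = float(u @ (e.Sinv @ u))
                    tr = float(np.sum(e.Sinv.multiply(Cinv[sl, sl])))
                em.scalars[e.name] = (quad + tr) / q
                score.append(-0.5 * (q / s2 - tr / s2 ** 2 - quad / s2 ** 2))
            else:
                ka = th.kas[e.name]
                kinv = linalg.inv(ka)
                q = e.q
                M = np.zeros((e.n_coef, e.n_coef))
                for k in range(e.n_coef):
                    uk = sol[off + k * q: off + (k + 1) * q]
                    for l in range(k, e.n_coef):
                        ul = sol[off + l * q: off + (l + 1) * q]
                        blk = Cinv[off + k * q: off + (k + 1) * q,
                                   off + l * q: off + (l + 1) * q]
                        M[k, l] = M[l, k] = (float(uk @ (e.Ainv @ ul))
                                             + float(np.sum(e.Ainv.multiply(blk))))
                em.kas[e.name] = M / q
                W = q * kinv - kinv @ M @ kinv
                for k in range(e.n_coef):
                    for l in range(k, e.n_coef):
                        mult = 1.0 if k == l else 2.0
                        score.append(-0.5 * mult * W[k, l])
        ehat, tq = st["ehat"], st["tq"]
        for c in range(self.n_res_classes):
            m = self.class_masks[c]
            s2 = th.resid[c]
            ee = float(ehat[m] @ ehat[m])
            trc = float(tq[m].sum())
            em.resid[c] = (ee + trc) / self.class_n[c]
            score.append(-0.5 * ((self.class_n[c] - trc / s2) / s2 - ee / s2 ** 2))
        return self._clip(em), np.array(score)

    def _ai_matrix(self, th: Theta, st):
        """AI_ij = 0.5 f_i' P f_j with the working vectors f_i = V_i P y."""
        sol, cho, rinv, ehat = st["sol"], st["cho"], st["rinv"], st["ehat"]
        fs = []
        for e, off in zip(self.effects, self.offsets):
            if isinstance(e, ScalarEffect):
                u = sol[off: off + e.n_levels]
                fs.append((e.Z @ u) / th.scalars[e.name])
            else:
                ka = th.kas[e.name]
                kinv = linalg.inv(ka)
                q = e.q
                U = sol[off: off + e.n_coef * q].reshape(e.n_coef, q)
                KU = kinv @ U
                for k in range(e.n_coef):
                    for l in range(k, e.n_coef):
                        E = np.zeros((e.n_coef, e.n_coef))
                        E[k, l] = E[l, k] = 1.0
                        fs.append(e.Z @ (E @ KU).ravel())
        for c in range(self.n_res_classes):
            f = np.zeros_like(self.y)
            m = self.class_masks[c]
            f[m] = ehat[m] / th.resid[c]
            fs.append(f)
        Fm = np.column_stack(fs)
        G = rinv[:, None] * Fm
        H = self.T.T @ G
        S = linalg.cho_solve(cho, H, check_finite=False)
        PF = G - rinv[:, None] * (self.T @ S)
        return 0.5 * (Fm.T @ PF)

    def fit(self, start: Theta | None = None, verbose: bool = False) -> tuple[Theta, FitResult]:
        th = start or self.start_values()
        th = self._clip(th)
        history = []
        converged = False
        st = self._stats(th)
        it = 0
        n_stalled = 0
        for it in range(1, self.max_iter + 1):
            logl = st["logl"]
            history.append(logl)
            em, score = self._em_and_score(th, st)
            cand = None
            if it > self.n_em_warmup:
                cand = self._ai_candidate(th, st, em, score, logl)
                if cand is None:
                    cand = self._overrelaxed_em(th, em, logl)
            new = self._bend(cand if cand is not None else em)
            vec_old, vec_new = self._theta_vec(th), self._theta_vec(new)
            denom = np.maximum(np.abs(vec_old), self._floor())
            dpar = float(np.max(np.abs(vec_new - vec_old) / denom))
            th = new
            st_new = self._stats(th)
            dlogl = st_new["logl"] - logl
            if verbose:
                logger.info("iter %d logL %.6f dlogL %.3g dpar %.3g", it, st_new["logl"], dlogl, dpar)
            st = st_new
            if abs(dlogl) < self.logl_tol * max(1.0, abs(logl)) and dpar < self.param_tol:
                converged = True
                break
            # secondary rule: a boundary-pinned component can keep drifting
            # in a likelihood-flat direction; three consecutive iterations
            # with a negligible logL gain count as converged.
            n_stalled = n_stalled + 1 if abs(dlogl) < 100 * self.logl_tol * max(1.0, abs(logl)) else 0
            if n_stalled >= 3:
                converged = True
                break
        history.append(st["logl"])
        return th, FitResult(
            components={}, logL=st["logl"], n_params=self._theta_vec(th).size,
            n_records=self.y.size, converged=converged, n_iter=it,
            fixed_effects=st["sol"][: self.p],
            solutions={"all": st["sol"]}, history=history)

    def _ai_candidate(self, th, st, em, score, logl0):
        """Damped average-information step (Levenberg-Marquardt style).

        Tries increasingly damped Newton directions and keeps the first
        one that stays in the parameter space and does not decrease the
        restricted logL; returns None to fall back to the EM step.
        """
        try:
            AI = self._ai_matrix(th, st)
        except (linalg.LinAlgError, ValueError):
            return None
        d = np.diag(AI).copy()
        d[d <= 0] = np.abs(d).max() + 1e-12
        vec0 = self._theta_vec(th)
        best = None
        ll_em = None
        for rho in (0.0, 0.01, 0.1, 1.0, 10.0):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", linalg.LinAlgWarning)
                    delta = linalg.solve(AI + rho * np.diag(d), score, assume_a="pos")
            except (linalg.LinAlgError, ValueError):
                continue
            cand = self._vec_theta(vec0 + delta)
            if not self._valid(cand):
                cand = self._bend(cand)
                if not self._valid(cand):
                    continue
            ll = self.loglik(cand)
            if ll is None or ll < logl0 - 1e-10 * max(1.0, abs(logl0)):
                continue
            if ll_em is None:
                ll_em = self.loglik(em)
            if ll_em is None or ll >= ll_em:
                return cand
            best = best if best is not None else cand
        return best

    def _overrelaxed_em(self, th, em, logl0):
        """Extrapolate along the EM direction (theta + a*(em - theta)).

        EM creeps along flat likelihood ridges; doubling the step often
        recovers most of the Newton gain at the cost of one factorization
        per trial.  Returns the best extrapolation that improves on both
        the current point and the plain EM step, else None.
        """
        v0, v1 = self._theta_vec(th), self._theta_vec(em)
        best, best_ll = None, self.loglik(em)
        if best_ll is None:
            return None
        for alpha in (2.0, 4.0):
            cand = self._bend(self._vec_theta(v0 + alpha * (v1 - v0)))
            if not self._valid(cand):
                continue
            ll = self.loglik(cand)
            if ll is not None and ll > best_ll:
                best, best_ll = cand, ll
        return best

    def solution_block(self, sol: np.ndarray, name: str) -> np.ndarray:
        for e, off in zip(self.effects, self.offsets):
            width = e.Z.shape[1]
            if e.name == name:
                return sol[off: off + width]
        raise KeyError(name)


def _drop_dependent_columns(X, tol: float = 1e-9):
    """QR-based removal of linearly dependent fixed-effect columns."""
    if X.shape[1] == 0:
        return X, []
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * diag.max()).sum()) if diag.size else 0
    keep = np.sort(piv[:rank])
    return X[:, keep], [c for c in range(X.shape[1]) if c not in keep]


def _chol_inverse(L: np.ndarray) -> np.ndarray:
    """Inverse of C from its lower Cholesky factor via LAPACK dpotri."""
    inv, info = linalg.lapack.dpotri(L, lower=1)
    if info != 0:
        raise linalg.LinAlgError(f"dpotri failed (info={info})")
    inv = np.tril(inv) + np.tril(inv, -1).T
    return inv


# ---------------------------------------------------------------------------
# design helpers

def _class_dummies(codes, drop_first: bool = True) -> np.ndarray:
    levels = pd.unique(pd.Series(codes).sort_values())
    start = 1 if (drop_first and len(levels) > 1) else 0
    cols = [(np.asarray(codes) == lv).astype(float) for lv in levels[start:]]
    return np.column_stack(cols) if cols else np.empty((len(codes), 0))


def _indicator(codes) -> tuple[sparse.csr_matrix, list]:
    levels = list(pd.unique(pd.Series(codes)))
    lut = {lv: j for j, lv in enumerate(levels)}
    n = len(codes)
    Z = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), [lut[c] for c in codes])),
        shape=(n, len(levels)))
    return Z, levels


def _animal_indicator(cows, ped: Pedigree) -> sparse.csr_matrix:
    n = len(cows)
    idx = [ped.loc(c) for c in cows]
    return sparse.csr_matrix((np.ones(n), (np.arange(n), idx)),
                             shape=(n, len(ped)))


def _regression_Z(cows, phi_rows, ped: Pedigree, n_coef: int) -> sparse.csr_matrix:
    """Coefficient-major Z for the animal regression block."""
    n = len(cows)
    q = len(ped)
    idx = np.array([ped.loc(c) for c in cows])
    rows = np.tile(np.arange(n), n_coef)
    cols = np.concatenate([k * q + idx for k in range(n_coef)])
    vals = np.concatenate([phi_rows[:, k] for k in range(n_coef)])
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n_coef * q))


# ---------------------------------------------------------------------------
# public model fits

def fit_repeatability(table: pd.DataFrame, ped: Pedigree,
                      ainv: sparse.spmatrix | None = None,
                      F: np.ndarray | None = None,
                      start: Theta | None = None,
                      **engine_kw) -> FitResult:
    """Repeatability animal model for Re.

    y = mu + Cn class + Fc class + animal (A) + permanent environment
    + HYS + e, all records treated as one trait with constant components.
    Returns variance components, h2, repeatability and per-animal EGVs.
    """
    if F is None:
        F = inbreeding_meuwissen_luo(ped)
    if ainv is None:
        ainv = a_inverse_sparse(ped, F)
    ld_a = a_logdet(ped, F)

    y = table["re"].to_numpy(dtype=float)
    X = np.column_stack([
        np.ones(len(table)),
        _class_dummies(table["cn"].to_numpy()),
        _class_dummies(table["fc_class"].to_numpy()) if "fc_class" in table
        else np.empty((len(table), 0)),
    ])
    Z_pe, pe_levels = _indicator(table["cow"])
    Z_hys, hys_levels = _indicator(table["hys"])
    effects = [
        ScalarEffect("animal", _animal_indicator(table["cow"], ped), ainv, ld_a),
        ScalarEffect("pe", Z_pe),
        ScalarEffect("hys", Z_hys),
    ]
    model = REMLModel(y, X, effects, **engine_kw)
    th, res = model.fit(start=start)
    sol = res.solutions["all"]
    total = th.scalars["animal"] + th.scalars["pe"] + th.scalars["hys"] + th.resid[0]
    res.components = {
        "animal": th.scalars["animal"], "pe": th.scalars["pe"],
        "hys": th.scalars["hys"], "residual": th.resid[0], "total": total,
    }
    res.solutions = {
        "egv": pd.Series(model.solution_block(sol, "animal"), index=ped.ids),
        "pe": pd.Series(model.solution_block(sol, "pe"), index=pe_levels),
        "hys": pd.Series(model.solution_block(sol, "hys"), index=hys_levels),
    }
    res.meta = {
        "model": "rep",
        "h2": th.scalars["animal"] / total,
        "repeatability": (th.scalars["animal"] + th.scalars["pe"]) / total,
        "theta": th,
    }
    return res


def fit_rrm(table: pd.DataFrame, ped: Pedigree, r: int = 2,
            n_res_classes: int = 6, n_fc_classes: int = 16,
            fc_class_width: float = 0.02,
            ainv: sparse.spmatrix | None = None,
            F: np.ndarray | None = None,
            start: Theta | None = None,
            **engine_kw) -> FitResult:
    """Random-regression animal model of order ``r`` on the Cn scale.

    Fixed Legendre regressions on calving number and on the inbreeding
    class midpoint; random order-``r`` animal regression with coefficient
    covariance ``Ka (x) A``; scalar permanent-environment and HYS effects;
    residual variance in ``n_res_classes`` classes of min(Cn, 6).
    """
    if r not in (1, 2):
        raise ValueError("random-regression order must be 1 or 2")
    if F is None:
        F = inbreeding_meuwissen_luo(ped)
    if ainv is None:
        ainv = a_inverse_sparse(ped, F)
    ld_a = a_logdet(ped, F)

    y = table["re"].to_numpy(dtype=float)
    cn = table["cn"].to_numpy(dtype=float)
    x_cn = legendre.standardize_cn(cn)
    Phi_cn = legendre.legendre_basis(x_cn, r)

    fc_cls = (table["fc_class"].to_numpy(dtype=float) if "fc_class" in table
              else np.zeros(len(table)))
    mids = (fc_cls + 0.5) * fc_class_width
    span = n_fc_classes * fc_class_width
    x_fc = np.clip(-1.0 + 2.0 * mids / span, -1.0, 1.0)
    Phi_fc = legendre.legendre_basis(x_fc, r)[:, 1:]   # phi_0 duplicates the Cn intercept

    X = np.column_stack([Phi_cn, Phi_fc])
    Z_pe, pe_levels = _indicator(table["cow"])
    Z_hys, hys_levels = _indicator(table["hys"])
    res_class = (np.minimum(table["cn"].to_numpy(dtype=int), n_res_classes) - 1
                 if n_res_classes > 1 else None)
    effects = [
        RegressionEffect("animal", _regression_Z(table["cow"], Phi_cn, ped, r + 1),
                         ainv, ld_a, r + 1),
        ScalarEffect("pe", Z_pe),
        ScalarEffect("hys", Z_hys),
    ]
    model = REMLModel(y, X, effects, res_class=res_class,
                      n_res_classes=n_res_classes, **engine_kw)
    th, res = model.fit(start=start)
    sol = res.solutions["all"]
    q = len(ped)
    coefs = model.solution_block(sol, "animal").reshape(r + 1, q).T
    basis = legendre.Basis.on_calvings(r)
    res.components = {
        "Ka": th.kas["animal"], "pe": th.scalars["pe"], "hys": th.scalars["hys"],
        "residual": th.resid.copy(),
    }
    res.solutions = {
        "coefficients": pd.DataFrame(coefs, index=ped.ids,
                                     columns=[f"a{k}" for k in range(r + 1)]),
        "egv": pd.DataFrame(legendre.egv_trajectory(coefs, basis.Phi), index=ped.ids,
                            columns=[f"cn{int(c)}" for c in basis.points]),
        "pe": pd.Series(model.solution_block(sol, "pe"), index=pe_levels),
        "hys": pd.Series(model.solution_block(sol, "hys"), index=hys_levels),
    }
    res.meta = {"model": f"ra{r}", "order": r, "basis": basis, "theta": th}
    return res


def trajectory_table(res: FitResult) -> pd.DataFrame:
    """Per-calving genetic variance, total variance and h2 from an RA fit."""
    Ka = res.components["Ka"]
    basis: legendre.Basis = res.meta["basis"]
    sp2, shys2 = res.components["pe"], res.components["hys"]
    resid = res.components["residual"]
    rows = []
    for i, cn_pt in enumerate(basis.points):
        cls = min(int(cn_pt), len(resid)) - 1
        g = legendre.covfun_variance(Ka, basis.Phi[i])
        tot = g + sp2 + shys2 + resid[cls]
        rows.append({"cn": int(cn_pt), "genetic_var": g, "total_var": tot,
                     "h2": g / tot})
    return pd.DataFrame(rows)


def information_criteria(logL: float, k: int, n: int | None = None) -> dict:
    """AIC = -2logL + 2k; BIC = -2logL + k ln n (n = number of records)."""
    out = {"AIC": -2.0 * logL + 2.0 * k}
    if n:
        out["BIC"] = -2.0 * logL + k * np.log(n)
    return out


def relative_importance(components: dict) -> dict:
    """Each variance component as % of the total (sums to 100)."""
    items = {k: v for k, v in components.items() if k != "total" and np.isscalar(v)}
    total = sum(items.values())
    if total <= 0:
        raise ValueError("total variance must be positive")
    return {k: 100.0 * v / total for k, v in items.items()}


def bootstrap_components(table: pd.DataFrame, ped: Pedigree, n_boot: int = 20,
                         seed: int = 0, model: str = "rep", **fit_kw) -> pd.DataFrame:
    """Cow-level bootstrap of the variance components (uncertainty hook).

    Resamples cows with replacement, refits, and returns one row of
    scalar components per replicate (for RA fits, Ka is reported through
    the per-calving genetic variances).  A cow drawn twice keeps one
    animal/pe level (the pedigree link cannot be duplicated), so the
    replicate spread is an approximate, slightly conservative measure of
    uncertainty.  Analytic standard errors are out of scope; this is the
    supported route to uncertainty statements.
    """
    rng = np.random.default_rng(seed)
    cows = table["cow"].unique()
    rows = []
    for b in range(n_boot):
        chosen = rng.choice(cows, size=len(cows), replace=True)
        boot = pd.concat([table[table["cow"] == c] for c in chosen],
                         ignore_index=True)
        if model == "rep":
            res = fit_repeatability(boot, ped, **fit_kw)
            rows.append({k: res.components[k]
                         for k in ("animal", "pe", "hys", "residual")})
        else:
            res = fit_rrm(boot, ped, **fit_kw)
            basis = res.meta["basis"]
            g = np.diag(basis.Phi @ res.components["Ka"] @ basis.Phi.T)
            row = {f"genetic_var_cn{i + 1}": g[i] for i in range(len(g))}
            row.update({"pe": res.components["pe"], "hys": res.components["hys"]})
            rows.append(row)
    return pd.DataFrame(rows)


def genetic_trend(egv: pd.Series, birth_year: pd.Series) -> pd.DataFrame:
    """Mean EGV by birth year with counts and SDs (genetic-progress curve)."""
    df = pd.DataFrame({"egv": egv, "year": pd.Series(birth_year).reindex(egv.index)})
    df = df.dropna()
    g = df.groupby("year")["egv"]
    return pd.DataFrame({"mean_egv": g.mean(), "sd_egv": g.std(ddof=1),
                         "n": g.size()}).reset_index()
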