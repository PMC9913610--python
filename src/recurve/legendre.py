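"""Legendre basis on the calving-number scale and covariance-function arithmetic.

A random-regression animal model expresses the additive-genetic effect of
animal *m* at calving *i* as ``phi_i . a_m`` where ``phi_i`` evaluates the
first ``r+1`` *normalized* Legendre polynomials at the standardized calving
number and ``a_m`` is the animal's coefficient vector.  With coefficient
covariance ``Ka`` the implied genetic variance at calving *i* is the
quadratic form ``phi_i Ka phi_i'``, from which point heritabilities,
genetic correlations and per-calving breeding values (EGVs) follow.

Normalized polynomials (``sqrt((2k+1)/2) P_k``) are used throughout; this
rescales ``Ka`` but leaves every derived quantity (``Phi Ka Phi'``, h2,
rg, EGV) unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

CN_MIN, CN_MAX = 1, 9


def standardize_cn(cn, cn_min: float = CN_MIN, cn_max: float = CN_MAX):
    """Map calving number onto [-1, 1]; values outside the scale are an error."""
    if not cn_min < cn_max:
        raise ValueError("cn_min must be < cn_max")
    cn = np.asarray(cn, dtype=float)
    if np.any(cn < cn_min) or np.any(cn > cn_max):
        raise ValueError(f"calving number outside [{cn_min}, {cn_max}]; no extrapolation")
    return -1.0 + 2.0 * (cn - cn_min) / (cn_max - cn_min)


def legendre_basis(x, r: int) -> np.ndarray:
    """Rows of normalized Legendre polynomial values phi_0..phi_r at x.

    phi_k(x) = sqrt((2k+1)/2) * P_k(x), orthonormal on [-1, 1].
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(np.abs(x) > 1 + 1e-12):
        raise ValueError("basis evaluated outside [-1, 1]")
    cols = []
    for k in range(r + 1):
        coef = np.zeros(k + 1)
        coef[k] = 1.0
        cols.append(np.sqrt((2 * k + 1) / 2.0) * npleg.legval(x, coef))
    return np.column_stack(cols)


@dataclass(frozen=True)
class Basis:
    """Basis matrix over a fixed set of evaluation points."""

    order: int
    scale: tuple
    points: np.ndarray
    Phi: np.ndarray

    @classmethod
    def on_calvings(cls, r: int, cn_min: int = CN_MIN, cn_max: int = CN_MAX) -> "Basis":
        pts = np.arange(cn_min, cn_max + 1, dtype=float)
        x = standardize_cn(pts, cn_min, cn_max)
        return cls(order=r, scale=(cn_min, cn_max), points=pts, Phi=legendre_basis(x, r))


def _check_ka(Ka: np.ndarray) -> np.ndarray:
    Ka = np.asarray(Ka, dtype=float)
    if Ka.ndim != 2 or Ka.shape[0] != Ka.shape[1]:
        raise ValueError("Ka must be square")
    if not np.allclose(Ka, Ka.T, atol=1e-10 * (1 + np.abs(Ka).max())):
        raise ValueError("Ka must be symmetric")
    return Ka


def covfun_variance(Ka: np.ndarray, phi_i: np.ndarray) -> float:
    """Genetic variance at one trajectory point: phi_i Ka phi_i'."""
    Ka = _check_ka(Ka)
    phi_i = np.asarray(phi_i, dtype=float).ravel()
    return float(phi_i @ Ka @ phi_i)


def covfun_matrix(Ka: np.ndarray, Phi: np.ndarray) -> np.ndarray:
    """Implied genetic covariance matrix over all points: Phi Ka Phi'."""
    Ka = _check_ka(Ka)
    return Phi @ Ka @ Phi.T


def trajectory_h2(Ka, phi_i, sigma_p2: float, sigma_hys2: float, sigma_e2_i: float) -> float:
    """Point heritability g_i / (g_i + sigma_p2 + sigma_hys2 + sigma_e2_i)."""
    g = covfun_variance(Ka, phi_i)
    denom = g + sigma_p2 + sigma_hys2 + sigma_e2_i
    if denom <= 0:
        raise ValueError("total variance must be positive")
    return g / denom


def genetic_correlation(Ka, phi_i, phi_j) -> float:
    """Genetic correlation between the trait expressed at two points."""
    gi = covfun_variance(Ka, phi_i)
    gj = covfun_variance(Ka, phi_j)
    if gi <= 0 or gj <= 0:
        return np.nan
    gij = float(np.asarray(phi_i).ravel() @ _check_ka(Ka) @ np.asarray(phi_j).ravel())
    return gij / np.sqrt(gi * gj)


def genetic_correlation_matrix(Ka, Phi) -> np.ndarray:
    G = covfun_matrix(Ka, Phi)
    sd = np.sqrt(np.diag(G))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = G / np.outer(sd, sd)
    return R


def egv_trajectory(a_m: np.ndarray, Phi: np.ndarray) -> np.ndarray:
    """Per-point EGVs for one animal (or a stack of animals): Phi a_m'.

    ``a_m`` may be a single coefficient vector or an (n_animals, r+1)
    matrix; the result has one column per trajectory point.
    """
    a = np.atleast_2d(np.asarray(a_m, dtype=float))
    return a @ np.asarray(Phi).T
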