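"""Unidimensionality assessment for ordinal item batteries.

Three stages, mirroring common practice for Rasch assumption checking:

1. polychoric correlations between the ordered-categorical items (two-step
   maximum likelihood per pair, thresholds from the marginal proportions);
2. parallel analysis to decide how many factors the correlation matrix
   supports beyond chance;
3. an exploratory bi-factor solution (Schmid-Leiman orthogonalization of a
   hierarchical factor model): the scale counts as unidimensional when every
   item loads more on the general factor than on any specific factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal, norm

from .responses import MISSING, ResponseMatrix

__all__ = [
    "polychoric_corr",
    "polychoric_matrix",
    "parallel_analysis",
    "bifactor_check",
    "BifactorResult",
]

_INF = 8.0  # effective infinity for latent thresholds


def _cell_probs(rho: float, cuts_x: np.ndarray, cuts_y: np.ndarray) -> np.ndarray:
    """Bivariate-normal rectangle probabilities for a contingency table."""
    cx = np.concatenate(([-_INF], cuts_x, [_INF]))
    cy = np.concatenate(([-_INF], cuts_y, [_INF]))
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    cdf = mvn.cdf(pts).reshape(gx.shape)
    probs = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    return np.clip(probs, 1e-12, None)


def polychoric_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step ML polychoric correlation of two ordinal variables.

    Thresholds are fixed at the normal quantiles of the marginal cumulative
    proportions; the correlation maximizes the bivariate-normal likelihood of
    the observed contingency table.
    """
    ok = (x != MISSING) & (y != MISSING)
    x, y = np.asarray(x)[ok], np.asarray(y)[ok]
    if len(x) == 0:
        raise ValueError("no pairwise-complete observations")
    xc = np.unique(x)
    yc = np.unique(y)
    if len(xc) < 2 or len(yc) < 2:
        raise ValueError("both variables need at least 2 observed categories")
    table = np.zeros((len(xc), len(yc)))
    for i, a in enumerate(xc):
        for j, b in enumerate(yc):
            table[i, j] = np.sum((x == a) & (y == b))
    cuts_x = norm.ppf(np.cumsum(table.sum(axis=1))[:-1] / table.sum())
    cuts_y = norm.ppf(np.cumsum(table.sum(axis=0))[:-1] / table.sum())

    def nll(rho: float) -> float:
        return -float(np.sum(table * np.log(_cell_probs(rho, cuts_x, cuts_y))))

    res = minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-5})
    return float(res.x)


def polychoric_matrix(data: ResponseMatrix) -> pd.DataFrame:
    """Item-by-item polychoric correlation matrix.

    Items with a single observed category are excluded with a warning.  The
    pairwise-assembled matrix is repaired to the nearest positive
    semi-definite matrix (eigenvalue clipping) if needed, with a warning.
    """
    keep, ids = [], []
    for j, item_id in enumerate(data.item_ids):
        col = data.values[:, j]
        if len(np.unique(col[col != MISSING])) < 2:
            warnings.warn(f"{item_id}: single observed category, excluded")
            continue
        keep.append(j)
        ids.append(item_id)
    if len(keep) < 2:
        raise ValueError("fewer than 2 usable items")
    p = len(keep)
    R = np.eye(p)
    for a in range(p):
        for b in range(a + 1, p):
            R[a, b] = R[b, a] = polychoric_corr(data.values[:, keep[a]], data.values[:, keep[b]])
    eigval = np.linalg.eigvalsh(R)
    if eigval.min() < -1e-8:
        warnings.warn("polychoric matrix not PSD; applying nearest-PSD repair")
        w, v = np.linalg.eigh(R)
        R = v @ np.diag(np.clip(w, 1e-8, None)) @ v.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return pd.DataFrame(R, index=ids, columns=ids)


def parallel_analysis(
    corr: np.ndarray | pd.DataFrame,
    n_obs: int,
    reps: int = 100,
    quantile: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> int:
    """Number of factors retained by (principal-component) parallel analysis.

    Observed eigenvalues are compared position by position with the chosen
    quantile of eigenvalues from ``reps`` random standard-normal datasets of
    the same shape; counting stops at the first observed eigenvalue that does
    not beat chance.  Pure-noise data therefore yields 0.
    """
    R = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr)
    p = R.shape[0]
    if R.shape != (p, p):
        raise ValueError("corr must be square")
    if reps < 20:
        warnings.warn(f"parallel analysis with reps={reps} < 20 is unstable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = np.sort(np.linalg.eigvalsh(R))[::-1]
    sim = np.empty((reps, p))
    for r in range(reps):
        X = rng.standard_normal((n_obs, p))
        sim[r] = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    thresh = np.quantile(sim, quantile, axis=0)
    n = 0
    for k in range(p):
        if obs[k] > thresh[k]:
            n += 1
        else:
            break
    return n


# ---------------------------------------------------------------------------
# exploratory factor machinery (principal-axis factoring + rotations)

def _paf(R: np.ndarray, n_factors: int, max_iter: int = 200, tol: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Principal-axis factoring; returns (loadings, heywood_flag)."""
    p = R.shape[0]
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    h2 = np.clip(smc, 0.05, 0.998)
    heywood = False
    L = np.zeros((p, n_factors))
    for _ in range(max_iter):
        Rh = R.copy()
        np.fill_diagonal(Rh, h2)
        w, v = np.linalg.eigh(Rh)
        idx = np.argsort(w)[::-1][:n_factors]
        L = v[:, idx] * np.sqrt(np.clip(w[idx], 0, None))
        new_h2 = np.sum(L**2, axis=1)
        if np.any(new_h2 > 1.0):
            heywood = True
            new_h2 = np.clip(new_h2, None, 0.998)
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            break
        h2 = new_h2
    return L, heywood


def _varimax(L: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    p, k = L.shape
    if k < 2:
        return L
    Rm = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = L @ Rm
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - (Lr * np.mean(Lr**2, axis=0)))
        )
        Rm = u @ vt
        d_new = np.sum(s)
        if d_new < d * (1 + tol):
            break
        d = d_new
    return L @ Rm


def _promax(L: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique rotation; returns (pattern matrix, factor correlations)."""
    X = _varimax(L)
    if X.shape[1] < 2:
        return X, np.eye(X.shape[1])
    Q = X * np.abs(X) ** (power - 1)  # power target preserving signs
    U, *_ = np.linalg.lstsq(X, Q, rcond=None)
    U = U @ np.diag(np.sqrt(np.diag(np.linalg.inv(U.T @ U))))
    pattern = X @ U
    phi = np.linalg.inv(U.T @ U)
    d = np.sqrt(np.diag(phi))
    phi = phi / np.outer(d, d)
    # orient each factor positively (sign indeterminacy)
    signs = np.sign(pattern.sum(axis=0))
    signs[signs == 0] = 1.0
    pattern = pattern * signs
    phi = phi * np.outer(signs, signs)
    return pattern, phi


@dataclass
class BifactorResult:
    """Schmid-Leiman bi-factor loadings and the unidimensionality verdict."""

    n_factors: int
    general_loadings: pd.Series
    specific_loadings: pd.Series  # per item, max |loading| over specific factors
    unidimensional: bool
    heywood: bool = False


def bifactor_check(
    corr: np.ndarray | pd.DataFrame,
    n_specific: int,
) -> BifactorResult:
    """Exploratory bi-factor check via Schmid-Leiman orthogonalization.

    First-order factors are extracted by principal-axis factoring with promax
    rotation; a single second-order (general) factor is fitted to the factor
    correlations; the Schmid-Leiman transform yields orthogonal general and
    specific loadings.  ``unidimensional`` is true when every item's general
    loading exceeds its largest specific loading (in absolute value).  With
    ``n_specific = 1`` the single factor *is* the general factor and the
    specific loadings are zero.  Heywood cases are reported via the result
    flag, not silently hidden.
    """
    R = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, dtype=float)
    ids = list(corr.columns) if isinstance(corr, pd.DataFrame) else [f"item{j}" for j in range(R.shape[0])]
    p = R.shape[0]
    if p < 2:
        raise ValueError("bi-factor analysis needs at least 2 items")
    if n_specific < 1:
        raise ValueError("n_specific must be >= 1")
    n_specific = min(n_specific, p // 2 if p // 2 >= 1 else 1)
    if n_specific == 1:
        L, heywood = _paf(R, 1)
        general = np.abs(L[:, 0])
        specific = np.zeros(p)
    else:
        L1, hey1 = _paf(R, n_specific)
        pattern, phi = _promax(L1)
        g2, hey2 = _paf(phi, 1)  # second-order general factor on factor corrs
        g = g2[:, 0]
        general = np.abs(pattern @ g)
        u = np.sqrt(np.clip(1.0 - g**2, 0.0, 1.0))
        specific_full = pattern * u[None, :]
        specific = np.max(np.abs(specific_full), axis=1)
        heywood = hey1 or hey2
    gl = pd.Series(general, index=ids, name="general")
    sl = pd.Series(specific, index=ids, name="specific_max")
    return BifactorResult(
        n_factors=n_specific,
        general_loadings=gl,
        specific_loadings=sl,
        unidimensional=bool(np.all(gl.to_numpy() > sl.to_numpy())),
        heywood=heywood,
    )
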