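"""Conditional maximum-likelihood (CML) calibration of the Partial Credit Model.

CML estimates item thresholds by conditioning on each person's sum score, the
sufficient statistic for ability, so the person parameters drop out of the
likelihood entirely and the threshold estimates do not depend on the ability
distribution.  The conditional likelihood is built from polytomous elementary
symmetric functions, evaluated in log space by the summation (convolution)
recursion, which is numerically stable for instruments far larger than the
11-item case this package targets.

Writing ``eta_ik = sum_{j<=k} tau_ij`` for the cumulative category parameters,
a response pattern ``x`` with sum score ``r`` has conditional probability

    P(x | r) = exp(-sum_i eta_{i, x_i}) / gamma_r,

where ``gamma_r`` is the elementary symmetric function of order ``r``:
the sum of ``exp(-sum_i eta_{i, x_i})`` over all patterns with sum ``r``.
Persons with extreme sum scores (0 or the maximum) carry no information and
are dropped.  The gradient is the classic observed-minus-expected category
count, with expectations computed from leave-one-item-out symmetric
functions.

CML is identified only up to an additive constant on the ability scale; the
reported solution constrains the mean of all thresholds to zero and records
the constant removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .calibration import ItemCalibration
from .responses import MISSING, ResponseMatrix

__all__ = ["CmlResult", "calibrate_items_cml", "CategoryCollapseWarning", "EstimationError"]


class CategoryCollapseWarning(UserWarning):
    """A never-observed category was collapsed before estimation."""


class EstimationError(RuntimeError):
    """CML optimisation failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_items: list[ItemCalibration] | None = None):
        super().__init__(message)
        self.last_items = last_items


@dataclass
class CmlResult:
    """Outcome of a CML calibration."""

    items: list[ItemCalibration]  # mean-zero-centred thresholds with SEs
    converged: bool
    n_iterations: int
    gradient_norm: float
    log_likelihood: float
    normalization_shift: float  # constant subtracted to centre the thresholds
    n_persons_used: int  # interior-score persons entering the likelihood
    collapsed: dict[str, list[int]] = field(default_factory=dict)  # applied category maps


def _log_esf(log_a: list[np.ndarray]) -> np.ndarray:
    """Log elementary symmetric functions by log-space convolution.

    ``log_a[i][k]`` is ``-eta_ik`` for item i, ``k = 0..m_i`` (``eta_i0 = 0``).
    Returns ``log gamma_r`` for ``r = 0..sum m_i``.
    """
    out = np.array([0.0])
    for la in log_a:
        m = len(la) - 1
        new = np.full(len(out) + m, -np.inf)
        for k in range(m + 1):
            new[k : k + len(out)] = np.logaddexp(new[k : k + len(out)], out + la[k])
        out = new
    return out


def _log_esf_loo(log_a: list[np.ndarray]) -> list[np.ndarray]:
    """Leave-one-item-out log ESFs via prefix/suffix convolutions."""
    n = len(log_a)
    prefix: list[np.ndarray] = [np.array([0.0])]
    for la in log_a[:-1]:
        prefix.append(_combine(prefix[-1], la))
    suffix: list[np.ndarray] = [np.array([0.0])]
    for la in reversed(log_a[1:]):
        suffix.append(_combine(suffix[-1], la))
    suffix = suffix[::-1]
    return [_merge(prefix[i], suffix[i]) for i in range(n)]


def _combine(log_gamma: np.ndarray, la: np.ndarray) -> np.ndarray:
    m = len(la) - 1
    new = np.full(len(log_gamma) + m, -np.inf)
    for k in range(m + 1):
        new[k : k + len(log_gamma)] = np.logaddexp(new[k : k + len(log_gamma)], log_gamma + la[k])
    return new


def _merge(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    new = np.full(len(a) + len(b) - 1, -np.inf)
    for k in range(len(b)):
        new[k : k + len(a)] = np.logaddexp(new[k : k + len(a)], a + b[k])
    return new


def _collapse_unobserved(
    values: np.ndarray, on_unobserved: str
) -> tuple[np.ndarray, list[int], dict[int, list[int]]]:
    """Remap each item's categories to the contiguous observed range.

    Returns the remapped matrix, per-item max categories, and the applied
    maps (column index -> original->new category vector) where collapsing
    was needed.
    """
    vals = values.copy()
    maxcats: list[int] = []
    applied: dict[int, list[int]] = {}
    for j in range(vals.shape[1]):
        col = vals[:, j]
        obs = np.unique(col[col != MISSING])
        if len(obs) < 2:
            raise ValueError(f"item column {j} has fewer than 2 observed categories")
        top = int(obs.max())
        cmap = np.zeros(top + 1, dtype=np.int64)
        nxt = 0
        for c in range(top + 1):
            cmap[c] = nxt
            if c in obs:
                nxt += 1
        cmap = np.minimum(cmap, nxt - 1)
        if len(obs) != top + 1 or obs.min() != 0:
            if on_unobserved == "error":
                raise ValueError(
                    f"item column {j} has never-observed categories {sorted(set(range(top + 1)) - set(obs.tolist()))}"
                )
            warnings.warn(
                f"item column {j}: collapsing never-observed categories", CategoryCollapseWarning
            )
            applied[j] = cmap.tolist()
            mask = col != MISSING
            col[mask] = cmap[col[mask]]
        maxcats.append(int(col[col != MISSING].max()))
    return vals, maxcats, applied


def calibrate_items_cml(
    data: ResponseMatrix,
    max_iter: int = 200,
    gtol: float = 1e-8,
    on_unobserved: str = "collapse",
) -> CmlResult:
    """Calibrate PCM thresholds by conditional maximum likelihood.

    Persons with extreme sum scores are dropped internally (they contribute a
    constant to the conditional likelihood); persons with any missing
    response are also excluded from calibration, keeping a single
    score-group structure.  Thresholds are reported centred to overall mean
    zero together with the centring constant.

    ``on_unobserved`` controls never-observed categories: ``"collapse"``
    (default, with a :class:`CategoryCollapseWarning`) or ``"error"``.
    """
    if data.n_items < 2:
        raise ValueError("at least 2 items required for CML calibration")
    complete = ~data.missing_mask.any(axis=1)
    vals = data.values[complete]
    if vals.shape[0] == 0:
        raise ValueError("no complete response patterns available")
    vals, maxcats, applied = _collapse_unobserved(vals, on_unobserved)
    max_sum = int(sum(maxcats))
    sums = vals.sum(axis=1)
    interior = (sums > 0) & (sums < max_sum)
    vals = vals[interior]
    sums = sums[interior]
    n_used = vals.shape[0]
    if n_used == 0:
        raise ValueError("no interior-score persons: calibration is impossible")

    n_items = vals.shape[1]
    # sufficient statistics: category counts per item, persons per sum score
    counts = [np.bincount(vals[:, j], minlength=maxcats[j] + 1) for j in range(n_items)]
    m_r = np.bincount(sums, minlength=max_sum + 1).astype(float)
    slices = []
    off = 0
    for m in maxcats:
        slices.append(slice(off, off + m))
        off += m
    n_par = off

    def unpack(x: np.ndarray) -> list[np.ndarray]:
        """tau vector -> per-item -eta arrays (with leading 0 for k=0)."""
        out = []
        for sl in slices:
            eta = np.cumsum(x[sl])
            out.append(np.concatenate(([0.0], -eta)))
        return out

    def nll_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        log_a = unpack(x)
        log_gamma = _log_esf(log_a)
        loo = _log_esf_loo(log_a)
        # nll = sum_i sum_k n_ik * eta_ik + sum_r m_r * log gamma_r
        nll = float(np.dot(m_r, log_gamma))
        grad_eta = []  # d nll / d eta_ik for k = 1..m_i
        for j in range(n_items):
            eta_terms = -log_a[j]  # eta_ik, k = 0..m
            nll += float(np.dot(counts[j], eta_terms))
            g = np.empty(maxcats[j])
            for k in range(1, maxcats[j] + 1):
                # E[count of category k on item j] summed over score groups:
                # sum_r m_r * exp(-eta_jk + log gamma^(-j)_{r-k} - log gamma_r)
                lg = np.full(max_sum + 1, -np.inf)
                lo, hi = k, k + len(loo[j]) - 1
                lg[lo : hi + 1] = log_a[j][k] + loo[j]
                with np.errstate(invalid="ignore"):
                    expc = np.where(m_r > 0, m_r * np.exp(lg - log_gamma), 0.0)
                g[k - 1] = counts[j][k] - np.nansum(expc)
            grad_eta.append(g)
        # chain rule: d/d tau_ij = sum_{k >= j} d/d eta_ik
        grad = np.empty(n_par)
        for j, sl in enumerate(slices):
            grad[sl] = np.cumsum(grad_eta[j][::-1])[::-1]
        return nll, grad

    x0 = np.zeros(n_par)
    res = minimize(
        nll_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-14},
    )
    gnorm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) or gnorm < 1e-5
    shift = float(np.mean(res.x))
    centred = res.x - shift

    ses = _threshold_ses(nll_grad, res.x, n_par)

    items_out: list[ItemCalibration] = []
    for j, sl in enumerate(slices):
        items_out.append(
            ItemCalibration(
                item_id=data.item_ids[j],
                thresholds=tuple(centred[sl]),
                threshold_ses=tuple(ses[sl]) if ses is not None else None,
            )
        )
    result = CmlResult(
        items=items_out,
        converged=converged,
        n_iterations=int(res.nit),
        gradient_norm=gnorm,
        log_likelihood=-float(res.fun),
        normalization_shift=shift,
        n_persons_used=int(n_used),
        collapsed={data.item_ids[j]: m for j, m in applied.items()},
    )
    if not converged:
        raise EstimationError(
            f"CML did not converge in {max_iter} iterations (|grad| = {gnorm:.3g})",
            last_items=items_out,
        )
    return result


def _threshold_ses(nll_grad, x_opt: np.ndarray, n_par: int) -> np.ndarray | None:
    """SEs from the observed information (finite differences of the gradient).

    The conditional likelihood is flat along the overall-shift direction; the
    pseudo-inverse restricts the information to the identified subspace.
    """
    h = 1e-5
    H = np.empty((n_par, n_par))
    for j in range(n_par):
        xp = x_opt.copy()
        xp[j] += h
        xm = x_opt.copy()
        xm[j] -= h
        H[:, j] = (nll_grad(xp)[1] - nll_grad(xm)[1]) / (2 * h)
    H = (H + H.T) / 2
    try:
        w, v = np.linalg.eigh(H)
    except np.linalg.LinAlgError:  # pragma: no cover
        return None
    # exactly one near-zero eigenvalue is expected (the shift direction);
    # invert on the identified subspace only
    keep = w > 1e-8 * w.max()
    if keep.sum() < n_par - 1:
        return None
    var = ((v[:, keep] ** 2) / w[keep]).sum(axis=1)
    return np.sqrt(var)
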