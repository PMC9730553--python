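"""Model-fit diagnostics for a Partial Credit Model calibration.

Covers the assumption checks run at each calibration iteration: standardized
response residuals, information-weighted (infit) mean squares for items and
persons, residual-correlation screening for local dependence, threshold
ordering with a minimal-change collapse search, targeting summaries, and the
person separation index (PSI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import ItemCalibration
from .cml import CmlResult, calibrate_items_cml, _log_esf, _log_esf_loo
from .pcm import PersonAbility, item_moments, score_table
from .responses import MISSING, ResponseMatrix
from .scoring import RecodeMap

__all__ = [
    "abilities_for_matrix",
    "score_conditional_moments",
    "standardized_residuals",
    "item_infit",
    "person_infit",
    "residual_correlation_flags",
    "threshold_order_check",
    "suggest_collapse",
    "person_separation_index",
    "targeting_summary",
    "FitReport",
]

#: conventional good-fit band for item infit mean squares
ITEM_INFIT_RANGE = (0.7, 1.3)
#: person infit above this is flagged as misfitting
PERSON_MISFIT_CUTOFF = 2.0
#: local dependence: flag pairs with r >= mean off-diagonal r + this margin
DEPENDENCE_MARGIN = 0.2


def abilities_for_matrix(
    data: ResponseMatrix,
    items: Sequence[ItemCalibration],
    extreme_adjust: float = 0.3,
) -> list[PersonAbility]:
    """ML ability per person (complete patterns via the sum-score table).

    Extreme scores receive the fractional-score extrapolated estimate so
    every person has a finite ability; their records carry no SE.
    """
    from .pcm import estimate_person_ability

    table = score_table(items, anchors=None, extreme_adjust=extreme_adjust)
    sums = data.sum_scores()
    complete = ~data.missing_mask.any(axis=1)
    cache: dict[tuple, PersonAbility] = {}
    out: list[PersonAbility] = []
    for i in range(data.n_persons):
        if complete[i]:
            out.append(table[sums[i]])
            continue
        key = (tuple(data.missing_mask[i]), int(sums[i]))
        if key not in cache:
            answered = ~data.missing_mask[i]
            sub = [it for it, a in zip(items, answered) if a]
            cache[key] = estimate_person_ability(
                int(sums[i]), sub, anchors=None, extreme_adjust=extreme_adjust
            )
        out.append(cache[key])
    return out


def score_conditional_moments(
    items: Sequence[ItemCalibration],
) -> tuple[np.ndarray, np.ndarray]:
    """Exact CML moments ``E[X_j | r]`` and ``Var[X_j | r]`` per sum score.

    The conditional distribution of an item score given the pattern sum is
    free of the person parameter; residuals standardized with these moments
    have mean-square exactly 1 in expectation under the model, unlike
    moments evaluated at an estimated ability.  Returns two
    ``(max_sum + 1, n_items)`` arrays.
    """
    log_a = []
    for it in items:
        eta = np.cumsum(it.thresholds)
        log_a.append(np.concatenate(([0.0], -eta)))
    lg = _log_esf(log_a)
    loo = _log_esf_loo(log_a)
    max_sum = len(lg) - 1
    E = np.zeros((max_sum + 1, len(items)))
    V = np.zeros_like(E)
    for j, it in enumerate(items):
        m = it.max_category
        P = np.zeros((max_sum + 1, m + 1))
        for k in range(m + 1):
            lo, hi = k, k + len(loo[j]) - 1
            P[lo : hi + 1, k] = np.exp(log_a[j][k] + loo[j] - lg[lo : hi + 1])
        ks = np.arange(m + 1)
        E[:, j] = P @ ks
        V[:, j] = P @ (ks * ks) - (P @ ks) ** 2
    return E, V


def _thetas_of(abilities) -> np.ndarray:
    if isinstance(abilities, np.ndarray):
        return np.asarray(abilities, dtype=float)
    return np.asarray([a.theta for a in abilities], dtype=float)


def _moment_arrays(
    data: ResponseMatrix,
    items: Sequence[ItemCalibration],
    abilities=None,
    moments: str = "score",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell conditional means and variances E_ni, Var_ni.

    ``moments="score"`` conditions on each person's sum score over answered
    items (missingness patterns handled separately); ``moments="theta"``
    evaluates the PCM moments at the supplied ability estimates.
    """
    n, p = data.values.shape
    E = np.full((n, p), np.nan)
    V = np.full((n, p), np.nan)
    if moments == "theta":
        if abilities is None:
            raise ValueError('moments="theta" requires ability estimates')
        thetas = _thetas_of(abilities)
        if len(thetas) != n:
            raise ValueError("abilities must match the response matrix")
        for j, it in enumerate(items):
            E[:, j], V[:, j] = item_moments(thetas, it)
        return E, V
    if moments != "score":
        raise ValueError(f"unknown moments convention {moments!r}")
    sums = data.sum_scores()
    patterns: dict[tuple[int, ...], np.ndarray] = {}
    miss = data.missing_mask
    for key in {tuple(row) for row in miss}:
        patterns[key] = np.all(miss == np.asarray(key, bool), axis=1)
    for key, rows in patterns.items():
        answered = ~np.asarray(key, bool)
        sub_items = [it for it, a in zip(items, answered) if a]
        if len(sub_items) < 2:
            continue  # a single answered item has a degenerate conditional
        Es, Vs = score_conditional_moments(sub_items)
        # extreme sum scores have a point-mass conditional: no residual exists
        Vs[0, :] = np.nan
        Vs[-1, :] = np.nan
        Es[0, :] = np.nan
        Es[-1, :] = np.nan
        sub_sums = sums[rows]
        cols = np.nonzero(answered)[0]
        E[np.ix_(rows, cols)] = Es[sub_sums]
        V[np.ix_(rows, cols)] = Vs[sub_sums]
    return E, V


def standardized_residuals(
    data: ResponseMatrix,
    items: Sequence[ItemCalibration],
    abilities: Sequence[PersonAbility] | np.ndarray | None = None,
    moments: str = "score",
) -> np.ndarray:
    """Standardized residuals ``z_ni = (x_ni - E_ni) / sqrt(Var_ni)``.

    Moments are conditional on the person's sum score by default (see
    :func:`score_conditional_moments`); pass ``moments="theta"`` together
    with ability estimates for moments at ``theta_hat``.  Missing responses
    produce NaN; degenerate conditional variances (extreme scores, or an
    ability pinned far outside the item range) also produce NaN, with a
    warning.
    """
    E, V = _moment_arrays(data, items, abilities, moments)
    x = np.where(data.missing_mask, np.nan, data.values.astype(float))
    with np.errstate(invalid="ignore"):
        degenerate = V <= 1e-12
    if np.any(degenerate & ~data.missing_mask):
        warnings.warn("zero conditional variance for some cells; residuals set missing")
    V = np.where(degenerate, np.nan, V)
    with np.errstate(invalid="ignore"):
        return (x - E) / np.sqrt(V)


def item_infit(
    data: ResponseMatrix,
    items: Sequence[ItemCalibration],
    abilities: Sequence[PersonAbility] | np.ndarray | None = None,
    moments: str = "score",
) -> pd.Series:
    """Information-weighted item fit: ``sum_n (x-E)^2 / sum_n Var`` per item.

    Expectation 1 under the model; values in ``[0.7, 1.3]`` are conventionally
    taken as good fit.  Items with fewer than 2 responses are NaN.
    """
    E, V = _moment_arrays(data, items, abilities, moments)
    V = np.where(np.nan_to_num(V) <= 1e-12, np.nan, V)
    obs = ~data.missing_mask & np.isfinite(V)
    sq = np.where(obs, (np.where(obs, data.values, 0) - E) ** 2, 0.0)
    vv = np.where(obs, V, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fit = sq.sum(axis=0) / vv.sum(axis=0)
    fit = np.where(obs.sum(axis=0) >= 2, fit, np.nan)
    return pd.Series(fit, index=data.item_ids, name="infit")


def person_infit(
    data: ResponseMatrix,
    items: Sequence[ItemCalibration],
    abilities: Sequence[PersonAbility] | np.ndarray | None = None,
    misfit_cutoff: float = PERSON_MISFIT_CUTOFF,
    moments: str = "score",
) -> tuple[pd.Series, float]:
    """Per-person infit mean square and the fraction above ``misfit_cutoff``.

    Persons whose conditional moments are degenerate (extreme sum scores
    under the score convention) get NaN and do not enter the misfit
    fraction.
    """
    E, V = _moment_arrays(data, items, abilities, moments)
    V = np.where(np.nan_to_num(V) <= 1e-12, np.nan, V)
    obs = ~data.missing_mask & np.isfinite(V)
    sq = np.where(obs, (np.where(obs, data.values, 0) - E) ** 2, 0.0)
    vv = np.where(obs, V, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fit = sq.sum(axis=1) / vv.sum(axis=1)
    fit = np.where(obs.sum(axis=1) >= 1, fit, np.nan)
    ser = pd.Series(fit, index=data.person_ids, name="person_infit")
    finite = np.isfinite(fit)
    if not finite.any():
        raise ValueError("no person has a defined infit (all degenerate)")
    frac = float(np.mean(fit[finite] > misfit_cutoff))
    return ser, frac


def residual_correlation_flags(
    residuals: np.ndarray | pd.DataFrame,
    item_ids: Sequence[str] | None = None,
    margin: float = DEPENDENCE_MARGIN,
) -> tuple[pd.DataFrame, list[tuple[str, str]], float]:
    """Local-dependence screen on the residual correlation matrix.

    Pearson correlations over pairwise-complete observations; a pair is
    flagged when its correlation is at least ``margin`` above the mean of all
    off-diagonal correlations.  Returns (correlation matrix, flagged pairs,
    threshold used).
    """
    if isinstance(residuals, pd.DataFrame):
        df = residuals
    else:
        if item_ids is None:
            item_ids = [f"item{j}" for j in range(residuals.shape[1])]
        df = pd.DataFrame(residuals, columns=list(item_ids))
    if df.shape[1] < 3:
        raise ValueError("at least 3 items required for the dependence screen")
    corr = df.corr(method="pearson", min_periods=2)
    off = corr.values[np.triu_indices_from(corr.values, k=1)]
    mean_off = float(np.nanmean(off))
    threshold = mean_off + margin
    flags = [
        (corr.columns[i], corr.columns[j])
        for i in range(len(corr))
        for j in range(i + 1, len(corr))
        if np.isfinite(corr.iat[i, j]) and corr.iat[i, j] >= threshold
    ]
    return corr, flags, threshold


def threshold_order_check(items: Sequence[ItemCalibration]) -> list[str]:
    """Items whose thresholds are not strictly increasing."""
    return [
        it.item_id
        for it in items
        if it.max_category > 1 and np.any(np.diff(it.thresholds) <= 0)
    ]


@dataclass
class CollapseStep:
    item_id: str
    merged_categories: tuple[int, int]  # categories merged (lower kept)
    inversion: float  # size of the threshold inversion that drove the merge
    disordered_after: list[str]


def suggest_collapse(
    data: ResponseMatrix,
    result: CmlResult | None = None,
    max_steps: int = 20,
) -> tuple[RecodeMap, list[CollapseStep]]:
    """Search for a minimal monotone category collapse that orders thresholds.

    Iteratively merges the adjacent category pair with the largest threshold
    inversion on the worst item, refits by CML, and repeats until every item
    is ordered or categories are exhausted.  Returns the cumulative recode
    map (identity rows for untouched items) and the per-iteration log.
    """
    if result is None:
        result = calibrate_items_cml(data)
    current = data
    # cumulative maps start as identities on the observed ranges
    cum: dict[str, list[int]] = {
        it.item_id: list(range(it.max_category + 1)) for it in result.items
    }
    log: list[CollapseStep] = []
    for _ in range(max_steps):
        disordered = threshold_order_check(result.items)
        if not disordered:
            break
        # worst item = largest inversion among disordered thresholds
        worst_item, worst_k, worst_gap = None, None, 0.0
        for it in result.items:
            if it.item_id not in disordered:
                continue
            gaps = -np.diff(it.thresholds)
            k = int(np.argmax(gaps))
            if gaps[k] >= worst_gap:
                worst_item, worst_k, worst_gap = it.item_id, k, float(gaps[k])
        it = next(i for i in result.items if i.item_id == worst_item)
        if it.max_category < 2:
            log.append(CollapseStep(worst_item, (-1, -1), worst_gap, disordered))
            break
        # merge categories worst_k+1 and worst_k+2 (the pair straddling the
        # inverted threshold gap); on the item's current 0..m scale
        lo = worst_k + 1
        j = current.item_ids.index(worst_item)
        vals = current.values.copy()
        col = vals[:, j]
        mask = (col != MISSING) & (col > lo)
        col[mask] -= 1
        current = ResponseMatrix(vals, list(current.person_ids), list(current.item_ids), current.group)
        prev = cum[worst_item]
        cum[worst_item] = [v - 1 if v > lo else v for v in prev]
        result = calibrate_items_cml(current)
        log.append(
            CollapseStep(worst_item, (lo, lo + 1), worst_gap, threshold_order_check(result.items))
        )
    return RecodeMap({k: tuple(v) for k, v in cum.items()}), log


def person_separation_index(
    abilities: Sequence[PersonAbility],
    include_extremes: bool = True,
) -> float:
    """Person separation index: the fraction of observed ability variance
    not attributable to estimation error,

        PSI = (var(theta_hat) - mean(SE^2)) / var(theta_hat),

    floored at 0.  Squared SEs are averaged over measurable (non-extreme)
    persons; with ``include_extremes`` (default) the extrapolated abilities
    of extreme scorers stay in the variance, mirroring how separation
    reliability is reported by the major Rasch packages.  Set
    ``include_extremes=False`` to drop extreme scorers entirely.
    """
    thetas = np.array([a.theta for a in abilities], dtype=float)
    ses = np.array([a.se if a.se is not None else np.nan for a in abilities], dtype=float)
    measurable = np.isfinite(ses)
    if measurable.sum() < 2:
        raise ValueError("PSI requires at least 2 non-extreme persons")
    if not include_extremes:
        thetas = thetas[measurable]
    var = float(np.var(thetas, ddof=1))
    if var <= 0:
        raise ValueError("PSI undefined: zero variance of ability estimates")
    mse = float(np.mean(ses[measurable] ** 2))
    return max(0.0, (var - mse) / var)


@dataclass
class TargetingSummary:
    person_mean: float
    person_sd: float
    person_range: tuple[float, float]
    item_mean: float
    item_sd: float
    item_range: tuple[float, float]
    person_hist: tuple[np.ndarray, np.ndarray]  # counts, bin edges
    item_thresholds: dict[str, tuple[float, ...]]


def targeting_summary(
    abilities: Sequence[PersonAbility],
    items: Sequence[ItemCalibration],
    bins: int = 40,
    include_extremes: bool = False,
) -> TargetingSummary:
    """Person and item locations on the shared logit continuum.

    Item statistics are computed over all thresholds (so the range spans the
    extreme thresholds); person statistics over measurable persons by
    default.  The histogram + threshold positions form a person-item map.
    """
    thetas = np.array([a.theta for a in abilities], dtype=float)
    if not include_extremes:
        flags = np.array([a.extreme_flag for a in abilities])
        thetas = thetas[~flags]
    allth = np.concatenate([np.asarray(it.thresholds) for it in items])
    counts, edges = np.histogram(thetas, bins=bins)
    return TargetingSummary(
        person_mean=float(np.mean(thetas)),
        person_sd=float(np.std(thetas, ddof=1)) if len(thetas) > 1 else 0.0,
        person_range=(float(np.min(thetas)), float(np.max(thetas))),
        item_mean=float(np.mean(allth)),
        item_sd=float(np.std(allth, ddof=1)) if len(allth) > 1 else 0.0,
        item_range=(float(np.min(allth)), float(np.max(allth))),
        person_hist=(counts, edges),
        item_thresholds={it.item_id: it.thresholds for it in items},
    )


@dataclass
class FitReport:
    """Bundle of fit diagnostics, serializable to JSON."""

    item_infit: pd.Series
    person_infit: pd.Series
    person_misfit_fraction: float
    residual_correlations: pd.DataFrame
    dependence_flags: list[tuple[str, str]]
    dependence_threshold: float
    disordered_items: list[str]
    psi: float
    targeting: TargetingSummary
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        t = self.targeting
        return {
            "item_infit": self.item_infit.round(4).to_dict(),
            "person_misfit_fraction": round(self.person_misfit_fraction, 4),
            "residual_correlations": self.residual_correlations.round(4).to_dict(),
            "dependence_flags": [list(p) for p in self.dependence_flags],
            "dependence_threshold": round(self.dependence_threshold, 4),
            "disordered_items": self.disordered_items,
            "psi": round(self.psi, 4),
            "targeting": {
                "person_mean": round(t.person_mean, 4),
                "person_sd": round(t.person_sd, 4),
                "person_range": [round(v, 4) for v in t.person_range],
                "item_mean": round(t.item_mean, 4),
                "item_sd": round(t.item_sd, 4),
                "item_range": [round(v, 4) for v in t.item_range],
            },
            **self.extras,
        }

    def to_text(self) -> str:
        """Human-readable one-page summary."""
        t = self.targeting
        lines = [
            "Model fit report",
            "================",
            "item infit (good fit 0.7-1.3):",
            self.item_infit.round(2).to_string(),
            f"person misfit fraction (infit > {PERSON_MISFIT_CUTOFF}): "
            f"{self.person_misfit_fraction:.1%}",
            f"local dependence flags (r >= {self.dependence_threshold:.3f}): "
            f"{self.dependence_flags or 'none'}",
            f"disordered items: {self.disordered_items or 'none'}",
            f"person separation index: {self.psi:.3f}",
            f"targeting: persons {t.person_mean:.2f} +/- {t.person_sd:.2f} "
            f"[{t.person_range[0]:.2f}, {t.person_range[1]:.2f}], "
            f"item thresholds {t.item_mean:.2f} +/- {t.item_sd:.2f} "
            f"[{t.item_range[0]:.2f}, {t.item_range[1]:.2f}]",
        ]
        return "\n".join(lines)


def plot_person_item_map(targeting: TargetingSummary, path=None):
    """Person-item map: ability histogram above, threshold locations below.

    Requires matplotlib (optional dependency); returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts, edges = targeting.person_hist
    fig, (ax0, ax1) = plt.subplots(
        2, 1, sharex=True, figsize=(8, 5), height_ratios=[3, 2]
    )
    ax0.bar(edges[:-1], counts, width=np.diff(edges), align="edge", color="0.6")
    ax0.set_ylabel("persons")
    for y, (item_id, thr) in enumerate(targeting.item_thresholds.items()):
        ax1.scatter(thr, [y] * len(thr), facecolors="white", edgecolors="black", s=25)
        ax1.scatter([np.mean(thr)], [y], color="black", s=30)
    ax1.set_yticks(range(len(targeting.item_thresholds)))
    ax1.set_yticklabels(list(targeting.item_thresholds))
    ax1.set_xlabel("latent continuum (logits)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def fit_report(
    data: ResponseMatrix,
    items: Sequence[ItemCalibration],
    abilities: Sequence[PersonAbility] | None = None,
) -> FitReport:
    """Run the full diagnostic battery for a calibrated dataset."""
    if abilities is None:
        abilities = abilities_for_matrix(data, items)
    resid = standardized_residuals(data, items, abilities)
    inf_i = item_infit(data, items, abilities)
    inf_p, frac = person_infit(data, items, abilities)
    corr, flags, thr = residual_correlation_flags(resid, data.item_ids)
    psi = person_separation_index(abilities)
    return FitReport(
        item_infit=inf_i,
        person_infit=inf_p,
        person_misfit_fraction=frac,
        residual_correlations=corr,
        dependence_flags=flags,
        dependence_threshold=thr,
        disordered_items=threshold_order_check(items),
        psi=psi,
        targeting=targeting_summary(abilities, items),
    )
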