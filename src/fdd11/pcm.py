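"""Partial Credit Model response function and person measurement.

The PCM gives the probability that a person with ability ``theta`` (logits)
responds in category ``k`` of an item with thresholds ``tau_1..tau_m``::

    P(X = k | theta) = exp(sum_{j<=k} (theta - tau_j)) / sum_l exp(...)

with the empty sum equal to 0 for ``k = 0``.  The person sum score over the
instrument is the sufficient statistic for ``theta``, so maximum-likelihood
person measurement reduces to solving ``E[score | theta] = observed score``;
the standard error is the inverse square root of the Fisher (test)
information at the solution.  Extreme sum scores (0 and the maximum) have no
finite ML estimate and are handled by configurable anchors or a
fractional-score adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import log_softmax

from .calibration import ItemCalibration

__all__ = [
    "PersonAbility",
    "category_probabilities",
    "probability_matrix",
    "expected_score_and_information",
    "estimate_person_ability",
    "score_table",
]

THETA_BRACKET = (-10.0, 10.0)
SCORE_TOL = 1e-8


@dataclass(frozen=True)
class PersonAbility:
    """ML ability estimate for one (sum score, item set) combination."""

    theta: float
    se: float | None
    sum_score: int
    extreme_flag: bool = False


def _check_theta(theta: float) -> float:
    theta = float(theta)
    if not np.isfinite(theta):
        raise ValueError(f"theta must be finite, got {theta}")
    return theta


def category_probabilities(theta: float, item: ItemCalibration) -> np.ndarray:
    """PCM category probabilities ``P(X = k | theta)``, ``k = 0..m``."""
    theta = _check_theta(theta)
    tau = np.asarray(item.thresholds)
    cum = np.concatenate(([0.0], np.cumsum(theta - tau)))
    return np.exp(log_softmax(cum))


def probability_matrix(thetas: np.ndarray, item: ItemCalibration) -> np.ndarray:
    """Vectorised ``(n, m+1)`` matrix of category probabilities."""
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    if not np.all(np.isfinite(thetas)):
        raise ValueError("theta must be finite")
    tau = np.asarray(item.thresholds)
    cum = np.concatenate(
        [np.zeros((len(thetas), 1)), np.cumsum(thetas[:, None] - tau[None, :], axis=1)], axis=1
    )
    return np.exp(log_softmax(cum, axis=1))


def item_moments(thetas: np.ndarray, item: ItemCalibration) -> tuple[np.ndarray, np.ndarray]:
    """Conditional mean and variance of the item score at each theta."""
    p = probability_matrix(thetas, item)
    k = np.arange(p.shape[1])
    mean = p @ k
    var = p @ (k * k) - mean**2
    return mean, var

def expected_score_and_information(
    theta: float, items: Sequence[ItemCalibration]
) -> tuple[float, float]:
    """Expected instrument sum score and Fisher test information at theta.

    The information of a PCM item equals the conditional variance of its
    score, so the test information is the sum of item score variances.
    """
    theta = _check_theta(theta)
    if not items:
        raise ValueError("at least one item required")
    th = np.array([theta])
    means = 0.0
    infos = 0.0
    for it in items:
        m, v = item_moments(th, it)
        means += m[0]
        infos += v[0]
    return float(means), float(infos)


def _solve_theta(target: float, items: Sequence[ItemCalibration]) -> float:
    lo, hi = THETA_BRACKET
    f = lambda t: expected_score_and_information(t, items)[0] - target
    # expected score is strictly increasing; widen the bracket if needed
    while f(lo) > 0 and lo > -60:
        lo *= 2
    while f(hi) < 0 and hi < 60:
        hi *= 2
    return float(brentq(f, lo, hi, xtol=SCORE_TOL))


def estimate_person_ability(
    sum_score: int,
    items: Sequence[ItemCalibration],
    anchors: tuple[float, float] | None = None,
    extreme_adjust: float = 0.3,
    allow_extrapolation: bool = True,
) -> PersonAbility:
    """ML ability for a given sum score under a fixed calibration.

    For interior scores the estimate solves ``E[score|theta] = sum_score`` and
    ``SE = information(theta)^(-1/2)``.  Extreme scores (0 or the maximum)
    have no ML estimate: with ``anchors`` given, those published constants are
    returned; otherwise, if ``allow_extrapolation``, the ML solution at the
    fractional score ``extreme_adjust`` / ``max - extreme_adjust`` is used.
    Extreme results carry ``extreme_flag=True`` and no standard error.
    """
    max_score = sum(it.max_category for it in items)
    if not 0 <= sum_score <= max_score:
        raise ValueError(f"sum score {sum_score} outside 0..{max_score}")
    if sum_score in (0, max_score):
        if anchors is not None:
            theta = anchors[0] if sum_score == 0 else anchors[1]
        elif allow_extrapolation:
            target = extreme_adjust if sum_score == 0 else max_score - extreme_adjust
            theta = _solve_theta(target, items)
        else:
            raise ValueError(
                f"sum score {sum_score} is extreme: no ML estimate exists and no "
                "anchors are configured"
            )
        return PersonAbility(theta=float(theta), se=None, sum_score=int(sum_score), extreme_flag=True)
    theta = _solve_theta(float(sum_score), items)
    info = expected_score_and_information(theta, items)[1]
    return PersonAbility(
        theta=theta, se=float(info**-0.5), sum_score=int(sum_score), extreme_flag=False
    )


def score_table(
    items: Sequence[ItemCalibration],
    anchors: tuple[float, float] | None = None,
    extreme_adjust: float = 0.3,
) -> list[PersonAbility]:
    """Sum-score-to-ability conversion table for a complete response pattern.

    One entry per sum score ``0..max``; the sufficient-statistic property of
    the PCM makes this the complete scoring rule for complete patterns.
    """
    max_score = sum(it.max_category for it in items)
    return [
        estimate_person_ability(s, items, anchors=anchors, extreme_adjust=extreme_adjust)
        for s in range(max_score + 1)
    ]
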