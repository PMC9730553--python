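"""FDD11 scoring: recoding, the emotion testlet, missingness filtering,
sum scoring, the 0-100 transformation and disability levels.

The published instrument asks 11 questions (12 in country implementations
that split the emotion question into "sad, low or depressed" and "worried,
nervous or anxious"; those two are combined into a single testlet by summing
and recoding).  Original 5-point responses are collapsed per the published
recode table, the recoded responses are summed (maximum 30), the sum score is
converted to a logit ability via the PCM, and the ability is mapped affinely
onto a 0-100 disability scale split into No / Mild / Moderate / Severe by the
published cut-offs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import CalibrationArtifact, Cutoffs, ItemCalibration
from .pcm import PersonAbility, estimate_person_ability, score_table
from .responses import MISSING, ResponseMatrix

__all__ = [
    "RecodeMap",
    "fdd11_recode_map",
    "apply_recodes",
    "build_emotion_testlet",
    "filter_missingness",
    "transform_to_scale",
    "assign_level",
    "derive_cutoffs",
    "score_persons",
    "ScaledScore",
    "EMOTION_SUBITEMS",
]

#: column names recognised as the split emotion sub-items (12-question form)
EMOTION_SUBITEMS = ("Q09a", "Q09b")
TESTLET_ID = "Q09"


@dataclass(frozen=True)
class RecodeMap:
    """Per-item monotone maps original category index -> recoded index."""

    maps: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        clean = {}
        for item_id, vec in self.maps.items():
            vec = tuple(int(v) for v in vec)
            if list(vec) != sorted(vec):
                raise ValueError(f"{item_id}: recode map must be monotone non-decreasing")
            if set(vec) != set(range(max(vec) + 1)):
                raise ValueError(f"{item_id}: recode map must be surjective onto 0..max")
            clean[item_id] = vec
        object.__setattr__(self, "maps", clean)

    def recoded_max(self, item_id: str) -> int:
        return max(self.maps[item_id])

    def __getitem__(self, item_id: str) -> tuple[int, ...]:
        return self.maps[item_id]


def fdd11_recode_map(artifact: CalibrationArtifact) -> RecodeMap:
    """The instrument's recode strategy as shipped in the calibration artifact."""
    maps = {}
    for it in artifact.items:
        if it.recode is None:
            raise ValueError(f"{it.item_id}: calibration artifact carries no recode map")
        maps[it.item_id] = it.recode
    return RecodeMap(maps)


def apply_recodes(data: ResponseMatrix, recodes: RecodeMap) -> ResponseMatrix:
    """Collapse original response categories item by item; missing stays missing."""
    vals = data.values.copy()
    errors: list[str] = []
    for j, item_id in enumerate(data.item_ids):
        vec = np.asarray(recodes[item_id])
        col = vals[:, j]
        answered = col != MISSING
        bad = answered & ((col < 0) | (col >= len(vec)))
        if bad.any():
            for i in np.nonzero(bad)[0]:
                errors.append(f"person {data.person_ids[i]}, item {item_id}: {col[i]}")
            continue
        col[answered] = vec[col[answered]]
    if errors:
        raise ValueError("out-of-range categories for recode:\n" + "\n".join(errors[:20]))
    return ResponseMatrix(vals, list(data.person_ids), list(data.item_ids), data.group)


def build_emotion_testlet(q9a: np.ndarray | int, q9b: np.ndarray | int) -> np.ndarray | int:
    """Combine the two emotion sub-items into the 5-category testlet.

    The sub-item responses (0-4 each) are summed to 0-8 and recoded
    0,1,1,2,2,3,3,4,4.  Missing either sub-item makes the testlet missing.
    """
    scalar = np.isscalar(q9a) and np.isscalar(q9b)
    a = np.atleast_1d(np.asarray(q9a, dtype=np.int64))
    b = np.atleast_1d(np.asarray(q9b, dtype=np.int64))
    for name, v in (("q9a", a), ("q9b", b)):
        ok = (v == MISSING) | ((v >= 0) & (v <= 4))
        if not ok.all():
            raise ValueError(f"{name}: categories must be 0..4 or missing")
    total = a + b
    vec = np.array([0, 1, 1, 2, 2, 3, 3, 4, 4])
    out = np.where((a == MISSING) | (b == MISSING), MISSING, vec[np.clip(total, 0, 8)])
    return int(out[0]) if scalar else out


def combine_twelve_item(data: ResponseMatrix) -> ResponseMatrix:
    """Collapse a 12-question matrix (Q09a/Q09b present) to the 11-item form.

    The testlet column keeps the position of the first sub-item and is on the
    0-8 *summed* scale, ready for the published Q09 recode.
    """
    a, b = EMOTION_SUBITEMS
    if a not in data.item_ids or b not in data.item_ids:
        raise ValueError(f"expected columns {a} and {b}")
    ja, jb = data.item_ids.index(a), data.item_ids.index(b)
    va, vb = data.values[:, ja], data.values[:, jb]
    summed = np.where((va == MISSING) | (vb == MISSING), MISSING, va + vb)
    keep = [j for j in range(data.n_items) if j != jb]
    vals = data.values[:, keep].copy()
    ids = [data.item_ids[j] for j in keep]
    pos = ids.index(a)
    vals[:, pos] = summed
    ids[pos] = TESTLET_ID
    return ResponseMatrix(vals, list(data.person_ids), ids, data.group)


def filter_missingness(
    data: ResponseMatrix, max_missing: int = 2
) -> tuple[ResponseMatrix, list[str]]:
    """Retain persons with at most ``max_missing`` missing items.

    Returns the retained matrix and the excluded person ids.
    """
    n_missing = data.n_missing_per_person()
    keep = n_missing <= max_missing
    excluded = [pid for pid, k in zip(data.person_ids, keep) if not k]
    return data.subset_persons(keep), excluded


def transform_to_scale(theta: float | np.ndarray, anchors: tuple[float, float]) -> float | np.ndarray:
    """Affine map of ability onto 0-100, clamped outside the anchors."""
    lo, hi = float(anchors[0]), float(anchors[1])
    if not lo < hi:
        raise ValueError(f"degenerate anchors {anchors}")
    out = 100.0 * (np.asarray(theta, dtype=float) - lo) / (hi - lo)
    out = np.clip(out, 0.0, 100.0)
    return float(out) if np.isscalar(theta) else out


def assign_level(transformed: float, cutoffs: Cutoffs, levels: Sequence[str] = ("No", "Mild", "Moderate", "Severe")) -> str:
    """Disability level for a 0-100 score.

    Intervals are left-closed/right-open at the cut-offs ([c1, c2) is Mild,
    etc.); the top interval is closed at 100.
    """
    if not 0 <= transformed <= 100:
        raise ValueError(f"transformed score {transformed} outside [0, 100]")
    c1, c2, c3 = cutoffs.as_tuple()
    if transformed < c1:
        return levels[0]
    if transformed < c2:
        return levels[1]
    if transformed < c3:
        return levels[2]
    return levels[3]


def derive_cutoffs(transformed_scores: np.ndarray) -> Cutoffs:
    """Cut-offs as (mean - SD, mean, mean + SD) of the transformed scores.

    The SD uses the n-1 denominator.  Raises if the scores are (nearly)
    constant or a cut-off leaves (0, 100).
    """
    x = np.asarray(transformed_scores, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError("cut-off derivation needs at least two distinct scores")
    mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    return Cutoffs(mu - sd, mu, mu + sd)


@dataclass(frozen=True)
class ScaledScore:
    """Final per-person scoring record."""

    person_id: str
    sum_score: int
    theta: float
    se: float | None
    transformed: float
    level: str
    n_missing: int
    extreme_flag: bool


def score_persons(
    data: ResponseMatrix,
    artifact: CalibrationArtifact,
    extreme_adjust: float = 0.3,
) -> list[ScaledScore]:
    """Score recoded, missingness-filtered persons against a calibration.

    Complete patterns are scored through the sum-score lookup table (the sum
    score is sufficient for ability under the PCM); persons with missing
    items get an ML estimate over their answered items only.  Extreme scores
    on the full item set map to the artifact anchors.
    """
    if list(data.item_ids) != artifact.item_ids:
        raise ValueError(
            f"item set mismatch: data has {data.item_ids}, artifact has {artifact.item_ids}"
        )
    data.validate_ranges([it.max_category for it in artifact.items])
    if artifact.cutoffs is None:
        raise ValueError("artifact carries no cut-offs")
    table = score_table(artifact.items, anchors=artifact.anchors, extreme_adjust=extreme_adjust)
    n_missing = data.n_missing_per_person()
    sums = data.sum_scores()
    out: list[ScaledScore] = []
    for i, pid in enumerate(data.person_ids):
        if n_missing[i] == 0:
            pa = table[sums[i]]
        else:
            answered = ~data.missing_mask[i]
            sub_items = [it for it, a in zip(artifact.items, answered) if a]
            pa = estimate_person_ability(
                int(sums[i]), sub_items, anchors=None, extreme_adjust=extreme_adjust
            )
        tr = transform_to_scale(pa.theta, artifact.anchors)
        out.append(
            ScaledScore(
                person_id=pid,
                sum_score=int(sums[i]),
                theta=pa.theta,
                se=pa.se,
                transformed=tr,
                level=assign_level(tr, artifact.cutoffs, artifact.levels),
                n_missing=int(n_missing[i]),
                extreme_flag=pa.extreme_flag,
            )
        )
    return out
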