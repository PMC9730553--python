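"""Item calibrations and the calibration artifact.

An :class:`ItemCalibration` holds the Partial Credit Model parameters of a
single polytomous item: the adjacent-category thresholds ``tau_1..tau_m`` on
the logit scale (the ability at which two adjacent response categories are
equally likely) and the item location ``delta`` (their mean).  Thresholds are
stored *uncentred*, exactly as a calibration table prints them, so that
scoring reproduces the published conversion table without knowledge of the
normalisation the original software used.

A :class:`CalibrationArtifact` bundles a full instrument: items (with their
original-scale recode maps), the logit anchors that pin the 0-100 transformed
scale, and the disability-level cut-offs.  The published FDD11 calibration
ships with the package as a versioned JSON fixture, see :func:`published`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ItemCalibration",
    "Cutoffs",
    "CalibrationArtifact",
    "published",
    "load_artifact",
    "save_artifact",
]

#: tolerance for location == mean(thresholds) when loading printed tables
_LOCATION_TOL = 0.005

LEVELS = ("No", "Mild", "Moderate", "Severe")


@dataclass(frozen=True)
class ItemCalibration:
    """PCM parameters of one polytomous item.

    Parameters
    ----------
    item_id
        Item label, e.g. ``"Q03"``.
    thresholds
        Adjacent-category thresholds ``tau_1..tau_m`` in logits; the item has
        ``m + 1`` response categories ``0..m``.
    threshold_ses
        Optional standard errors of the thresholds, in logits.
    location
        Item location ``delta`` (mean of the thresholds); derived when omitted.
    """

    item_id: str
    thresholds: tuple[float, ...]
    threshold_ses: tuple[float, ...] | None = None
    location: float = None  # type: ignore[assignment]
    recode: tuple[int, ...] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        thr = tuple(float(t) for t in self.thresholds)
        if len(thr) < 1:
            raise ValueError(f"{self.item_id}: at least one threshold required")
        if not np.all(np.isfinite(thr)):
            raise ValueError(f"{self.item_id}: thresholds must be finite")
        object.__setattr__(self, "thresholds", thr)
        if self.threshold_ses is not None:
            ses = tuple(float(s) for s in self.threshold_ses)
            if len(ses) != len(thr):
                raise ValueError(f"{self.item_id}: SE vector length mismatch")
            object.__setattr__(self, "threshold_ses", ses)
        mean_thr = float(np.mean(thr))
        if self.location is None:
            object.__setattr__(self, "location", mean_thr)
        elif abs(self.location - mean_thr) > _LOCATION_TOL + 1e-9:
            raise ValueError(
                f"{self.item_id}: location {self.location} is not the mean of "
                f"the thresholds ({mean_thr:.4f}) within {_LOCATION_TOL}"
            )
        if self.recode is not None:
            rec = tuple(int(r) for r in self.recode)
            if list(rec) != sorted(rec):
                raise ValueError(f"{self.item_id}: recode map must be monotone")
            if set(rec) != set(range(self.max_category + 1)):
                raise ValueError(
                    f"{self.item_id}: recode map must be onto 0..{self.max_category}"
                )
            object.__setattr__(self, "recode", rec)

    @property
    def max_category(self) -> int:
        """Highest response category ``m`` (number of thresholds)."""
        return len(self.thresholds)


@dataclass(frozen=True)
class Cutoffs:
    """Disability-level cut-offs on the 0-100 scale (``c1 < c2 < c3``)."""

    c1: float
    c2: float
    c3: float

    def __post_init__(self) -> None:
        if not (0 < self.c1 < self.c2 < self.c3 < 100):
            raise ValueError(f"cut-offs must satisfy 0 < c1 < c2 < c3 < 100, got {self}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.c1, self.c2, self.c3)


@dataclass
class CalibrationArtifact:
    """A complete instrument calibration: items, scale anchors, cut-offs."""

    instrument: str
    items: list[ItemCalibration]
    anchors: tuple[float, float]  # (theta mapped to 0, theta mapped to 100)
    cutoffs: Cutoffs | None = None
    provenance: str = ""
    schema_version: int = 1
    levels: tuple[str, ...] = LEVELS

    def __post_init__(self) -> None:
        lo, hi = self.anchors
        if not lo < hi:
            raise ValueError("anchors must satisfy theta_min < theta_max")
        self.anchors = (float(lo), float(hi))

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def max_sum_score(self) -> int:
        return sum(it.max_category for it in self.items)

    def item(self, item_id: str) -> ItemCalibration:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "instrument": self.instrument,
            "provenance": self.provenance,
            "items": [
                {
                    "id": it.item_id,
                    "label": it.label,
                    "max_category": it.max_category,
                    "thresholds": list(it.thresholds),
                    "threshold_ses": list(it.threshold_ses) if it.threshold_ses else None,
                    "location": it.location,
                    "recode": list(it.recode) if it.recode else None,
                }
                for it in self.items
            ],
            "anchors": {"theta_min": self.anchors[0], "theta_max": self.anchors[1]},
            "cutoffs": (
                {"c1": self.cutoffs.c1, "c2": self.cutoffs.c2, "c3": self.cutoffs.c3}
                if self.cutoffs
                else None
            ),
            "levels": list(self.levels),
        }


def _artifact_from_dict(d: dict) -> CalibrationArtifact:
    items = []
    for row in d["items"]:
        n_thr = len(row["thresholds"])
        if row.get("max_category") not in (None, n_thr):
            raise ValueError(
                f"{row['id']}: max_category {row['max_category']} does not match "
                f"{n_thr} thresholds"
            )
        items.append(
            ItemCalibration(
                item_id=row["id"],
                thresholds=tuple(row["thresholds"]),
                threshold_ses=tuple(row["threshold_ses"]) if row.get("threshold_ses") else None,
                location=row.get("location"),
                recode=tuple(row["recode"]) if row.get("recode") else None,
                label=row.get("label", ""),
            )
        )
    anch = d["anchors"]
    cut = d.get("cutoffs")
    return CalibrationArtifact(
        instrument=d.get("instrument", ""),
        items=items,
        anchors=(anch["theta_min"], anch["theta_max"]),
        cutoffs=Cutoffs(cut["c1"], cut["c2"], cut["c3"]) if cut else None,
        provenance=d.get("provenance", ""),
        schema_version=d.get("schema_version", 1),
        levels=tuple(d.get("levels", LEVELS)),
    )


def load_artifact(path: str | Path) -> CalibrationArtifact:
    """Load a calibration artifact from a JSON file."""
    with open(path) as fh:
        return _artifact_from_dict(json.load(fh))


def save_artifact(artifact: CalibrationArtifact, path: str | Path) -> None:
    """Write a calibration artifact to JSON."""
    with open(path, "w") as fh:
        json.dump(artifact.to_dict(), fh, indent=1)
        fh.write("\n")


def published() -> CalibrationArtifact:
    """The published FDD11 calibration (items, anchors, cut-offs).

    Thresholds and their standard errors are the printed values from the final
    pooled-survey fit; anchors are the logit abilities mapped to 0 and 100 on
    the transformed scale; cut-offs are the published mean-SD / mean / mean+SD
    values (4.3, 22.6, 40.8).
    """
    text = resources.files("fdd11").joinpath("data/fdd11_calibration.json").read_text()
    return _artifact_from_dict(json.loads(text))
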