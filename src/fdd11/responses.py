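"""The person-by-item response matrix container.

Responses are ordinal categories stored 0-based as integers; missing entries
are coded :data:`MISSING` (-1).  An optional per-person group label (e.g.
country of survey implementation) travels with the matrix for differential
item functioning screens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["MISSING", "ResponseMatrix", "read_responses_csv", "write_responses_csv"]

MISSING: int = -1

#: cell values treated as missing when reading CSVs
DEFAULT_MISSING_CODES = ("", "NA", "N/A", "NaN", "nan", "-9")


@dataclass
class ResponseMatrix:
    """Persons x items ordinal responses with optional group labels."""

    values: np.ndarray  # (n_persons, n_items) int, MISSING = -1
    person_ids: list[str]
    item_ids: list[str]
    group: np.ndarray | None = None  # (n_persons,) object labels

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (persons x items)")
        n, p = self.values.shape
        self.person_ids = [str(x) for x in self.person_ids]
        self.item_ids = [str(x) for x in self.item_ids]
        if len(self.person_ids) != n or len(self.item_ids) != p:
            raise ValueError("id lengths do not match the value matrix")
        if np.any(self.values < MISSING):
            raise ValueError("categories must be >= 0 (or -1 for missing)")
        if self.group is not None:
            self.group = np.asarray(self.group, dtype=object)
            if self.group.shape != (n,):
                raise ValueError("group labels must cover every person")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def n_missing_per_person(self) -> np.ndarray:
        return self.missing_mask.sum(axis=1)

    def sum_scores(self) -> np.ndarray:
        """Per-person sum over answered items (missing treated as 0)."""
        return np.where(self.missing_mask, 0, self.values).sum(axis=1)

    def column(self, item_id: str) -> np.ndarray:
        return self.values[:, self.item_ids.index(item_id)]

    def validate_ranges(self, max_categories: Sequence[int]) -> None:
        """Raise if any non-missing value exceeds its item's top category."""
        bad: list[str] = []
        for j, m in enumerate(max_categories):
            col = self.values[:, j]
            off = (col != MISSING) & ((col < 0) | (col > m))
            for i in np.nonzero(off)[0]:
                bad.append(f"person {self.person_ids[i]}, item {self.item_ids[j]}: {col[i]}")
        if bad:
            raise ValueError("out-of-range categories:\n" + "\n".join(bad[:20]))

    def subset_persons(self, mask: np.ndarray) -> "ResponseMatrix":
        return ResponseMatrix(
            values=self.values[mask],
            person_ids=[p for p, keep in zip(self.person_ids, mask) if keep],
            item_ids=list(self.item_ids),
            group=self.group[mask] if self.group is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.where(self.missing_mask, np.nan, self.values),
            index=pd.Index(self.person_ids, name="person_id"),
            columns=self.item_ids,
        )
        if self.group is not None:
            df["group"] = self.group
        return df


def read_responses_csv(
    path: str | Path,
    item_columns: Sequence[str] | None = None,
    id_column: str = "person_id",
    group_column: str | None = None,
    missing_codes: Sequence[str] = DEFAULT_MISSING_CODES,
    one_based: bool = False,
) -> ResponseMatrix:
    """Read a response CSV (one row per person).

    ``item_columns`` defaults to every column whose name starts with ``Q``.
    Set ``one_based=True`` for surveys coded 1 ("no difficulty") to 5
    ("extreme difficulty"); categories are shifted to the internal 0-based
    representation.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty or not len(df.columns):
        raise ValueError(f"{path}: no data rows")
    if item_columns is None:
        item_columns = [c for c in df.columns if c.upper().startswith("Q")]
    if not item_columns:
        raise ValueError(f"{path}: no item columns found")
    vals = np.full((len(df), len(item_columns)), MISSING, dtype=np.int64)
    for j, col in enumerate(item_columns):
        if col not in df.columns:
            raise ValueError(f"{path}: missing item column {col}")
        raw = df[col].str.strip()
        ok = ~raw.isin(missing_codes)
        try:
            parsed = raw[ok].astype(float).astype(int)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric response in column {col}") from exc
        vals[ok.to_numpy(), j] = parsed.to_numpy() - (1 if one_based else 0)
    if np.any(vals < MISSING):
        raise ValueError(f"{path}: categories below the minimum after recoding")
    person_ids = (
        df[id_column].tolist() if id_column in df.columns else [str(i) for i in range(len(df))]
    )
    group = None
    if group_column is not None:
        if group_column not in df.columns:
            raise ValueError(f"{path}: missing group column {group_column}")
        group = df[group_column].to_numpy(dtype=object)
    return ResponseMatrix(vals, person_ids, list(item_columns), group)


def write_responses_csv(data: ResponseMatrix, path: str | Path) -> None:
    df = data.to_frame().reset_index()
    for c in data.item_ids:
        df[c] = df[c].astype("Int64")
    df.to_csv(path, index=False)
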