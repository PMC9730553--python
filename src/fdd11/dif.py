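"""Differential item functioning (DIF) screening across a grouping variable.

Each item's standardized residuals are analysed with a two-way ANOVA on group
and ability class interval (quantile bins of the estimated ability).  The
reported F statistic is the group main effect with ``groups - 1`` numerator
degrees of freedom, matching how DIF is conventionally reported for Rasch
analyses of multi-country survey data.  A significant group effect means
respondents of equal ability respond systematically differently by group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["DifReport", "dif_test"]


@dataclass
class DifReport:
    """Per-item group-main-effect F tests."""

    table: pd.DataFrame  # index item, columns F, df_num, df_den, p_value
    group_variable: str
    n_class_intervals: int
    class_edges: np.ndarray

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="item")

    def to_dict(self) -> dict:
        return {
            "group_variable": self.group_variable,
            "n_class_intervals": self.n_class_intervals,
            "items": self.table.round(6).to_dict(orient="index"),
        }


def _class_intervals(thetas: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Ability quantile bins (duplicate quantiles merged)."""
    qs = np.quantile(thetas, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    if len(edges) - 1 < n_bins:
        warnings.warn(
            f"ability distribution supports only {len(edges) - 1} class intervals "
            f"(requested {n_bins}); duplicate quantile edges merged"
        )
    idx = np.clip(np.searchsorted(edges, thetas, side="right") - 1, 0, len(edges) - 2)
    return idx, edges


def dif_test(
    residuals: np.ndarray | pd.DataFrame,
    groups: np.ndarray,
    thetas: np.ndarray,
    n_class_intervals: int = 6,
    min_group_size: int = 30,
    item_ids=None,
) -> DifReport:
    """Two-way ANOVA DIF screen of standardized residuals.

    Parameters
    ----------
    residuals
        Persons x items standardized residuals (NaN = missing).
    groups
        Per-person group label (e.g. country).
    thetas
        Per-person ability estimates used to form class intervals.
    n_class_intervals
        Number of ability quantile bins (default 6).
    min_group_size
        Groups smaller than this raise an error.

    Returns a report with, per item, the group main-effect F statistic, its
    numerator df (= number of groups - 1) and p-value from a type-II ANOVA
    of ``residual ~ group + class_interval + group:class_interval``.
    """
    if isinstance(residuals, pd.DataFrame):
        item_ids = list(residuals.columns)
        resid = residuals.to_numpy(dtype=float)
    else:
        resid = np.asarray(residuals, dtype=float)
        if item_ids is None:
            item_ids = [f"item{j}" for j in range(resid.shape[1])]
    groups = np.asarray(groups, dtype=object)
    thetas = np.asarray(thetas, dtype=float)
    if not (len(groups) == len(thetas) == resid.shape[0]):
        raise ValueError("residuals, groups and thetas must align")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("DIF screening needs at least 2 groups")
    small = labels[counts < min_group_size]
    if len(small):
        raise ValueError(f"groups below the minimum size {min_group_size}: {list(small)}")
    cls, edges = _class_intervals(thetas, n_class_intervals)

    rows = {}
    for j, item in enumerate(item_ids):
        df = pd.DataFrame({"z": resid[:, j], "group": groups, "interval": cls}).dropna()
        # merge intervals that lost all observations for some group to keep
        # the two-way layout estimable
        model = smf.ols("z ~ C(group) + C(interval) + C(group):C(interval)", data=df)
        fitted = model.fit()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                anova = sm.stats.anova_lm(fitted, typ=2)
            row = anova.loc["C(group)"]
            f_stat, df_num, p = float(row["F"]), int(row["df"]), float(row["PR(>F)"])
            df_den = int(anova.loc["Residual", "df"])
        except (ValueError, KeyError):
            # degenerate layout: fall back to the additive model
            fitted = smf.ols("z ~ C(group) + C(interval)", data=df).fit()
            anova = sm.stats.anova_lm(fitted, typ=2)
            row = anova.loc["C(group)"]
            f_stat, df_num, p = float(row["F"]), int(row["df"]), float(row["PR(>F)"])
            df_den = int(anova.loc["Residual", "df"])
        rows[item] = {"F": f_stat, "df_num": df_num, "df_den": df_den, "p_value": p}
    table = pd.DataFrame.from_dict(rows, orient="index")
    return DifReport(
        table=table,
        group_variable="group",
        n_class_intervals=len(edges) - 1,
        class_edges=edges,
    )
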