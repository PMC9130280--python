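"""Cell-type composition per group and between-condition comparisons.

Supports the knockout-line readouts: stacked-composition percentages per
condition/timepoint, n-fold changes between percentages (e.g. myeloid cells
at 5.5% in a ZEB2 knockout versus 65.6% in wild type, a 12-fold decrease),
and a two-sided Welch t-test on collected cell counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["proportions", "FoldChange", "fold_change", "count_difference_test"]


def proportions(labels: pd.Series, grouping: pd.Series) -> pd.DataFrame:
    """Exact counts and percentages of each cell type within each group.

    Returns a long-format table (group, cell_type, count, percent) suitable
    for stacked-area plotting; percentages sum to 100 within each group.
    """
    labels = pd.Series(labels)
    grouping = pd.Series(grouping)
    if len(labels) != len(grouping):
        raise ValueError("labels and grouping must cover the same cells")
    if len(labels) == 0:
        raise ValueError("no cells")
    if labels.isna().any() or grouping.isna().any():
        raise ValueError("every cell needs both a label and a group")
    labels = labels.astype(str)
    grouping = grouping.astype(str)
    table = (
        pd.DataFrame({"group": grouping.to_numpy(), "cell_type": labels.to_numpy()})
        .groupby(["group", "cell_type"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = table.groupby("group")["count"].transform("sum")
    if (totals == 0).any():
        raise ValueError("empty group")
    table["percent"] = 100.0 * table["count"] / totals
    return table.sort_values(["group", "cell_type"], kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class FoldChange:
    ratio: float
    n_fold: int
    direction: str  # "increase" | "decrease" | "no change"

    @property
    def statement(self) -> str:
        if self.direction == "no change":
            return "no change"
        return f"{self.n_fold}-fold {self.direction}"


def fold_change(percent_a: float, percent_b: float) -> FoldChange:
    """Fold change from group a to group b, phrased like the field does.

    The ratio is always larger/smaller; the direction states whether b is an
    increase or decrease relative to a; the n-fold statement rounds the ratio
    to the nearest integer (65.6% -> 5.5% reads "12-fold decrease").
    """
    if percent_a <= 0 or percent_b <= 0:
        raise ValueError("both percentages must be positive")
    if percent_a == percent_b:
        return FoldChange(ratio=1.0, n_fold=1, direction="no change")
    ratio = max(percent_a, percent_b) / min(percent_a, percent_b)
    direction = "decrease" if percent_b < percent_a else "increase"
    return FoldChange(ratio=float(ratio), n_fold=int(round(ratio)), direction=direction)


def count_difference_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Welch t-test on per-line collected cell counts.

    Returns (t, p). Unequal variances are not assumed; degrees of freedom
    follow Welch-Satterthwaite. If both groups are constant with equal means
    the difference is exactly zero and p is reported as 1.0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return sign * float("inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
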