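"""Averaged ecosystem-multifunctionality index.

Every function variable is min-max standardized to [0, 1] across all samples
(STD = (X - Xmin) / (Xmax - Xmin)) and a sample's multifunctionality is the
mean of its standardized values. Group contrasts use one-way ANOVA plus
pairwise Welch t-tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "min_max_standardize",
    "multifunctionality_index",
    "compare_groups",
    "GroupComparison",
]


def min_max_standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Min-max standardize each column to [0, 1] across all samples.

    Per column the minimum maps to 0 and the maximum to 1; ordering within a
    column is preserved. A constant column (max == min) is mapped to all
    zeros with a warning, keeping the number of functions fixed. Min and max
    are pooled over every sample in the matrix — never per group.
    """
    matrix = pd.DataFrame(matrix).astype(float)
    if len(matrix) < 2:
        raise ValueError("standardization needs at least 2 samples")
    lo, hi = matrix.min(axis=0), matrix.max(axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        warnings.warn(
            "constant column(s) mapped to all zeros: "
            + ", ".join(map(str, matrix.columns[constant])),
            UserWarning,
            stacklevel=2,
        )
    span = span.where(~constant, 1.0)
    std = (matrix - lo) / span
    std.loc[:, constant] = 0.0
    return std


def multifunctionality_index(standardized: pd.DataFrame) -> pd.Series:
    """Per-sample average multifunctionality: the row mean of STD values."""
    standardized = pd.DataFrame(standardized).astype(float)
    if standardized.shape[1] == 0:
        raise ValueError("no function columns")
    values = standardized.to_numpy()
    if values.size and ((values < -1e-12) | (values > 1 + 1e-12)).any():
        raise ValueError("standardized values must lie in [0, 1]")
    return pd.Series(
        values.mean(axis=1), index=standardized.index, name="multifunctionality"
    )


@dataclass
class GroupComparison:
    """One-way ANOVA across groups plus all pairwise Welch t-tests."""

    group_means: pd.Series
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, t, p, degenerate
    degenerate: bool = field(default=False)


def _welch_pair(a: np.ndarray, b: np.ndarray):
    """Welch t-test robust to zero-variance groups.

    Two identical constant groups give (t=0, p=1); constant groups with
    different means are perfectly separated and reported as p=0 with a
    degenerate-variance flag.
    """
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, True
        return np.inf if a.mean() > b.mean() else -np.inf, 0.0, True
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), False


def compare_groups(index: pd.Series, grouping: pd.Series) -> GroupComparison:
    """Compare per-sample multifunctionality between groups.

    Requires >= 2 groups with >= 2 samples each. Returns group means, the
    one-way fixed-effects ANOVA F and p, and Welch t statistics for every
    group pair.
    """
    index = pd.Series(index).astype(float)
    grouping = pd.Series(grouping).reindex(index.index)
    if grouping.isna().any():
        raise ValueError("grouping is missing for some samples")
    groups = {g: index[grouping == g].to_numpy() for g in grouping.unique()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, values in groups.items():
        if len(values) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")

    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        anova_f, anova_p, degenerate = 0.0, 1.0, True
    elif all(v.var(ddof=1) == 0 for v in groups.values()):
        anova_f, anova_p, degenerate = np.inf, 0.0, True
    else:
        anova_f, anova_p = stats.f_oneway(*groups.values())
        anova_f, anova_p, degenerate = float(anova_f), float(anova_p), False

    rows = []
    for ga, gb in itertools.combinations(groups, 2):
        t, p, flag = _welch_pair(groups[ga], groups[gb])
        rows.append((ga, gb, t, p, flag))
        degenerate = degenerate or flag
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p", "degenerate"])
    means = pd.Series({g: v.mean() for g, v in groups.items()}, name="mean")
    return GroupComparison(means, anova_f, anova_p, pairwise, degenerate)
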