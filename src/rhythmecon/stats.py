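"""Shared statistical helpers: two-group tests and class-based group splits."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ComparisonResult

__all__ = ["welch_test", "split_by_class", "log_with_floor"]


def welch_test(
    x,
    y,
    category: str = "",
    controlled: bool = False,
    equal_var: bool = False,
    group_labels: tuple[str, str] = ("group1", "group2"),
) -> ComparisonResult:
    """Two-sample location test (Welch by default, Student if ``equal_var``).

    Both groups need >= 2 finite observations; raises ``ValueError`` otherwise,
    naming the category and group sizes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError(
            f"comparison {category!r} needs >= 2 observations per group "
            f"(got {len(x)} and {len(y)})"
        )
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    ci = res.confidence_interval(0.95)
    return ComparisonResult(
        category=category,
        n1=len(x),
        n2=len(y),
        mean1=float(np.mean(x)),
        mean2=float(np.mean(y)),
        statistic=float(res.statistic),
        df=float(res.df),
        pvalue=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        controlled=controlled,
        test="student" if equal_var else "welch",
        group_labels=group_labels,
    )


def split_by_class(
    values: pd.Series, classes: pd.Series
) -> tuple[pd.Series, pd.Series]:
    """Split ``values`` into (rhythmic, non_rhythmic) groups by class labels.

    Genes classified ``ambiguous`` (intermediate p-values) are excluded, as are
    genes absent from either input.
    """
    common = values.index.intersection(classes.index)
    v = values.loc[common]
    c = classes.loc[common]
    return v[c == "rhythmic"], v[c == "non_rhythmic"]


def log_with_floor(values: pd.Series) -> pd.Series:
    """Natural log with a half-minimum-positive pseudo-floor for zeros.

    Proteomics abundance tables contain exact zeros; flooring at half the
    smallest positive value keeps them in log-scale comparisons without
    distorting ranks.
    """
    v = pd.Series(values, dtype=float).copy()
    positive = v[v > 0]
    if positive.empty:
        raise ValueError("no positive values to log-transform")
    floor = positive.min() / 2.0
    v[v <= 0] = floor
    return np.log(v)
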