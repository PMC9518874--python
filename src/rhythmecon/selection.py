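"""Evolutionary constraint (dN/dS) versus rhythm class, raw and
expression-controlled.

Highly expressed genes are under stronger purifying selection, and rhythmic
genes are enriched in highly expressed genes, so a raw comparison of dN/dS
between rhythm classes is confounded. The control regresses log(dN/dS) on
log(expression) and compares the residuals between classes instead.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import ComparisonResult
from .stats import split_by_class, welch_test

logger = logging.getLogger(__name__)

__all__ = [
    "residualize_dnds",
    "compare_dnds",
    "compare_sets_dnds",
    "SELECTION_CATEGORIES",
]


def residualize_dnds(dnds: pd.Series, expression: pd.Series) -> pd.Series:
    """Residuals of the OLS fit of log(dN/dS) on log(expression).

    Genes with dN/dS = 0 or non-positive expression are excluded before the
    log (count logged at INFO).
    """
    df = pd.DataFrame({"dnds": dnds, "expr": expression}).dropna()
    usable = (df["dnds"] > 0) & (df["expr"] > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("excluding %d genes with zero dN/dS or non-positive expression", n_dropped)
    df = df[usable]
    if len(df) < 3:
        raise ValueError(f"need >= 3 usable genes for the regression, got {len(df)}")
    X = sm.add_constant(np.log(df["expr"].to_numpy()))
    fit = sm.OLS(np.log(df["dnds"].to_numpy()), X).fit()
    return pd.Series(fit.resid, index=df.index, name="dnds_residual")


SELECTION_CATEGORIES = {
    "a": "rRNA vs nrRNA (all genes)",
    "b": "rProtein vs nrProtein (all genes)",
    "c": "rRNA vs nrRNA among rhythmic proteins",
    "d": "rProtein vs nrProtein among rhythmic transcripts",
}


def compare_dnds(
    dnds: pd.Series,
    rna_classes: pd.Series,
    protein_classes: pd.Series | None,
    category: str,
    expression: pd.Series | None = None,
    controlled: bool = False,
) -> ComparisonResult:
    """Welch test of dN/dS (log scale) or its expression residuals between
    rhythm classes under one Table-2-style category design.

    Uncontrolled: log(dN/dS) values; controlled: residuals from
    :func:`residualize_dnds` (requires ``expression``).
    """
    if category not in SELECTION_CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {sorted(SELECTION_CATEGORIES)}")
    if category in ("b", "c", "d") and protein_classes is None:
        raise ValueError(f"category {category!r} needs protein rhythm classes")
    if controlled:
        if expression is None:
            raise ValueError("controlled comparison needs the expression covariate")
        values = residualize_dnds(dnds, expression)
    else:
        positive = dnds[dnds > 0]
        values = np.log(positive)

    if category == "a":
        compare, condition = rna_classes, None
    elif category == "b":
        compare, condition = protein_classes, None
    elif category == "c":
        compare = rna_classes
        condition = protein_classes[protein_classes == "rhythmic"].index
    else:  # d
        compare = protein_classes
        condition = rna_classes[rna_classes == "rhythmic"].index

    vals = values if condition is None else values.loc[values.index.intersection(condition)]
    g1, g2 = split_by_class(vals, compare)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError(
            f"category {category!r} ({SELECTION_CATEGORIES[category]}): "
            f"group sizes {len(g1)} and {len(g2)} after conditioning"
        )
    res = welch_test(
        g1, g2, category=category, controlled=controlled,
        group_labels=("rhythmic", "non_rhythmic"),
    )
    return res


def compare_sets_dnds(set_a, set_b, dnds: pd.Series) -> ComparisonResult:
    """Student's t-test of log(dN/dS) between the correlation-sign gene sets.

    Set A holds genes rhythmic where highly expressed (negative cross-tissue
    correlation of expression with rhythm p); set B the positive-correlation
    genes. The sets must be disjoint and non-singleton.
    """
    set_a = pd.Index(set_a)
    set_b = pd.Index(set_b)
    overlap = set_a.intersection(set_b)
    if len(overlap):
        raise ValueError(f"gene sets overlap ({len(overlap)} shared genes)")
    positive = dnds[dnds > 0]
    log_d = np.log(positive)
    a_vals = log_d.loc[log_d.index.intersection(set_a)]
    b_vals = log_d.loc[log_d.index.intersection(set_b)]
    return welch_test(
        a_vals, b_vals, category="sets_AB", equal_var=True,
        group_labels=("set_A", "set_B"),
    )
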