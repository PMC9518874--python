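"""Protein expression cost: C_p = N_p * L_p * c_bar_AA.

The cost of expressing a protein is its abundance times its length times the
mean biosynthetic cost of its residues (high-energy phosphate bonds per
molecule). Abundance enters under two conventions: the mean over time points
and the "maximum" defined as the average of the two largest distinct
observations (robust to a single spiky measurement). Costs are compared
between rhythm classes with Welch tests on log-scaled values (the per-residue
cost c_bar_AA is compared on its natural scale).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import AACostTable, ComparisonResult, ExpressionTimeSeries, ProteinRecord
from .stats import log_with_floor, split_by_class, welch_test

__all__ = [
    "avg_aa_cost",
    "mean_abundance",
    "max_abundance",
    "expression_cost",
    "build_cost_table",
    "compare_costs",
]

#: residues excluded from the c_bar_AA average (no defined cost); they still
#: count towards protein length
AMBIGUOUS_RESIDUES = set("BZXUJO*")


def avg_aa_cost(record: ProteinRecord, costs: AACostTable) -> float:
    """Mean per-residue synthesis cost over residues with a defined cost."""
    vals = [costs[aa] for aa in record.sequence if aa not in AMBIGUOUS_RESIDUES]
    if not vals:
        raise ValueError(
            f"protein {record.protein_id} has no residue with a defined cost"
        )
    return float(np.mean(vals))


def mean_abundance(series) -> float:
    """Arithmetic mean abundance over time points; NaN if all missing."""
    v = np.asarray(series, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return np.nan
    return float(np.mean(v))


def max_abundance(series) -> float:
    """Average of the two largest *distinct* observed values.

    A constant series (or a single observation) degenerates to that value:
    the limit of the two-distinct-maxima average as they coincide.
    """
    v = np.asarray(series, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return np.nan
    distinct = np.unique(v)  # sorted ascending
    if len(distinct) == 1:
        return float(distinct[0])
    return float((distinct[-1] + distinct[-2]) / 2.0)


def expression_cost(abundance: float, length: int, cbar_aa: float) -> float:
    if abundance < 0 or length < 0 or cbar_aa < 0:
        raise ValueError("cost inputs must be non-negative")
    return float(abundance) * float(length) * float(cbar_aa)


def build_cost_table(
    records: list[ProteinRecord],
    ts: ExpressionTimeSeries,
    costs: AACostTable,
) -> pd.DataFrame:
    """Per-protein cost table for proteins present in both inputs.

    Columns: ``L_p``, ``cbar_AA``, ``meanN``, ``maxN``, ``C_p_mean``,
    ``C_p_max``, ``cost_source``.
    """
    by_id = {r.protein_id: r for r in records}
    rows = []
    for pid in ts.gene_ids:
        rec = by_id.get(pid)
        if rec is None:
            continue
        series = ts.values.loc[pid].to_numpy(dtype=float)
        mean_n = mean_abundance(series)
        max_n = max_abundance(series)
        cbar = avg_aa_cost(rec, costs)
        rows.append(
            {
                "gene_id": pid,
                "L_p": rec.length,
                "cbar_AA": cbar,
                "meanN": mean_n,
                "maxN": max_n,
                "C_p_mean": expression_cost(mean_n, rec.length, cbar) if np.isfinite(mean_n) else np.nan,
                "C_p_max": expression_cost(max_n, rec.length, cbar) if np.isfinite(max_n) else np.nan,
                "cost_source": costs.source,
            }
        )
    if not rows:
        raise ValueError("no protein is present in both the FASTA and the expression matrix")
    return pd.DataFrame(rows).set_index("gene_id")


#: cost-table columns compared between classes, and whether each is log-scaled
_COMPONENT_LOG = {
    "C_p_mean": True,
    "C_p_max": True,
    "L_p": True,
    "meanN": True,
    "maxN": True,
    "cbar_AA": False,
}


def compare_costs(
    cost_table: pd.DataFrame,
    classes: pd.Series,
    components: tuple[str, ...] = ("C_p_mean", "C_p_max", "cbar_AA", "L_p", "meanN", "maxN"),
) -> dict[str, ComparisonResult]:
    """Welch tests of each cost component between rhythmic and non-rhythmic
    proteins. All components but ``cbar_AA`` are compared on the natural-log
    scale (with a half-minimum floor for zeros)."""
    results = {}
    for comp in components:
        vals = cost_table[comp].dropna()
        if _COMPONENT_LOG[comp]:
            vals = log_with_floor(vals)
        g_r, g_nr = split_by_class(vals, classes)
        results[comp] = welch_test(
            g_r,
            g_nr,
            category=comp,
            group_labels=("rhythmic", "non_rhythmic"),
        )
    return results
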