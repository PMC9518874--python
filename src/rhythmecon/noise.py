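"""Single-cell expression noise via the mean-decorrelated F* statistic.

Variance scales with mean expression, so raw variance is useless as a noise
measure. F* divides each gene's variance by the value predicted from a
polynomial fit of log variance on log mean across genes; the lowest
polynomial degree whose residual noise is uncorrelated with the mean (by
Kendall's tau and the regression slope) is selected. F* = 1 means exactly
on-trend variance; F* < 1 means quieter than expected for that expression
level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ComparisonResult, SingleCellMatrix
from .stats import split_by_class, welch_test

__all__ = [
    "filter_expressed",
    "fstar",
    "select_degree",
    "noise_table",
    "compare_noise",
    "NOISE_CATEGORIES",
]


def filter_expressed(sc: SingleCellMatrix, threshold: float = 1.5) -> SingleCellMatrix:
    """Keep genes with log10(FPKM + 1) > threshold in at least one cell."""
    logged = np.log10(sc.values.to_numpy(dtype=float) + 1.0)
    keep = np.nanmax(logged, axis=1) > threshold
    if not keep.any():
        raise ValueError(f"no gene passes the expression filter at {threshold}")
    return SingleCellMatrix(
        values=sc.values.loc[keep],
        cell_types=sc.cell_types,
        tissue=sc.tissue,
    )


def _fit_fstar(mu: np.ndarray, sigma2: np.ndarray, degree: int) -> np.ndarray:
    """F* at one polynomial degree: sigma2 / exp(P_d(log mu))."""
    log_mu = np.log(mu)
    log_s2 = np.log(sigma2)
    coeffs = np.polynomial.Polynomial.fit(log_mu, log_s2, degree)
    fitted = coeffs(log_mu)
    return sigma2 / np.exp(fitted)


def _decorrelation_diagnostics(fstar_vals: np.ndarray, mu: np.ndarray) -> dict:
    log_f = np.log(fstar_vals)
    log_mu = np.log(mu)
    tau = stats.kendalltau(log_mu, log_f).statistic
    reg = stats.linregress(log_mu, log_f)
    return {
        "kendall_tau": float(tau),
        "slope": float(reg.slope),
        "r_squared": float(reg.rvalue**2),
    }


def select_degree(
    mu: np.ndarray,
    sigma2: np.ndarray,
    degrees=range(1, 6),
    kendall_threshold: float = 0.05,
    slope_threshold: float = 0.05,
) -> tuple[int, pd.DataFrame]:
    """Choose the lowest polynomial degree that decorrelates F* from the mean.

    For each candidate degree the |Kendall tau|, |slope|, and R-squared of
    log F* against log mu are reported; the lowest degree meeting both
    thresholds wins, else the degree minimizing |Kendall tau| (ties broken by
    the lower degree).
    """
    degrees = list(degrees)
    if len(degrees) < 2:
        raise ValueError("need >= 2 candidate degrees")
    rows = []
    for d in degrees:
        f = _fit_fstar(mu, sigma2, d)
        diag = _decorrelation_diagnostics(f, mu)
        diag["degree"] = d
        diag["passes"] = (
            abs(diag["kendall_tau"]) < kendall_threshold
            and abs(diag["slope"]) < slope_threshold
        )
        rows.append(diag)
    table = pd.DataFrame(rows).set_index("degree")
    passing = table.index[table["passes"]]
    if len(passing):
        chosen = int(passing.min())
    else:
        chosen = int(table["kendall_tau"].abs().idxmin())
    return chosen, table


def fstar(
    mu,
    sigma2,
    degree: int | str = "auto",
    kendall_threshold: float = 0.05,
    slope_threshold: float = 0.05,
) -> tuple[pd.Series, int, pd.DataFrame | None]:
    """F* per gene given cross-cell means and variances.

    ``degree="auto"`` runs :func:`select_degree` over degrees 1..5.
    Returns (F* series, degree used, diagnostics table or None).
    """
    mu_s = pd.Series(mu, dtype=float)
    s2_s = pd.Series(sigma2, dtype=float)
    valid = (mu_s > 0) & (s2_s > 0) & mu_s.notna() & s2_s.notna()
    if valid.sum() < 20:
        raise ValueError(f"need >= 20 genes with positive mean and variance, got {int(valid.sum())}")
    mu_v = mu_s[valid].to_numpy()
    s2_v = s2_s[valid].to_numpy()
    diagnostics = None
    if degree == "auto":
        degree, diagnostics = select_degree(
            mu_v, s2_v, kendall_threshold=kendall_threshold, slope_threshold=slope_threshold
        )
    f = _fit_fstar(mu_v, s2_v, int(degree))
    out = pd.Series(np.nan, index=mu_s.index, name="fstar")
    out[valid] = f
    return out, int(degree), diagnostics


def noise_table(
    sc: SingleCellMatrix,
    degree: int | str = "auto",
    per_cell_type: bool = True,
) -> pd.DataFrame:
    """Per-gene noise table: mu, sigma2, fstar, degree_selected, n_cells_used.

    With ``per_cell_type`` the statistic is computed within each cell type and
    averaged per gene weighted by cell count; otherwise cells are pooled.
    """
    groups: list[tuple[pd.DataFrame, int]] = []
    if per_cell_type and sc.cell_types.nunique() > 1:
        for _, cells in sc.cell_types.groupby(sc.cell_types):
            sub = sc.values[cells.index]
            groups.append((sub, sub.shape[1]))
    else:
        groups.append((sc.values, sc.n_cells))

    acc = []
    for sub, n_cells in groups:
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        f, deg, _ = fstar(mu, s2, degree=degree)
        acc.append(
            pd.DataFrame(
                {"mu": mu, "sigma2": s2, "fstar": f, "degree_selected": deg, "weight": n_cells}
            )
        )
    combined = pd.concat(acc)
    combined = combined.dropna(subset=["fstar"])

    def _agg(g: pd.DataFrame) -> pd.Series:
        w = g["weight"].to_numpy(dtype=float)
        return pd.Series(
            {
                "mu": np.average(g["mu"], weights=w),
                "sigma2": np.average(g["sigma2"], weights=w),
                "fstar": np.average(g["fstar"], weights=w),
                "degree_selected": int(g["degree_selected"].iloc[0]),
                "n_cells_used": int(w.sum()),
            }
        )

    table = combined.groupby(level=0).apply(_agg)
    table.index.name = "gene_id"
    return table


#: Table-1-style comparison designs: (conditioning classes, compared classes)
NOISE_CATEGORIES = {
    "a": "rhythmic vs non-rhythmic transcripts",
    "b": "rhythmic vs non-rhythmic proteins",
    "c": "rRNA vs nrRNA among rhythmic proteins",
    "d": "rRNA vs nrRNA among non-rhythmic proteins",
    "e": "rProtein vs nrProtein among constant transcripts",
}


def compare_noise(
    noise: pd.DataFrame,
    rna_classes: pd.Series,
    protein_classes: pd.Series | None,
    category: str,
) -> ComparisonResult:
    """Welch test of log F* between rhythm classes under one category design.

    a: rhythmic vs non-rhythmic transcripts (all genes);
    b: rhythmic vs non-rhythmic proteins;
    c/d: transcripts compared within rhythmic / non-rhythmic proteins;
    e: proteins compared within genes with constant (non-rhythmic) transcripts.
    """
    if category not in NOISE_CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {sorted(NOISE_CATEGORIES)}")
    if category in ("b", "c", "d", "e") and protein_classes is None:
        raise ValueError(f"category {category!r} needs protein rhythm classes")
    log_f = np.log(noise["fstar"].dropna())

    if category == "a":
        compare, condition = rna_classes, None
    elif category == "b":
        compare, condition = protein_classes, None
    elif category == "c":
        compare = rna_classes
        condition = protein_classes[protein_classes == "rhythmic"].index
    elif category == "d":
        compare = rna_classes
        condition = protein_classes[protein_classes == "non_rhythmic"].index
    else:  # e
        compare = protein_classes
        condition = rna_classes[rna_classes == "non_rhythmic"].index

    vals = log_f if condition is None else log_f.loc[log_f.index.intersection(condition)]
    g1, g2 = split_by_class(vals, compare)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError(
            f"category {category!r} ({NOISE_CATEGORIES[category]}): conditioning "
            f"left group sizes {len(g1)} and {len(g2)}"
        )
    return welch_test(g1, g2, category=category, group_labels=("rhythmic", "non_rhythmic"))
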