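"""Multi-tissue analyses: Z normalization, the delta statistic, tissue
specificity (tau), and the cross-tissue expression/rhythmicity correlations.

delta asks, gene by gene, whether expression is higher in the tissues where
the gene is rhythmic than in those where it is flat; tau (Yanai's index)
measures how concentrated a gene's expression is in few tissues (0 = uniform,
1 = single-tissue).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "z_normalize",
    "delta",
    "test_delta",
    "OneSampleResult",
    "tau",
    "tau_table",
    "tau_vs_rhythmic_breadth",
    "per_gene_expression_rhythm_correlation",
]


def z_normalize(values: pd.Series) -> pd.Series:
    """Z-score across genes within one tissue, rescaled by the maximum z.

    ``z_i = (x_i - mean) / sd``, then divided by ``max(z)`` so the largest
    value is exactly 1. Values below the mean stay negative; only the upper
    range is mapped into (0, 1].
    """
    v = pd.Series(values, dtype=float)
    finite = v.dropna()
    if len(finite) < 2:
        raise ValueError("need >= 2 finite values to Z-normalize")
    sd = float(finite.std(ddof=1))
    if sd == 0:
        raise ValueError("zero standard deviation: cannot Z-normalize")
    z = (v - finite.mean()) / sd
    return z / float(z.max())


def delta(
    mean_z: pd.DataFrame,
    rhythm_classes: pd.DataFrame,
) -> pd.Series:
    """Per-gene difference in normalized expression, rhythmic minus
    non-rhythmic tissues.

    ``mean_z``: gene x tissue normalized expression; ``rhythm_classes``:
    gene x tissue labels in {rhythmic, non_rhythmic, ambiguous}. Genes
    lacking at least one tissue in each group are excluded (NaN).
    """
    if not mean_z.columns.equals(rhythm_classes.columns):
        rhythm_classes = rhythm_classes[mean_z.columns]
    z = mean_z.to_numpy(dtype=float)
    cls = rhythm_classes.to_numpy()
    r_mask = (cls == "rhythmic") & np.isfinite(z)
    nr_mask = (cls == "non_rhythmic") & np.isfinite(z)
    with np.errstate(invalid="ignore"):
        r_mean = np.where(r_mask.any(axis=1), np.nansum(np.where(r_mask, z, 0.0), axis=1) / r_mask.sum(axis=1), np.nan)
        nr_mean = np.where(nr_mask.any(axis=1), np.nansum(np.where(nr_mask, z, 0.0), axis=1) / nr_mask.sum(axis=1), np.nan)
    return pd.Series(r_mean - nr_mean, index=mean_z.index, name="delta")


@dataclass
class OneSampleResult:
    mean: float
    statistic: float
    df: int
    pvalue: float
    ci_low: float
    ci_high: float
    n: int


def test_delta(deltas) -> OneSampleResult:
    """One-sample Student's t-test of the delta distribution mean against 0."""
    d = np.asarray(pd.Series(deltas).dropna(), dtype=float)
    if len(d) < 2:
        raise ValueError(f"need >= 2 deltas, got {len(d)}")
    if np.ptp(d) == 0 and d[0] == 0.0:
        # degenerate all-zero distribution: no evidence against the null
        return OneSampleResult(0.0, 0.0, len(d) - 1, 1.0, 0.0, 0.0, len(d))
    res = stats.ttest_1samp(d, 0.0)
    ci = res.confidence_interval(0.95)
    return OneSampleResult(
        mean=float(np.mean(d)),
        statistic=float(res.statistic),
        df=int(res.df),
        pvalue=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n=len(d),
    )


def tau(per_tissue_expression, log_transform: bool = True) -> float:
    """Yanai's tissue-specificity index for one gene.

    Expression is log2(x + 1)-transformed (negatives clamped to 0), scaled by
    the maximum across tissues, and tau = sum(1 - scaled) / (n - 1).
    Returns NaN for genes with no expression anywhere.
    """
    x = np.asarray(per_tissue_expression, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        raise ValueError("tau needs >= 2 tissues")
    if (x < 0).any():
        raise ValueError("expression must be non-negative")
    if log_transform:
        x = np.log2(x + 1.0)
    x = np.maximum(x, 0.0)
    m = x.max()
    if m == 0:
        return np.nan
    n_hat = x / m
    return float(np.sum(1.0 - n_hat) / (n - 1))


def tau_table(mean_expr: pd.DataFrame, log_transform: bool = True) -> pd.Series:
    """tau for every gene of a gene x tissue mean-expression matrix."""
    out = {}
    for gene, row in mean_expr.iterrows():
        vals = row.dropna()
        out[gene] = tau(vals.to_numpy(), log_transform=log_transform) if len(vals) >= 2 else np.nan
    return pd.Series(out, name="tau")


def _partial_corr(x: np.ndarray, y: np.ndarray, covar: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing the covariate out of both."""
    X = np.column_stack([np.ones_like(covar), covar])
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    r, p = stats.pearsonr(rx, ry)
    return float(r), float(p)


def tau_vs_rhythmic_breadth(
    taus: pd.Series,
    n_rhythmic_tissues: pd.Series,
    covariate: pd.Series | None = None,
) -> dict:
    """Correlation of tissue specificity with the number of rhythmic tissues.

    Reports Pearson and Spearman coefficients with tests, plus a partial
    Pearson correlation controlling for the covariate (cross-tissue mean
    expression by default in the pipeline).
    """
    df = pd.DataFrame({"tau": taus, "breadth": n_rhythmic_tissues}).dropna()
    if len(df) < 10:
        raise ValueError(f"need >= 10 genes with both values, got {len(df)}")
    if df["tau"].nunique() < 2 or df["breadth"].nunique() < 2:
        raise ValueError("degenerate variance: correlation undefined")
    pear = stats.pearsonr(df["tau"], df["breadth"])
    spear = stats.spearmanr(df["tau"], df["breadth"])
    out = {
        "n": len(df),
        "pearson_r": float(pear.statistic),
        "pearson_p": float(pear.pvalue),
        "spearman_rho": float(spear.statistic),
        "spearman_p": float(spear.pvalue),
    }
    if covariate is not None:
        cov = covariate.reindex(df.index)
        mask = cov.notna()
        r, p = _partial_corr(
            df.loc[mask, "tau"].to_numpy(),
            df.loc[mask, "breadth"].to_numpy(dtype=float),
            cov[mask].to_numpy(dtype=float),
        )
        out["partial_pearson_r"] = r
        out["partial_pearson_p"] = p
    return out


def per_gene_expression_rhythm_correlation(
    mean_expr: pd.DataFrame,
    rhythm_p: pd.DataFrame,
    taus: pd.Series,
    tau_threshold: float = 0.5,
    min_tissues: int = 4,
) -> pd.DataFrame:
    """Across-tissue correlation of expression with the rhythm p-value,
    for tissue-specific genes (tau > threshold).

    A negative correlation means the gene is most rhythmic (lowest p) where
    it is most expressed. Genes are partitioned by the sign of the Spearman
    coefficient into set A (negative) and set B (positive) for the selection
    hand-off; genes with fewer than ``min_tissues`` informative tissues are
    skipped.

    Returns a frame with columns ``pearson_r``, ``spearman_rho``, ``n_tissues``,
    ``set`` ('A', 'B', or '' when the coefficient is 0/undefined).
    """
    specific = taus[taus > tau_threshold].index
    rows = []
    for gene in specific:
        if gene not in mean_expr.index or gene not in rhythm_p.index:
            continue
        e = mean_expr.loc[gene]
        p = rhythm_p.loc[gene]
        df = pd.DataFrame({"expr": e, "p": p}).dropna()
        if len(df) < min_tissues or df["expr"].nunique() < 2 or df["p"].nunique() < 2:
            continue
        pear = stats.pearsonr(df["expr"], df["p"]).statistic
        spear = stats.spearmanr(df["expr"], df["p"]).statistic
        label = "A" if spear < 0 else ("B" if spear > 0 else "")
        rows.append(
            {
                "gene_id": gene,
                "pearson_r": float(pear),
                "spearman_rho": float(spear),
                "n_tissues": len(df),
                "set": label,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["pearson_r", "spearman_rho", "n_tissues", "set"]
    )
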