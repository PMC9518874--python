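"""Z normalization, delta, tau, and the cross-tissue correlation analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhythmecon import (
    SimulationConfig,
    delta,
    per_gene_expression_rhythm_correlation,
    simulate_multitissue,
    tau,
    tau_table,
    tau_vs_rhythmic_breadth,
    test_delta as delta_mean_test,
    z_normalize,
)

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


# -- Z normalization -----------------------------------------------------------


def test_z_normalize_arithmetic():
    z = z_normalize(pd.Series([1.0, 2.0, 3.0]))
    np.testing.assert_allclose(z.to_numpy(), [-1.0, 0.0, 1.0])


def test_z_normalize_location_invariance():
    x = pd.Series([4.0, 9.0, 1.0, 7.0])
    z1 = z_normalize(x)
    z2 = z_normalize(x + 100.0)
    np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)


def test_z_normalize_max_is_exactly_one():
    rng = np.random.default_rng(0)
    z = z_normalize(pd.Series(rng.lognormal(size=50)))
    assert z.max() == pytest.approx(1.0, abs=0)


def test_z_normalize_zero_sd_rejected():
    with pytest.raises(ValueError, match="standard deviation"):
        z_normalize(pd.Series([3.0, 3.0, 3.0]))


# -- delta ---------------------------------------------------------------------


def _frame(z_rows, cls_rows, tissues=None):
    tissues = tissues or [f"t{i}" for i in range(len(z_rows[0]))]
    genes = [f"g{i}" for i in range(len(z_rows))]
    return (
        pd.DataFrame(z_rows, index=genes, columns=tissues),
        pd.DataFrame(cls_rows, index=genes, columns=tissues),
    )


def test_delta_arithmetic():
    z, cls = _frame(
        [[0.8, 0.6, 0.3]],
        [["rhythmic", "rhythmic", "non_rhythmic"]],
    )
    assert delta(z, cls).iloc[0] == pytest.approx(0.4)


def test_delta_zero_when_group_means_equal():
    z, cls = _frame(
        [[0.5, 0.3, 0.5, 0.3]],
        [["rhythmic", "rhythmic", "non_rhythmic", "non_rhythmic"]],
    )
    assert delta(z, cls).iloc[0] == pytest.approx(0.0)


def test_delta_excludes_genes_missing_a_group():
    z, cls = _frame(
        [[0.5, 0.3], [0.2, 0.9]],
        [["rhythmic", "rhythmic"], ["rhythmic", "non_rhythmic"]],
    )
    d = delta(z, cls)
    assert np.isnan(d.iloc[0])
    assert d.iloc[1] == pytest.approx(-0.7)


def test_delta_ambiguous_tissues_ignored():
    z, cls = _frame(
        [[0.8, 0.2, 100.0]],
        [["rhythmic", "non_rhythmic", "ambiguous"]],
    )
    assert delta(z, cls).iloc[0] == pytest.approx(0.6)


def test_delta_permutation_null_is_centered():
    """Random tissue labels: mean delta within 3 SE of 0."""
    rng = np.random.default_rng(31)
    z = pd.DataFrame(rng.normal(size=(150, 6)),
                     index=[f"g{i}" for i in range(150)],
                     columns=[f"t{i}" for i in range(6)])
    rep_means = []
    for _ in range(200):
        labels = rng.permuted(
            np.tile(["rhythmic", "rhythmic", "non_rhythmic",
                     "non_rhythmic", "non_rhythmic", "non_rhythmic"], (150, 1)),
            axis=1,
        )
        cls = pd.DataFrame(labels, index=z.index, columns=z.columns)
        rep_means.append(delta(z, cls).mean())
    rep_means = np.asarray(rep_means)
    se = rep_means.std(ddof=1) / np.sqrt(len(rep_means))
    assert abs(rep_means.mean()) < 3 * se


# -- one-sample test -----------------------------------------------------------


def test_delta_mean_test_all_zeros():
    res = delta_mean_test([0.0, 0.0, 0.0])
    assert res.statistic == 0.0
    assert res.pvalue == 1.0


def test_delta_mean_test_closed_form():
    res = delta_mean_test([0.1, 0.2, 0.3])
    assert res.mean == pytest.approx(0.2)
    assert res.statistic == pytest.approx(2 * np.sqrt(3), rel=1e-12)
    assert res.df == 2


def test_delta_mean_test_needs_two_values():
    with pytest.raises(ValueError):
        delta_mean_test([0.1])


def test_delta_planted_coupling_detected():
    """With the tissue coupling on, the one-sample CI excludes 0."""
    hits = 0
    for rep in range(20):
        cfg = SimulationConfig(
            n_genes=250, n_tissues=5, tissue_coupling=1.0, tissue_specific_fraction=0.6,
            n_timepoints=4, sampling_interval_h=6, n_cycles=1, seed=6000 + rep,
        )
        series, truth = simulate_multitissue(cfg)
        mean_expr = pd.DataFrame({t.tissue: t.values.mean(axis=1) for t in series})
        mean_z = pd.DataFrame({c: z_normalize(mean_expr[c]) for c in mean_expr.columns})
        cls = pd.DataFrame(
            np.where(
                truth[[f"rhythmic_in_{c}" for c in mean_expr.columns]].to_numpy(),
                "rhythmic",
                "non_rhythmic",
            ),
            index=truth.index,
            columns=mean_expr.columns,
        )
        res = delta_mean_test(delta(mean_z, cls))
        hits += res.ci_low > 0
    assert hits >= 19  # >= 95% of reps


# -- tau -----------------------------------------------------------------------


def test_tau_boundary_cases():
    assert tau([10.0, 0.0, 0.0, 0.0]) == pytest.approx(1.0)
    assert tau([5.0, 5.0, 5.0]) == pytest.approx(0.0)
    # log2 means [4, 2, 2]  ->  N_hat [1, .5, .5]  ->  tau 0.5
    expr = [2.0**4 - 1, 2.0**2 - 1, 2.0**2 - 1]
    assert tau(expr) == pytest.approx(0.5)


def test_tau_nan_for_silent_gene_and_input_contracts():
    assert np.isnan(tau([0.0, 0.0]))
    with pytest.raises(ValueError):
        tau([1.0])
    with pytest.raises(ValueError):
        tau([-1.0, 2.0])


def test_tau_approximately_scale_invariant_at_high_expression():
    rng = np.random.default_rng(7)
    expr = rng.uniform(1e3, 1e5, size=8)
    assert tau(expr) == pytest.approx(tau(expr * 10), abs=0.02)


def test_tau_table_matches_per_gene_calls():
    mat = pd.DataFrame(
        [[100.0, 1.0, 1.0], [50.0, 50.0, 50.0]],
        index=["gA", "gB"], columns=["t1", "t2", "t3"],
    )
    t = tau_table(mat)
    assert t["gA"] == pytest.approx(tau([100.0, 1.0, 1.0]))
    assert t["gB"] == pytest.approx(0.0)


# -- tau vs breadth ------------------------------------------------------------


def test_tau_vs_breadth_degenerate_variance_rejected():
    taus = pd.Series(np.linspace(0, 1, 20))
    breadth = pd.Series(np.full(20, 3))
    with pytest.raises(ValueError, match="degenerate"):
        tau_vs_rhythmic_breadth(taus, breadth)


def test_tau_vs_breadth_recovers_negative_sign():
    hits = 0
    for rep in range(20):
        cfg = SimulationConfig(
            n_genes=300, n_tissues=5, tissue_coupling=1.0, tissue_specific_fraction=0.5,
            n_timepoints=4, sampling_interval_h=6, n_cycles=1, seed=7000 + rep,
        )
        series, truth = simulate_multitissue(cfg)
        mean_expr = pd.DataFrame({t.tissue: t.values.mean(axis=1) for t in series})
        taus = tau_table(mean_expr)
        breadth = truth[[f"rhythmic_in_{c}" for c in mean_expr.columns]].sum(axis=1)
        # tissue-specific genes concentrate their rhythm in one tissue;
        # broadly expressed genes spread it, so tau and breadth anticorrelate
        out = tau_vs_rhythmic_breadth(taus, breadth)
        hits += out["pearson_r"] < 0
    assert hits >= 19


def test_partial_correlation_matches_plain_when_covariate_independent():
    rng = np.random.default_rng(13)
    n = 5000
    x = rng.normal(size=n)
    y = 0.5 * x + rng.normal(size=n)
    cov = rng.normal(size=n)  # independent of both
    out = tau_vs_rhythmic_breadth(
        pd.Series(x), pd.Series(y), covariate=pd.Series(cov)
    )
    assert abs(out["partial_pearson_r"] - out["pearson_r"]) < 0.02


# -- per-gene expression/rhythm correlation ------------------------------------


def test_per_gene_correlation_negative_by_construction():
    tissues = [f"t{i}" for i in range(6)]
    expr = pd.DataFrame([[10.0, 20.0, 30.0, 40.0, 50.0, 60.0]], index=["gA"], columns=tissues)
    pvals = pd.DataFrame([[0.9, 0.7, 0.5, 0.3, 0.1, 0.01]], index=["gA"], columns=tissues)
    taus = pd.Series({"gA": 0.8})
    out = per_gene_expression_rhythm_correlation(expr, pvals, taus)
    assert out.loc["gA", "spearman_rho"] == pytest.approx(-1.0)
    assert out.loc["gA", "set"] == "A"


def test_per_gene_correlation_null_centered_under_shuffling():
    rng = np.random.default_rng(17)
    n_genes, n_tissues = 200, 8
    tissues = [f"t{i}" for i in range(n_tissues)]
    genes = [f"g{i}" for i in range(n_genes)]
    expr = pd.DataFrame(rng.lognormal(3, 1, (n_genes, n_tissues)), index=genes, columns=tissues)
    pvals = pd.DataFrame(rng.uniform(size=(n_genes, n_tissues)), index=genes, columns=tissues)
    taus = pd.Series(1.0, index=genes)  # everyone passes the specificity gate
    out = per_gene_expression_rhythm_correlation(expr, pvals, taus)
    mean_rho = out["spearman_rho"].mean()
    se = out["spearman_rho"].std(ddof=1) / np.sqrt(len(out))
    assert abs(mean_rho) < 4 * se
    assert {"A", "B"} <= set(out["set"])


def test_per_gene_correlation_skips_sparse_genes():
    tissues = [f"t{i}" for i in range(3)]
    expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["gA"], columns=tissues)
    pvals = pd.DataFrame([[0.1, 0.2, 0.3]], index=["gA"], columns=tissues)
    out = per_gene_expression_rhythm_correlation(expr, pvals, pd.Series({"gA": 0.9}))
    assert out.empty
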