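"""Detector calibration and power, Brown's combination, diagnostics,
and classification rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rhythmecon import (
    ExpressionTimeSeries,
    SimulationConfig,
    classify,
    combine_by_gene,
    combine_pvalues_brown,
    detect_rhythm,
    diagnose_pvalue_distribution,
    simulate_timeseries,
)


def _make_ts(values: np.ndarray, times: np.ndarray) -> ExpressionTimeSeries:
    cols = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionTimeSeries(
        values=pd.DataFrame(values, columns=cols,
                            index=[f"g{i}" for i in range(values.shape[0])]),
        time_h=pd.Series(times, index=cols),
        replicate=pd.Series(["r"] * len(times), index=cols),
    )


def test_pure_cosine_detected_with_numerically_zero_p():
    t = np.arange(0, 48, 2.0)
    y = np.exp(2 + 0.5 * np.cos(2 * np.pi * t / 24))
    p = detect_rhythm(_make_ts(y[None, :], t), detector="cosinor_F")
    assert p.iloc[0] < 1e-10


def test_constant_series_gets_p_one_with_warning():
    t = np.arange(0, 48, 4.0)
    vals = np.vstack([np.full_like(t, 7.0), np.exp(np.cos(2 * np.pi * t / 24))])
    with pytest.warns(UserWarning, match="constant"):
        p = detect_rhythm(_make_ts(vals, t))
    assert p.iloc[0] == 1.0
    assert p.iloc[1] < 0.01


def test_too_few_usable_samples_gives_missing_p():
    t = np.array([0.0, 6.0, 12.0, 18.0])
    vals = np.array([[1.0, 2.0, np.nan, 4.0]])  # 3 usable
    p = detect_rhythm(_make_ts(vals, t))
    assert np.isnan(p.iloc[0])


def test_cosinor_type_I_error_calibrated():
    cfg = SimulationConfig(n_genes=500, rhythmic_fraction=0.0, seed=101)
    ts, _ = simulate_timeseries(cfg)
    p = detect_rhythm(ts, detector="cosinor_F")
    frac = (p < 0.05).mean()
    assert 0.02 < frac < 0.09


def test_cosinor_null_pvalues_uniform():
    cfg = SimulationConfig(n_genes=5000, rhythmic_fraction=0.0, seed=103)
    ts, _ = simulate_timeseries(cfg)
    p = detect_rhythm(ts, detector="cosinor_F")
    ks = stats.kstest(p, "uniform").statistic
    assert ks < 0.03


def test_cosinor_power_at_twice_noise_amplitude():
    cfg = SimulationConfig(n_genes=500, rhythmic_fraction=0.5,
                           amplitude_rel=0.6, noise_sd=0.3, seed=105)
    ts, truth = simulate_timeseries(cfg)
    p = detect_rhythm(ts, detector="cosinor_F")
    power = (p[truth["is_rhythmic_rna"]] < 0.01).mean()
    assert power >= 0.9


def test_median_p_monotone_in_amplitude():
    """More planted amplitude never raises the median p-value."""
    medians = []
    for amp in (0.0, 0.15, 0.3, 0.6, 1.2):
        cfg = SimulationConfig(n_genes=300, rhythmic_fraction=1.0,
                               amplitude_rel=amp, noise_sd=0.3, seed=107)
        ts, _ = simulate_timeseries(cfg)
        medians.append(detect_rhythm(ts).median())
    assert all(b <= a + 1e-12 for a, b in zip(medians, medians[1:]))


def test_robust_detector_calibration_and_power():
    cfg = SimulationConfig(n_genes=60, rhythmic_fraction=0.5,
                           amplitude_rel=0.9, noise_sd=0.3, seed=109)
    ts, truth = simulate_timeseries(cfg)
    p = detect_rhythm(ts, detector="robust_regression_perm",
                      n_permutations=200, seed=1)
    p2 = detect_rhythm(ts, detector="robust_regression_perm",
                       n_permutations=200, seed=1)
    pd.testing.assert_series_equal(p, p2)  # seeded permutations reproduce
    assert (p[truth["is_rhythmic_rna"]] < 0.05).mean() >= 0.8
    assert (p[~truth["is_rhythmic_rna"]] < 0.05).mean() < 0.2
    with pytest.raises(ValueError, match="seed"):
        detect_rhythm(ts, detector="robust_regression_perm")


def test_detector_needs_two_distinct_timepoints():
    t = np.full(6, 24.0)
    vals = np.random.default_rng(0).lognormal(size=(2, 6))
    with pytest.raises(ValueError, match="distinct time points"):
        detect_rhythm(_make_ts(vals, t))


# -- Brown's method ------------------------------------------------------------


def test_brown_single_p_returned_unchanged():
    data = np.random.default_rng(0).normal(size=(1, 30))
    for p in (0.013, 0.5, 0.99):
        assert combine_pvalues_brown([p], data) == pytest.approx(p, abs=0)


def test_brown_rejects_bad_inputs():
    data = np.random.default_rng(0).normal(size=(2, 30))
    with pytest.raises(ValueError):
        combine_pvalues_brown([], np.empty((0, 30)))
    with pytest.raises(ValueError):
        combine_pvalues_brown([0.0, 0.5], data)
    with pytest.raises(ValueError):
        combine_pvalues_brown([1.1, 0.5], data)
    with pytest.raises(ValueError):
        combine_pvalues_brown([0.5], data)  # 1 p, 2 rows


def test_brown_matches_fisher_under_independence():
    rng = np.random.default_rng(11)
    p = np.array([0.5, 0.5])
    fisher = stats.chi2.sf(-2 * np.sum(np.log(p)), 4)
    combined = [combine_pvalues_brown(p, rng.normal(size=(2, 200))) for _ in range(100)]
    assert abs(np.mean(combined) - fisher) / fisher < 0.1


def test_brown_duplicate_row_collapses_to_single_test():
    rng = np.random.default_rng(5)
    row = rng.normal(size=400)
    for p in (0.05, 0.3):
        combined = combine_pvalues_brown([p, p], np.vstack([row, row]))
        fisher = stats.chi2.sf(-4 * np.log(p), 4)
        assert abs(combined - p) < 0.02      # near the single-row p
        assert abs(combined - p) < abs(combined - fisher)  # not the Fisher value


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    k=st.integers(min_value=1, max_value=6),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_brown_always_in_unit_interval(k, seed):
    rng = np.random.default_rng(seed)
    pvals = rng.uniform(1e-6, 1.0, k)
    data = rng.normal(size=(k, 50))
    assert 0.0 <= combine_pvalues_brown(pvals, data) <= 1.0


def test_combine_by_gene_groups_duplicate_ids():
    rng = np.random.default_rng(3)
    data = pd.DataFrame(rng.normal(size=(3, 40)), index=["gX", "gX", "gY"])
    pvals = pd.Series([0.02, 0.04, 0.7], index=data.index)
    combined = combine_by_gene(pvals, data)
    assert set(combined.index) == {"gX", "gY"}
    assert combined["gY"] == pytest.approx(0.7)
    assert combined["gX"] < 0.04  # two concordant small p-values reinforce


# -- diagnostics ---------------------------------------------------------------


def test_diagnose_uniform_acceptable():
    rng = np.random.default_rng(1)
    rep = diagnose_pvalue_distribution(rng.uniform(size=2000))
    assert rep["acceptable"]
    assert rep["low_bin_enrichment"] == pytest.approx(1.0, abs=0.3)


def test_diagnose_rhythmic_mixture_acceptable():
    rng = np.random.default_rng(2)
    p = np.concatenate([rng.uniform(0, 0.01, 400), rng.uniform(size=1600)])
    rep = diagnose_pvalue_distribution(p)
    assert rep["acceptable"]
    assert rep["low_bin_enrichment"] > 1.0


def test_diagnose_anticonservative_shape_rejected():
    rng = np.random.default_rng(3)
    p = rng.beta(2, 1, size=2000)  # skewed towards high values
    rep = diagnose_pvalue_distribution(p)
    assert not rep["acceptable"]


def test_diagnose_needs_enough_pvalues():
    with pytest.raises(ValueError):
        diagnose_pvalue_distribution(np.full(50, 0.5))


# -- classification ------------------------------------------------------------


def test_threshold_classification_rule():
    p = pd.Series([0.005, 0.3, 0.7], index=list("abc"))
    out = classify(p, mode="threshold", p_rhythmic=0.01, p_flat=0.5)
    assert list(out["class"]) == ["rhythmic", "ambiguous", "non_rhythmic"]


def test_top_fraction_takes_exactly_15_of_100():
    rng = np.random.default_rng(4)
    p = pd.Series(rng.uniform(size=100), index=[f"g{i:03d}" for i in range(100)])
    out = classify(p, mode="top_fraction", top_fraction=0.15)
    assert (out["class"] == "rhythmic").sum() == 15
    # the rhythmic set is exactly the 15 smallest p-values
    assert set(out[out["class"] == "rhythmic"].index) == set(p.nsmallest(15).index)


def test_top_fraction_ties_broken_by_stable_order():
    p = pd.Series(0.5, index=[f"g{i}" for i in range(10)])
    out = classify(p, mode="top_fraction", top_fraction=0.2)
    assert list(out[out["class"] == "rhythmic"].index) == ["g0", "g1"]


def test_invalid_thresholds_rejected():
    p = pd.Series([0.1, 0.2])
    with pytest.raises(ValueError):
        classify(p, p_rhythmic=0.6, p_flat=0.5)
    with pytest.raises(ValueError):
        classify(p, mode="bogus")
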