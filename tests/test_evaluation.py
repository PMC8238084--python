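"""Aggregation: bias, regression, correlations, determinism, round-trips."""

import numpy as np
import pandas as pd
import pytest

from rtexclude import (
    SimConfig,
    bias_exclusion_correlation,
    compute_bias,
    regress_t_values,
    run_experiment,
    sample_skewness,
    significance_proportion,
    summarize_bias,
)


def toy_records(sig_by_method, approach="tails", diff=0.0):
    """Records with a given significance pattern per method."""
    rows = []
    for method, flags in sig_by_method.items():
        for rep, s in enumerate(flags):
            rows.append(
                {
                    "approach": approach,
                    "diff": diff,
                    "rep": rep,
                    "method": method,
                    "significant": bool(s),
                }
            )
    return pd.DataFrame(rows)


def test_significance_proportion_counts():
    rec = toy_records({"valid": [1] * 5 + [0] * 5, "2sd": [1, 1, 1] + [0] * 7})
    assert significance_proportion(rec, "2sd", "tails", 0.0) == pytest.approx(0.3)
    assert significance_proportion(rec, "valid", "tails", 0.0) == pytest.approx(0.5)
    with pytest.raises(ValueError, match="no records"):
        significance_proportion(rec, "MAD", "tails", 0.0)


def test_bias_is_gap_to_valid_and_zero_for_valid():
    rec = toy_records({"valid": [1] * 5 + [0] * 5, "2sd": [1] * 6 + [0] * 4})
    bias = compute_bias(rec)
    by = bias.set_index("method")["bias"]
    assert by["2sd"] == pytest.approx(0.10)
    assert by["valid"] == 0.0


def test_bias_requires_valid_rows():
    rec = toy_records({"2sd": [1, 0, 1]})
    with pytest.raises(ValueError, match="valid"):
        compute_bias(rec)


def test_bias_summary_layout(tiny_study):
    table = tiny_study.bias_table
    assert list(table.columns) == ["mean", "tails", "overlap"]
    assert set(table.index) == set(tiny_study.config.methods)
    np.testing.assert_allclose(
        table["mean"], table[["tails", "overlap"]].mean(axis=1)
    )
    # sorted by decreasing |mean|
    assert list(table["mean"].abs()) == sorted(table["mean"].abs(), reverse=True)


def test_regression_recovers_planted_coefficients():
    rng = np.random.default_rng(12)
    n = 4000
    methods = np.array(["no", "2sd", "MAD"])[rng.integers(0, 3, n)]
    diff = rng.uniform(0, 100, n)
    sd = rng.normal(175, 25, n)
    ntr = rng.uniform(20, 100, n)
    true = {"intercept": -1.0, "diff": 0.03, "mean_sd": -0.002, "mean_n": 0.014,
            "method[2sd]": 0.7, "method[MAD]": 1.2}
    t = (
        true["intercept"]
        + true["diff"] * diff
        + true["mean_sd"] * sd
        + true["mean_n"] * ntr
        + np.where(methods == "2sd", true["method[2sd]"], 0.0)
        + np.where(methods == "MAD", true["method[MAD]"], 0.0)
        + rng.normal(0, 0.5, n)
    )
    rec = pd.DataFrame(
        {
            "method": methods,
            "diff": diff,
            "t": t,
            "sd_after_1": sd,
            "sd_after_2": sd,
            "n_after_1": ntr,
            "n_after_2": ntr,
        }
    )
    fit = regress_t_values(rec)
    for name, value in true.items():
        est, se = fit.loc[name, "beta"], fit.loc[name, "se"]
        assert abs(est - value) <= 3 * se, name


def test_regression_needs_two_methods():
    rec = pd.DataFrame(
        {
            "method": ["no"] * 5,
            "diff": range(5),
            "t": np.arange(5.0),
            "sd_after_1": 175.0,
            "sd_after_2": 175.0,
            "n_after_1": 60,
            "n_after_2": 60,
        }
    )
    with pytest.raises(ValueError, match="at least 2 methods"):
        regress_t_values(rec)


def _corr_tables(props, biases):
    methods = ["2sd", "MAD", "q10"][: len(props)]
    rec = pd.DataFrame(
        {
            "approach": "tails",
            "diff": 0.0,
            "method": methods,
            "prop_excluded_low": np.asarray(props) / 2,
            "prop_excluded_high": np.asarray(props) / 2,
        }
    )
    bias = pd.DataFrame(
        {"approach": "tails", "diff": 0.0, "method": methods, "bias": biases}
    )
    return bias, rec


def test_bias_exclusion_correlation_perfect_line():
    bias, rec = _corr_tables([0.02, 0.04, 0.08], [0.01, 0.02, 0.04])
    out = bias_exclusion_correlation(bias, rec)
    assert out["tails"]["cells"] == pytest.approx(1.0)


def test_bias_exclusion_correlation_degenerate_inputs():
    bias, rec = _corr_tables([0.05, 0.05, 0.05], [0.01, 0.02, 0.04])
    with pytest.raises(ValueError, match="zero variance"):
        bias_exclusion_correlation(bias, rec)
    bias2, rec2 = _corr_tables([0.02, 0.04], [0.01, 0.02])
    with pytest.raises(ValueError, match="fewer than 3"):
        bias_exclusion_correlation(bias2, rec2)


def test_sample_skewness_matches_moment_definition():
    x = np.array([1.0, 2.0, 3.0, 10.0])
    d = x - x.mean()
    expected = (d**3).mean() / ((d**2).mean()) ** 1.5
    assert sample_skewness(x) == pytest.approx(expected)
    assert np.isnan(sample_skewness(np.full(5, 3.0)))


def test_rerun_with_same_seed_is_identical(tiny_study):
    again = run_experiment(tiny_study.config)
    pd.testing.assert_frame_equal(tiny_study.records, again.records)
    pd.testing.assert_frame_equal(tiny_study.bias_table, again.bias_table)


def test_each_iteration_block_is_complete(tiny_study):
    rec = tiny_study.records
    n_methods = len(tiny_study.config.methods)
    sizes = rec.groupby(["approach", "diff", "rep"], observed=True).size()
    assert (sizes == n_methods + 1).all()
    n_valid = (
        rec[rec["method"] == "valid"]
        .groupby(["approach", "diff", "rep"], observed=True)
        .size()
    )
    assert (n_valid == 1).all()


def test_records_roundtrip_reproduces_bias(tiny_study, tmp_path):
    out = tiny_study.save(tmp_path / "run")
    back = pd.read_csv(out / "records.csv")
    bias2 = compute_bias(back)
    key = ["approach", "diff", "method"]
    a = tiny_study.bias.astype({"approach": str, "method": str}).sort_values(key)
    b = bias2.sort_values(key)
    np.testing.assert_allclose(
        a["bias"].to_numpy(), b["bias"].to_numpy(), atol=1e-12
    )
    np.testing.assert_allclose(
        a["p_sign"].to_numpy(), b["p_sign"].to_numpy(), atol=1e-12
    )


def test_study_regression_ranks_predictors_like_full_run(study):
    """Population difference is the dominant predictor of the t-values and
    the adjusted MAD rule carries the largest method coefficient."""
    fit = study.regression
    assert fit["t"].abs().idxmax() == "diff"
    method_rows = fit[fit.index.str.startswith("method[")]
    assert method_rows["beta"].idxmax() == "method[MAD_adjusted]"


def test_bias_tracks_excluded_proportion_more_under_tails(study):
    corr = study.correlations
    assert corr["tails"]["cells"] > 0
    assert corr["overlap"]["cells"] > 0
    assert corr["tails"]["cells"] > corr["overlap"]["cells"]
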