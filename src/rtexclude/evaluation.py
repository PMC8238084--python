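"""Running the simulation study and aggregating its results.

One *iteration* of the study simulates a pair of valid RT samples with a
known population mu-difference, contaminates both samples with outliers,
applies every exclusion rule, and tests each resulting pair (plus the
uncontaminated pair, recorded under the pseudo-method ``"valid"``) with a
pooled two-sample t-test.  Aggregation over iterations yields, per method,
approach and difference level:

* ``p_sign`` — the proportion of significant tests, and
* ``bias(m | diff) = p_sign(m | diff) - p_sign(valid | diff)`` — how far a
  method's significance rate deviates from the uncontaminated benchmark.
  Positive bias points toward Type-I errors, negative toward Type-II.

Further summaries: a descriptive table of per-sample means, SDs, trial
counts and skewness for valid and contaminated samples; an OLS regression
of the t-values on the difference, the exclusion method (reference "no")
and the post-exclusion sample SD and size; and the Pearson correlation
between |bias| and the proportion of excluded RTs.
"""

from __future__ import annotations

import json
import logging
import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import SimConfig
from .contamination import contaminate_pair, draw_outlier_plan
from .distributions import draw_pair_config, make_pair
from .exclusion import METHODS
from .inference import _t_from_stats

__all__ = [
    "VALID_METHOD",
    "ExperimentResult",
    "sample_skewness",
    "iteration_rng",
    "run_experiment",
    "significance_proportion",
    "compute_bias",
    "summarize_bias",
    "regress_t_values",
    "bias_exclusion_correlation",
]

logger = logging.getLogger(__name__)

#: Pseudo-method name under which the uncontaminated pair is recorded.
VALID_METHOD = "valid"

# Stable approach codes used in substream derivation; independent of which
# subset of approaches a run selects.
_APPROACH_CODES = {"tails": 0, "overlap": 1}


def sample_skewness(x: np.ndarray) -> float:
    """Moment-ratio sample skewness g1 = m3 / m2^(3/2).

    Returns NaN for constant input.
    """
    x = np.asarray(x, dtype=float)
    d = x - x.mean()
    d2 = d * d
    m2 = d2.mean()
    if m2 == 0.0:
        return float("nan")
    m3 = (d2 * d).mean()
    return float(m3 / m2**1.5)


def iteration_rng(
    master_seed: int, approach: str, diff: float, rep: int
) -> np.random.Generator:
    """Random stream of one iteration, reproducible in isolation.

    The substream is derived from the master seed and the iteration's
    coordinates (approach, difference level, repetition index), so a single
    iteration can be re-run without replaying the whole grid.
    """
    key = (_APPROACH_CODES[approach], rep, int(round(float(diff) * 1000)))
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


@dataclass
class ExperimentResult:
    """All tables produced by one simulation run."""

    config: SimConfig
    records: pd.DataFrame
    bias: pd.DataFrame
    bias_table: pd.DataFrame
    regression: pd.DataFrame | None
    descriptives: pd.DataFrame
    correlations: dict
    counters: dict = field(default_factory=dict)

    def save(self, output_dir: str | Path | None = None) -> Path:
        """Write the result tables as CSV (plus correlations as JSON)."""
        out = Path(output_dir) if output_dir is not None else self.config.output_dir
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        self.bias.to_csv(out / "bias.csv", index=False)
        self.bias_table.to_csv(out / "bias_summary.csv")
        self.descriptives.to_csv(out / "descriptives.csv", index=False)
        if self.regression is not None:
            self.regression.to_csv(out / "regression.csv")
        with open(out / "correlations.json", "w", encoding="utf-8") as fh:
            json.dump(self.correlations, fh, indent=2)
        return out


def run_experiment(config: SimConfig) -> ExperimentResult:
    """Run the full simulation grid defined by ``config``.

    For every approach x difference x repetition: draw the pair
    configuration, simulate the valid pair, contaminate it, apply every
    exclusion method, and test.  Records are then aggregated into the bias,
    descriptive, regression and correlation summaries.

    Returns
    -------
    ExperimentResult
    """
    t_start = time.perf_counter()
    methods = list(config.methods)
    specs = [METHODS[m] for m in methods]
    diffs = list(config.diff_grid)
    reps = config.reps_per_diff
    min_n = config.min_n_after_exclusion
    n_iter = len(config.approaches) * len(diffs) * reps
    rows_per_iter = len(methods) + 1
    n_rows = n_iter * rows_per_iter

    # method code 0 is the "valid" pseudo-method
    method_categories = [VALID_METHOD] + methods

    col_approach = np.empty(n_rows, dtype=np.int8)
    col_diff = np.empty(n_rows, dtype=np.float64)
    col_rep = np.empty(n_rows, dtype=np.int32)
    col_method = np.empty(n_rows, dtype=np.int16)
    col_t = np.empty(n_rows, dtype=np.float64)
    col_df = np.empty(n_rows, dtype=np.int32)
    col_n1 = np.empty(n_rows, dtype=np.int16)
    col_n2 = np.empty(n_rows, dtype=np.int16)
    col_sd1 = np.empty(n_rows, dtype=np.float64)
    col_sd2 = np.empty(n_rows, dtype=np.float64)
    col_pel = np.empty(n_rows, dtype=np.float64)
    col_peh = np.empty(n_rows, dtype=np.float64)

    # per-approach, per-sample descriptive accumulators (2 samples per pair)
    n_samples = len(diffs) * reps * 2
    desc_acc = {
        ap: {
            "n": np.empty(n_samples, dtype=np.int16),
            "valid_mean": np.empty(n_samples),
            "valid_sd": np.empty(n_samples),
            "valid_skew": np.empty(n_samples),
            "cont_mean": np.empty(n_samples),
            "cont_sd": np.empty(n_samples),
            "cont_skew": np.empty(n_samples),
        }
        for ap in config.approaches
    }

    counters = {
        "degenerate_exclusion": Counter(),
        "low_n_after_exclusion": Counter(),
        "short_outlier_floor": Counter(),
    }

    row = 0
    for ap_idx, approach in enumerate(config.approaches):
        acc = desc_acc[approach]
        si = 0
        for diff in diffs:
            for rep in range(reps):
                rng = iteration_rng(config.master_seed, approach, diff, rep)
                pc = draw_pair_config(rng)
                s1, s2 = make_pair(pc, diff, rng)
                a, b = s1.values, s2.values
                plan = draw_outlier_plan(pc.n_trials, rng)
                c1, c2 = contaminate_pair((s1, s2), plan, approach, rng)
                if c1.degenerate_short_range or c2.degenerate_short_range:
                    counters["short_outlier_floor"][approach] += 1
                ca, cb = c1.values, c2.values
                n = pc.n_trials

                a_mean, b_mean = a.mean(), b.mean()
                a_var, b_var = a.var(ddof=1), b.var(ddof=1)

                # valid pseudo-method row; t oriented condition 2 - condition 1
                # so it grows with the population mu-shift
                t, dfree = _t_from_stats(b_mean, b_var, n, a_mean, a_var, n)
                col_approach[row] = ap_idx
                col_diff[row] = diff
                col_rep[row] = rep
                col_method[row] = 0
                col_t[row] = t
                col_df[row] = dfree
                col_n1[row] = n
                col_n2[row] = n
                col_sd1[row] = np.sqrt(a_var)
                col_sd2[row] = np.sqrt(b_var)
                col_pel[row] = 0.0
                col_peh[row] = 0.0
                row += 1

                # descriptives (both conditions)
                acc["n"][si] = n
                acc["valid_mean"][si] = a_mean
                acc["valid_sd"][si] = np.sqrt(a_var)
                acc["valid_skew"][si] = sample_skewness(a)
                acc["cont_mean"][si] = ca.mean()
                acc["cont_sd"][si] = ca.std(ddof=1)
                acc["cont_skew"][si] = sample_skewness(ca)
                si += 1
                acc["n"][si] = n
                acc["valid_mean"][si] = b_mean
                acc["valid_sd"][si] = np.sqrt(b_var)
                acc["valid_skew"][si] = sample_skewness(b)
                acc["cont_mean"][si] = cb.mean()
                acc["cont_sd"][si] = cb.std(ddof=1)
                acc["cont_skew"][si] = sample_skewness(cb)
                si += 1

                for mi, spec in enumerate(specs, start=1):
                    oa = spec.fn(ca)
                    ob = spec.fn(cb)
                    if oa.degenerate or ob.degenerate:
                        counters["degenerate_exclusion"][spec.name] += 1
                    ka = ca[oa.kept]
                    kb = cb[ob.kept]
                    na, nb = ka.size, kb.size
                    if na < min_n or nb < min_n:
                        counters["low_n_after_exclusion"][spec.name] += 1
                        t = np.nan
                        dfree = 0
                        sda = ka.std(ddof=1) if na >= 2 else np.nan
                        sdb = kb.std(ddof=1) if nb >= 2 else np.nan
                    else:
                        va = ka.var(ddof=1)
                        vb = kb.var(ddof=1)
                        t, dfree = _t_from_stats(kb.mean(), vb, nb, ka.mean(), va, na)
                        sda = np.sqrt(va)
                        sdb = np.sqrt(vb)
                    col_approach[row] = ap_idx
                    col_diff[row] = diff
                    col_rep[row] = rep
                    col_method[row] = mi
                    col_t[row] = t
                    col_df[row] = dfree
                    col_n1[row] = na
                    col_n2[row] = nb
                    col_sd1[row] = sda
                    col_sd2[row] = sdb
                    col_pel[row] = 0.5 * (oa.prop_excluded_low + ob.prop_excluded_low)
                    col_peh[row] = 0.5 * (oa.prop_excluded_high + ob.prop_excluded_high)
                    row += 1
        logger.info(
            "approach %s done (%d pairs, %.1f s elapsed)",
            approach,
            len(diffs) * reps,
            time.perf_counter() - t_start,
        )

    # two-sided p-values, vectorised over the whole record table
    p = np.full(n_rows, np.nan)
    defined = (col_df > 0) & ~np.isnan(col_t)
    p[defined] = 2.0 * stats.t.sf(np.abs(col_t[defined]), col_df[defined])
    significant = p < config.alpha  # NaN compares False

    records = pd.DataFrame(
        {
            "approach": pd.Categorical.from_codes(
                col_approach, categories=list(config.approaches)
            ),
            "diff": col_diff,
            "rep": col_rep,
            "method": pd.Categorical.from_codes(
                col_method, categories=method_categories
            ),
            "t": col_t,
            "df": col_df,
            "p": p,
            "significant": significant,
            "n_after_1": col_n1,
            "n_after_2": col_n2,
            "sd_after_1": col_sd1,
            "sd_after_2": col_sd2,
            "prop_excluded_low": col_pel,
            "prop_excluded_high": col_peh,
        }
    )

    bias = compute_bias(records)
    bias_table = summarize_bias(bias)
    descriptives = _descriptive_table(config, desc_acc)
    regression = None
    if len(methods) >= 2:
        regression = regress_t_values(records)
    correlations = None
    try:
        correlations = bias_exclusion_correlation(bias, records)
    except ValueError as exc:
        logger.info("bias/exclusion correlation not computed: %s", exc)
        correlations = {}
    counters = {k: dict(v) for k, v in counters.items()}
    logger.info(
        "experiment finished: %d iterations, %d records in %.1f s",
        n_iter,
        n_rows,
        time.perf_counter() - t_start,
    )
    return ExperimentResult(
        config=config,
        records=records,
        bias=bias,
        bias_table=bias_table,
        regression=regression,
        descriptives=descriptives,
        correlations=correlations,
        counters=counters,
    )


def _descriptive_table(config: SimConfig, desc_acc: dict) -> pd.DataFrame:
    """Per-approach summary of per-sample means, SDs, N and skewness."""
    rows = []
    for approach, acc in desc_acc.items():
        for sample, prefix in (("valid", "valid"), ("contaminated", "cont")):
            stats_map = {
                "mean": acc[f"{prefix}_mean"],
                "sd": acc[f"{prefix}_sd"],
                "n": acc["n"].astype(float),
                "skewness": acc[f"{prefix}_skew"],
            }
            for stat, values in stats_map.items():
                rows.append(
                    {
                        "approach": approach,
                        "sample": sample,
                        "statistic": stat,
                        "mean": float(np.nanmean(values)),
                        "sd": float(np.nanstd(values, ddof=1)),
                        "min": float(np.nanmin(values)),
                        "max": float(np.nanmax(values)),
                    }
                )
    return pd.DataFrame(rows)


def significance_proportion(
    records: pd.DataFrame, method: str, approach: str, diff: float
) -> float:
    """Proportion of significant tests among the matching records."""
    sel = records[
        (records["method"] == method)
        & (records["approach"] == approach)
        & (records["diff"] == diff)
    ]
    if sel.empty:
        raise ValueError(
            f"no records for method={method!r}, approach={approach!r}, diff={diff}"
        )
    return float(sel["significant"].mean())


def compute_bias(records: pd.DataFrame) -> pd.DataFrame:
    """Per method x approach x diff significance proportions and bias.

    ``bias = p_sign(method) - p_sign(valid)`` within each approach x diff
    cell; the ``"valid"`` pseudo-method therefore has bias 0 everywhere.

    Raises
    ------
    ValueError
        If the records contain no ``"valid"`` rows.
    """
    if (records["method"] == VALID_METHOD).sum() == 0:
        raise ValueError(f"records contain no {VALID_METHOD!r} rows")
    p_sign = (
        records.groupby(["approach", "diff", "method"], observed=True)["significant"]
        .mean()
        .rename("p_sign")
        .reset_index()
    )
    valid = (
        p_sign[p_sign["method"] == VALID_METHOD]
        .drop(columns="method")
        .rename(columns={"p_sign": "p_sign_valid"})
    )
    out = p_sign.merge(valid, on=["approach", "diff"], how="left")
    out["bias"] = out["p_sign"] - out["p_sign_valid"]
    return out


def summarize_bias(bias: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-diff bias into the study's summary layout.

    Rows are methods (the ``"valid"`` pseudo-method is dropped), columns the
    per-approach mean bias over all difference levels plus their unweighted
    cross-approach mean, sorted by decreasing absolute mean bias.
    """
    m = bias[bias["method"] != VALID_METHOD]
    wide = (
        m.groupby(["method", "approach"], observed=True)["bias"]
        .mean()
        .unstack("approach")
    )
    wide.insert(0, "mean", wide.mean(axis=1))
    wide = wide.reindex(wide["mean"].abs().sort_values(ascending=False).index)
    wide.columns.name = None
    return wide


def regress_t_values(
    records: pd.DataFrame, reference: str = "no"
) -> pd.DataFrame:
    """OLS of the per-iteration t-values on design and method factors.

    Predictors: the population difference, one indicator per exclusion
    method (against the ``reference`` level, by default "no exclusion"),
    and the post-exclusion sample SD and trial count averaged across the
    two conditions.  Rows of the ``"valid"`` pseudo-method and undefined
    tests are excluded.

    Returns
    -------
    pandas.DataFrame
        Coefficients indexed by term, with columns ``beta``, ``se`` and
        ``t``.
    """
    m = records[(records["method"] != VALID_METHOD) & np.isfinite(records["t"])]
    method_levels = [str(x) for x in m["method"].unique()]
    if len(method_levels) < 2:
        raise ValueError("regression requires records from at least 2 methods")
    if reference not in method_levels:
        reference = method_levels[0]
    dummy_levels = [lv for lv in method_levels if lv != reference]

    mean_sd = 0.5 * (m["sd_after_1"].to_numpy() + m["sd_after_2"].to_numpy())
    mean_n = 0.5 * (m["n_after_1"].to_numpy() + m["n_after_2"].to_numpy())
    method_arr = m["method"].astype(str).to_numpy()
    cols = [np.ones(len(m)), m["diff"].to_numpy(), mean_sd, mean_n]
    names = ["intercept", "diff", "mean_sd", "mean_n"]
    for lv in dummy_levels:
        cols.append((method_arr == lv).astype(float))
        names.append(f"method[{lv}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(m["t"].to_numpy(), X).fit()
    return pd.DataFrame(
        {"beta": fit.params, "se": fit.bse, "t": fit.tvalues}, index=names
    )


def bias_exclusion_correlation(
    bias: pd.DataFrame, records: pd.DataFrame
) -> dict:
    """Pearson correlation between |bias| and the excluded proportion.

    The "no" method excludes nothing by construction and is dropped, as is
    the ``"valid"`` pseudo-method.  Two aggregation units are reported per
    approach: ``cells`` correlates over method x diff cells, ``per_method``
    over per-method means across the difference grid.

    Raises
    ------
    ValueError
        With fewer than 3 cells or zero variance in either variable.
    """
    keep = ~records["method"].isin([VALID_METHOD, "no"])
    r = records[keep].copy()
    if r.empty:
        raise ValueError("no method records besides 'no' and 'valid'")
    r["prop_excluded"] = r["prop_excluded_low"] + r["prop_excluded_high"]
    excl = (
        r.groupby(["approach", "diff", "method"], observed=True)["prop_excluded"]
        .mean()
        .reset_index()
    )
    cells = excl.merge(
        bias[~bias["method"].isin([VALID_METHOD, "no"])],
        on=["approach", "diff", "method"],
    )
    out: dict = {}
    for approach, grp in cells.groupby("approach", observed=True):
        if len(grp) < 3:
            raise ValueError(f"fewer than 3 cells for approach {approach!r}")
        abias = grp["bias"].abs()
        # tolerance absorbs float-summation dust in constant columns
        if abias.std() < 1e-12 or grp["prop_excluded"].std() < 1e-12:
            raise ValueError(
                f"zero variance in bias or excluded proportion for {approach!r}"
            )
        r_cells = stats.pearsonr(abias, grp["prop_excluded"]).statistic
        per_method = grp.groupby("method", observed=True)[
            ["bias", "prop_excluded"]
        ].agg({"bias": lambda s: s.abs().mean(), "prop_excluded": "mean"})
        if len(per_method) >= 3 and per_method["prop_excluded"].std() > 0:
            r_meth = stats.pearsonr(
                per_method["bias"], per_method["prop_excluded"]
            ).statistic
        else:
            r_meth = float("nan")
        out[str(approach)] = {
            "cells": float(r_cells),
            "per_method": float(r_meth),
        }
    return out
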