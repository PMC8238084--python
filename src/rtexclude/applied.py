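"""Applying exclusion rules to empirical RT tables.

Input is a plain delimited table with (at least) three columns: a unit
identifier, a condition label and an RT in ms.  Each exclusion rule is
applied *within each condition separately*, mirroring how the simulation
applies rules per condition sample, and the per-condition proportions
excluded at the low (fast) and high (slow) tail are reported — the
numbers a study should state when describing its outlier handling.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .exclusion import METHODS, apply_method

__all__ = ["read_rt_table", "exclude_table"]


def read_rt_table(
    path: str | Path,
    id_col: str | None = None,
    condition_col: str | None = None,
    rt_col: str | None = None,
) -> pd.DataFrame:
    """Read a delimited RT table (delimiter sniffed; header expected).

    Without explicit column names the first three columns are taken as
    identifier, condition and RT.  RTs must be positive numbers.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 3 and not all([id_col, condition_col, rt_col]):
        raise ValueError(
            f"{path}: expected at least 3 columns (identifier, condition, RT), "
            f"got {df.shape[1]}"
        )
    id_col = id_col or df.columns[0]
    condition_col = condition_col or df.columns[1]
    rt_col = rt_col or df.columns[2]
    out = df[[id_col, condition_col, rt_col]].copy()
    out.columns = ["identifier", "condition", "rt"]
    out["rt"] = pd.to_numeric(out["rt"], errors="raise")
    if (out["rt"] <= 0).any():
        raise ValueError("RT values must be positive (ms)")
    return out


def exclude_table(
    table: pd.DataFrame, method: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag outliers in an empirical RT table, per condition.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``identifier``, ``condition``, ``rt`` (see
        :func:`read_rt_table`).
    method : str
        One of the ten exclusion-rule names.

    Returns
    -------
    (annotated, report)
        ``annotated`` is the input with added ``kept`` (bool) and ``tail``
        ({"", "low", "high"}) columns; ``report`` has one row per condition
        with the trial count, the low-/high-tail excluded proportions and
        their sum.
    """
    if method not in METHODS:
        raise ValueError(f"unknown exclusion method {method!r}")
    if not {"identifier", "condition", "rt"}.issubset(table.columns):
        raise ValueError("table must have columns identifier, condition, rt")
    annotated = table.copy()
    annotated["kept"] = True
    annotated["tail"] = ""
    report_rows = []
    for condition, grp in annotated.groupby("condition", sort=False):
        rts = grp["rt"].to_numpy(dtype=float)
        if rts.size == 1:
            warnings.warn(
                f"condition {condition!r} has a single trial; relative rules "
                "cannot exclude anything",
                stacklevel=2,
            )
        outcome = apply_method(method, rts)
        idx = grp.index
        annotated.loc[idx, "kept"] = outcome.kept
        if outcome.lower is not None:
            tail = np.where(
                rts < outcome.lower, "low", np.where(rts > outcome.upper, "high", "")
            )
        else:
            # transform-style rules: classify excluded values by side of the
            # kept range
            tail = np.full(rts.shape, "", dtype=object)
            if (~outcome.kept).any() and outcome.kept.any():
                kept_min = rts[outcome.kept].min()
                kept_max = rts[outcome.kept].max()
                tail[(~outcome.kept) & (rts < kept_min)] = "low"
                tail[(~outcome.kept) & (rts > kept_max)] = "high"
        annotated.loc[idx, "tail"] = tail
        report_rows.append(
            {
                "condition": condition,
                "n_trials": int(rts.size),
                "prop_excluded_low": outcome.prop_excluded_low,
                "prop_excluded_high": outcome.prop_excluded_high,
                "prop_excluded": outcome.prop_excluded,
            }
        )
    return annotated, pd.DataFrame(report_rows)
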